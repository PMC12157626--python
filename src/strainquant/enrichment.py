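"""Enrichment scoring of a GFP construct at Zyx-LCR-labelled strain sites.

The central pipeline: a reference mask is built from the RFP (Zyxin-LCR)
channel by Subtract Background (radius 3 px, sliding paraboloid) ->
Gaussian blur (sigma 1 px) -> Triangle auto-threshold -> Erode (1
iteration) -> particle filter (< 30 px removed).  Intensities are then read
from the ORIGINAL channels: RFP_i and GFP_i are the mean intensities inside
the mask, GFP_o the mean GFP intensity outside it, and the enrichment score
is

    score = (GFP_i - GFP_o) / RFP_i .

The score is invariant to a uniform GFP offset, scales linearly with GFP
gain, and is 0 for spatially uniform GFP.  Scores are normalized per trial
to the mean score of the wild-type reference group (so the reference mean is
exactly 1 within each trial), and groups are compared by one-way ANOVA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator, TransformerMixin

from .imageops import (
    DegenerateHistogramError,
    Histogram256,
    _THRESHOLD_METHODS,
    binarize,
    erode,
    gaussian_blur,
    label_and_filter,
    subtract_background,
)

__all__ = [
    "MaskParams",
    "EnrichmentMeasurement",
    "EmptyMaskError",
    "AnovaResult",
    "EnrichmentScorer",
    "ScoreNormalizer",
    "build_reference_mask",
    "measure_enrichment",
    "normalize_scores",
    "compare_groups",
    "run_enrichment_experiment",
]

log = logging.getLogger(__name__)


class EmptyMaskError(ValueError):
    """The reference mask contains no pixels; no measurement is defined."""


@dataclass(frozen=True)
class MaskParams:
    """Reference-mask construction parameters; defaults are the published
    recipe's verbatim settings."""

    bg_radius: float = 3.0
    use_paraboloid: bool = True
    blur_sigma: float = 1.0
    threshold_method: str = "Triangle"
    erode_iterations: int = 1
    min_area: int = 30
    connectivity: int = 8


@dataclass(frozen=True)
class EnrichmentMeasurement:
    """One image's measurement: mean intensities and the enrichment score."""

    rfp_i: float
    gfp_i: float
    gfp_o: float
    score: float
    mask_area: int
    image_id: str | None = None


def build_reference_mask(rfp, params: MaskParams | None = None, return_details: bool = False):
    """Build the strain-site reference mask from the RFP channel.

    The processed image exists only to define the mask; all intensity
    measurements are taken on the original channels.  A constant RFP image
    (degenerate histogram) yields an empty mask with a logged warning; the
    measurement layer rejects empty masks.
    """
    p = params or MaskParams()
    key = p.threshold_method.replace("_", "").replace("-", "").lower()
    try:
        threshold_fn = _THRESHOLD_METHODS[key]
    except KeyError:
        raise ValueError(f"unknown threshold method {p.threshold_method!r}") from None

    proc = subtract_background(rfp, p.bg_radius, p.use_paraboloid)
    proc = gaussian_blur(proc, p.blur_sigma)
    hist = Histogram256.from_image(proc)
    details = {"threshold_bin": None, "threshold_native": None, "mask_area": 0, "n_regions": 0}
    try:
        t = threshold_fn(hist)
    except DegenerateHistogramError:
        log.warning("constant RFP channel: reference mask is empty")
        mask = np.zeros(np.asarray(rfp).shape, dtype=bool)
        return (mask, details) if return_details else mask
    mask = binarize(hist.digitize(proc), t)
    if p.erode_iterations > 0:
        mask = erode(mask, p.erode_iterations)
    regions = label_and_filter(mask, p.min_area, p.connectivity)
    mask = regions.foreground
    details.update(
        threshold_bin=t,
        threshold_native=hist.bin_upper_edge(t),
        mask_area=int(mask.sum()),
        n_regions=regions.n_regions,
    )
    return (mask, details) if return_details else mask


def measure_enrichment(
    gfp,
    rfp,
    mask,
    image_id: str | None = None,
    stat: str = "mean",
    outside_region=None,
) -> EnrichmentMeasurement:
    """Measure RFP_i, GFP_i, GFP_o on the original channels and score.

    ``stat`` is ``"mean"`` (mean gray value, the default measure) or
    ``"sum"`` (integrated density).  ``outside_region`` optionally restricts
    the GFP_o complement to a cell/cytosol region; by default the whole
    image outside the mask is used.
    """
    gfp = np.asarray(gfp, dtype=np.float64)
    rfp = np.asarray(rfp, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if gfp.shape != rfp.shape or gfp.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: gfp {gfp.shape}, rfp {rfp.shape}, mask {mask.shape}"
        )
    if stat not in ("mean", "sum"):
        raise ValueError(f"stat must be 'mean' or 'sum', got {stat!r}")
    if not mask.any():
        raise EmptyMaskError("reference mask is empty; cannot measure enrichment")
    outside = ~mask
    if outside_region is not None:
        outside &= np.asarray(outside_region, dtype=bool)
    if not outside.any():
        raise ValueError("no pixels outside the mask to measure GFP_o")

    agg = np.mean if stat == "mean" else np.sum
    rfp_i = float(agg(rfp[mask]))
    gfp_i = float(agg(gfp[mask]))
    gfp_o = float(agg(gfp[outside]))
    if rfp_i <= 0:
        raise ValueError(f"RFP_i must be > 0 for a defined score, got {rfp_i}")
    score = (gfp_i - gfp_o) / rfp_i
    return EnrichmentMeasurement(
        rfp_i=rfp_i,
        gfp_i=gfp_i,
        gfp_o=gfp_o,
        score=score,
        mask_area=int(mask.sum()),
        image_id=image_id,
    )


class EnrichmentScorer(BaseEstimator, TransformerMixin):
    """Transformer: annotated image pairs -> per-image score table.

    Input records are ``(gfp, rfp, trial, group)`` or
    ``(gfp, rfp, trial, group, image_id)`` tuples.  Images whose mask comes
    out empty (or whose measurement is otherwise undefined) are skipped with
    a logged warning, matching the per-image error policy of the
    experiment-level runner.
    """

    def __init__(
        self,
        bg_radius: float = 3.0,
        use_paraboloid: bool = True,
        blur_sigma: float = 1.0,
        threshold_method: str = "Triangle",
        erode_iterations: int = 1,
        min_area: int = 30,
        connectivity: int = 8,
        intensity_stat: str = "mean",
    ):
        self.bg_radius = bg_radius
        self.use_paraboloid = use_paraboloid
        self.blur_sigma = blur_sigma
        self.threshold_method = threshold_method
        self.erode_iterations = erode_iterations
        self.min_area = min_area
        self.connectivity = connectivity
        self.intensity_stat = intensity_stat

    def fit(self, X=None, y=None):
        return self

    def _mask_params(self) -> MaskParams:
        return MaskParams(
            bg_radius=self.bg_radius,
            use_paraboloid=self.use_paraboloid,
            blur_sigma=self.blur_sigma,
            threshold_method=self.threshold_method,
            erode_iterations=self.erode_iterations,
            min_area=self.min_area,
            connectivity=self.connectivity,
        )

    def transform(self, X) -> pd.DataFrame:
        params = self._mask_params()
        rows = []
        for i, record in enumerate(X):
            if len(record) == 5:
                gfp, rfp, trial, group, image_id = record
            else:
                gfp, rfp, trial, group = record
                image_id = f"image_{i:04d}"
            try:
                mask, details = build_reference_mask(rfp, params, return_details=True)
                m = measure_enrichment(
                    gfp, rfp, mask, image_id=image_id, stat=self.intensity_stat
                )
            except (EmptyMaskError, ValueError) as exc:
                log.warning("skipping %s (trial=%s, group=%s): %s", image_id, trial, group, exc)
                continue
            rows.append(
                {
                    "trial": trial,
                    "group": group,
                    "image_id": image_id,
                    "mask_area": m.mask_area,
                    "threshold_bin": details["threshold_bin"],
                    "rfp_i": m.rfp_i,
                    "gfp_i": m.gfp_i,
                    "gfp_o": m.gfp_o,
                    "score": m.score,
                }
            )
        columns = [
            "trial", "group", "image_id", "mask_area", "threshold_bin",
            "rfp_i", "gfp_i", "gfp_o", "score",
        ]
        return pd.DataFrame(rows, columns=columns)


class ScoreNormalizer(BaseEstimator, TransformerMixin):
    """Per-trial normalization to the reference-group mean raw score.

    ``fit`` learns one divisor per trial (the mean raw score of the
    reference group within that trial); ``transform`` adds a ``normalized``
    column.  By construction the reference group's mean normalized score is
    exactly 1 in every trial.
    """

    def __init__(self, reference_group: str = "WT", score_col: str = "score"):
        self.reference_group = reference_group
        self.score_col = score_col

    def fit(self, X: pd.DataFrame, y=None):
        means: dict = {}
        for trial, sub in X.groupby("trial", sort=False):
            ref = sub.loc[sub["group"] == self.reference_group, self.score_col]
            if ref.empty:
                raise ValueError(
                    f"trial {trial!r} has no rows for reference group {self.reference_group!r}"
                )
            m = float(ref.mean())
            if m == 0:
                raise ValueError(
                    f"trial {trial!r}: reference-group mean score is 0; normalization undefined"
                )
            means[trial] = m
        self.reference_means_ = means
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "reference_means_"):
            raise ValueError("ScoreNormalizer must be fitted before transform")
        unknown = set(X["trial"]) - set(self.reference_means_)
        if unknown:
            raise ValueError(f"trials without fitted reference means: {sorted(map(str, unknown))}")
        out = X.copy()
        out["normalized"] = out[self.score_col] / out["trial"].map(self.reference_means_)
        return out


def normalize_scores(table: pd.DataFrame, reference_group: str = "WT") -> pd.DataFrame:
    """Divide each trial's raw scores by that trial's reference-group mean."""
    return ScoreNormalizer(reference_group=reference_group).fit_transform(table)


@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way fixed-effects ANOVA summary."""

    f: float
    p: float
    df_between: int
    df_within: int
    group_means: dict
    group_sds: dict
    group_ns: dict
    degenerate: bool = False


def compare_groups(
    table: pd.DataFrame,
    value_col: str = "normalized",
    group_col: str = "group",
) -> AnovaResult:
    """One-way ANOVA across construct groups.

    F = MS_between / MS_within with (k-1, N-k) degrees of freedom; the
    p-value comes from the F distribution.  If every group is internally
    constant (MS_within = 0) the result is degenerate: F is reported as
    infinity (or NaN when the group means also coincide) and flagged.
    """
    groups = {g: sub[value_col].to_numpy(dtype=np.float64) for g, sub in table.groupby(group_col, sort=False)}
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups for ANOVA, got {len(groups)}")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has {v.size} value(s); need >= 2")
    values = np.concatenate(list(groups.values()))
    grand = values.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_between = len(groups) - 1
    df_within = values.size - len(groups)
    stats = dict(
        group_means={g: float(v.mean()) for g, v in groups.items()},
        group_sds={g: float(v.std(ddof=1)) for g, v in groups.items()},
        group_ns={g: int(v.size) for g, v in groups.items()},
        df_between=df_between,
        df_within=df_within,
    )
    if ss_within == 0:
        if ss_between == 0:
            return AnovaResult(f=math.nan, p=math.nan, degenerate=True, **stats)
        return AnovaResult(f=math.inf, p=0.0, degenerate=True, **stats)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(scipy.stats.f.sf(f, df_between, df_within))
    return AnovaResult(f=float(f), p=p, degenerate=False, **stats)


@dataclass(frozen=True)
class ExperimentResult:
    """Score table (raw + normalized) with the group comparison."""

    scores: pd.DataFrame
    anova: AnovaResult | None
    params: MaskParams
    reference_group: str


def run_enrichment_experiment(
    records,
    params: MaskParams | None = None,
    reference_group: str = "WT",
    compare: bool = True,
) -> ExperimentResult:
    """Score every image pair, normalize per trial, compare groups.

    ``records`` is an iterable of ``(gfp, rfp, trial, group[, image_id])``.
    Per-image failures (empty mask, undefined score) are skipped and logged;
    the run fails only if the reference group ends up empty.  With fewer
    than two usable groups the ANOVA is omitted with a warning.
    """
    p = params or MaskParams()
    scorer = EnrichmentScorer(
        bg_radius=p.bg_radius,
        use_paraboloid=p.use_paraboloid,
        blur_sigma=p.blur_sigma,
        threshold_method=p.threshold_method,
        erode_iterations=p.erode_iterations,
        min_area=p.min_area,
        connectivity=p.connectivity,
    )
    table = scorer.transform(records)
    if table.empty or not (table["group"] == reference_group).any():
        raise ValueError(
            f"no usable images for reference group {reference_group!r}; cannot normalize"
        )
    table = normalize_scores(table, reference_group=reference_group)
    anova = None
    if compare:
        usable = table.groupby("group")["normalized"].count()
        if (usable >= 2).sum() >= 2:
            anova = compare_groups(table[table["group"].isin(usable[usable >= 2].index)])
        else:
            log.warning("fewer than two groups with >= 2 images; skipping ANOVA")
    return ExperimentResult(scores=table, anova=anova, params=p, reference_group=reference_group)
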