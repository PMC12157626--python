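"""Time-lapse bright-object counting (myosin-inhibition response curves).

Implements the published recipe for counting construct-positive structures
per frame: Subtract Background (radius 3 px, sliding paraboloid) ->
Rényi-entropy auto-threshold -> particle filter removing objects smaller
than 10 px -> object count.  The threshold is re-estimated independently in
each frame by default, because the recipe applies the mask pipeline per
frame; a fixed-threshold mode is available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .imageops import (
    DegenerateHistogramError,
    Histogram256,
    _THRESHOLD_METHODS,
    binarize,
    label_and_filter,
    subtract_background,
)

__all__ = ["CounterParams", "CountSeries", "ObjectCounter", "count_frame", "count_stack", "summarize_series"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CounterParams:
    """Defaults are the published recipe's verbatim settings."""

    bg_radius: float = 3.0
    use_paraboloid: bool = True
    threshold_method: str = "RenyiEntropy"
    min_area: int = 10
    connectivity: int = 8


@dataclass
class CountSeries:
    """Per-frame object counts of one time-lapse replicate."""

    counts: np.ndarray  # non-negative ints, one per frame
    times: np.ndarray  # minutes
    replicate: str | None = None
    condition: str | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.counts.shape != self.times.shape:
            raise ValueError("counts and times must have one entry per frame")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return int(self.counts.size)


class ObjectCounter(BaseEstimator, TransformerMixin):
    """Stateless transformer: time-lapse stack -> per-frame object counts.

    Parameters mirror :class:`CounterParams`.  ``fixed_threshold`` (a bin
    index 0..255) bypasses the per-frame automatic threshold when set.

    A constant frame has no thresholdable histogram; it yields a count of 0
    with a logged warning, so fully darkened time-lapses terminate cleanly.
    """

    def __init__(
        self,
        bg_radius: float = 3.0,
        use_paraboloid: bool = True,
        threshold_method: str = "RenyiEntropy",
        min_area: int = 10,
        connectivity: int = 8,
        fixed_threshold: int | None = None,
    ):
        self.bg_radius = bg_radius
        self.use_paraboloid = use_paraboloid
        self.threshold_method = threshold_method
        self.min_area = min_area
        self.connectivity = connectivity
        self.fixed_threshold = fixed_threshold

    def fit(self, X=None, y=None):
        return self

    def _threshold_fn(self):
        key = self.threshold_method.replace("_", "").replace("-", "").lower()
        try:
            return _THRESHOLD_METHODS[key]
        except KeyError:
            raise ValueError(
                f"unknown threshold method {self.threshold_method!r}"
            ) from None

    def count_frame(self, img) -> int:
        """Count surviving particles in one frame."""
        proc = subtract_background(img, self.bg_radius, self.use_paraboloid)
        hist = Histogram256.from_image(proc)
        if self.fixed_threshold is not None:
            t = int(self.fixed_threshold)
        else:
            try:
                t = self._threshold_fn()(hist)
            except DegenerateHistogramError:
                log.warning("constant frame: no structures distinguishable, count = 0")
                return 0
        mask = binarize(hist.digitize(proc), t)
        regions = label_and_filter(mask, self.min_area, self.connectivity)
        return regions.n_regions

    def transform(self, X) -> np.ndarray:
        """Apply :meth:`count_frame` to each frame of a (T, rows, cols)
        stack (or an iterable of frames)."""
        stack = np.asarray(X)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim != 3:
            raise ValueError(f"expected a (T, rows, cols) stack, got shape {stack.shape}")
        return np.array([self.count_frame(frame) for frame in stack], dtype=np.int64)


def _counter(params: CounterParams | None) -> ObjectCounter:
    p = params or CounterParams()
    return ObjectCounter(
        bg_radius=p.bg_radius,
        use_paraboloid=p.use_paraboloid,
        threshold_method=p.threshold_method,
        min_area=p.min_area,
        connectivity=p.connectivity,
    )


def count_frame(img, params: CounterParams | None = None) -> int:
    return _counter(params).count_frame(img)


def count_stack(
    stack,
    params: CounterParams | None = None,
    frame_interval: float = 1.0,
    replicate: str | None = None,
    condition: str | None = None,
) -> CountSeries:
    """Count objects independently in every frame of a time-lapse."""
    counts = _counter(params).transform(stack)
    times = np.arange(counts.size) * frame_interval
    return CountSeries(counts=counts, times=times, replicate=replicate, condition=condition)


def summarize_series(series: list[CountSeries], normalize: bool = False) -> pd.DataFrame:
    """Per-timepoint mean and standard deviation of counts, per condition.

    With ``normalize`` each series is divided by its own frame-0 count
    first (a series whose frame 0 is zero is excluded with a warning).  The
    standard deviation is the sample SD (ddof=1; NaN where n=1).
    """
    if not series:
        raise ValueError("no count series given")
    lengths = {len(s) for s in series}
    if len(lengths) != 1:
        raise ValueError(f"all series must have the same length, got lengths {sorted(lengths)}")
    rows = []
    for i, s in enumerate(series):
        values = s.counts.astype(np.float64)
        if normalize:
            if s.counts[0] == 0:
                log.warning(
                    "series %s (condition %s) excluded from normalized summary: frame-0 count is 0",
                    s.replicate if s.replicate is not None else i,
                    s.condition,
                )
                continue
            values = values / s.counts[0]
        for t, v in zip(s.times, values):
            rows.append(
                {
                    "condition": s.condition if s.condition is not None else "all",
                    "time_min": float(t),
                    "value": float(v),
                }
            )
    if not rows:
        raise ValueError("no series left to summarize (all excluded by normalization)")
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["condition", "time_min"], sort=True)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    return out
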