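"""Synthetic two-channel microscopy scenes with known ground truth.

The generator emulates the statistical structure of live fluorescence images
of *Xenopus* dorsal-mesoderm explants used to study LIM-domain recruitment
to mechanically strained actin:

* an RFP reference channel (Zyxin-LCR reporter): dim linear actin filaments
  with bright contiguous *strain-site* sub-segments, over a diffuse
  background;
* a GFP construct channel: a diffuse cytosolic pool of which a tunable
  fraction (``enrichment_rho``) is relocalized to the strain sites, plus
  optional round puncta;
* shot (Poisson) noise and additive Gaussian read noise, applied after
  compositing, then quantization to the requested bit depth.

Time-lapse stacks additionally decay the filament-associated signal
exponentially, emulating loss of strained-actin binding after myosin
inhibition (Blebbistatin); ``decay_tau = inf`` is the vehicle control.

Every scene is a pure function of its spec (including the seed):
identical spec -> bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SceneSpec",
    "TimeLapseSpec",
    "SceneTruth",
    "TimeLapseTruth",
    "make_scene",
    "make_timelapse",
    "render_noise",
]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a single two-channel scene.

    Intensities are in photons/pixel (pre-noise expected values).  With
    ``conserve_total`` on (the default for enrichment experiments), the GFP
    channel redistributes a fixed photon budget ``gfp_diffuse * n_pixels``
    between the diffuse pool and the strain sites: ``enrichment_rho`` is the
    fraction of the budget localized at strain sites, so total noiseless GFP
    is constant across rho.  With it off, strain signal of amplitude
    ``rho * gfp_strain`` is added on top of the diffuse level instead.
    """

    width: int = 512
    height: int = 512
    n_filaments: int = 10
    filament_width_sigma: float = 1.5
    filament_length_frac: tuple[float, float] = (0.3, 0.6)
    strain_fraction: float = 0.3
    n_puncta: int = 0
    puncta_sigma: float = 2.0
    puncta_amplitude: float = 300.0
    enrichment_rho: float = 0.8
    conserve_total: bool = True
    rfp_background: float = 20.0
    rfp_filament: float = 60.0
    rfp_strain: float = 400.0
    gfp_diffuse: float = 120.0
    gfp_strain: float = 2000.0
    photon_noise: bool = True
    read_sigma: float = 2.0
    hot_pixel_rate: float = 1.5e-4
    hot_pixel_amplitude: float = 8000.0
    bit_depth: int | str = 16
    seed: int = 0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError(f"width must be > 0, got {self.width}")
        if self.height <= 0:
            raise ValueError(f"height must be > 0, got {self.height}")
        if self.n_filaments < 0:
            raise ValueError(f"n_filaments must be >= 0, got {self.n_filaments}")
        if self.filament_width_sigma <= 0:
            raise ValueError(
                f"filament_width_sigma must be > 0, got {self.filament_width_sigma}"
            )
        if not 0.0 <= self.strain_fraction <= 1.0:
            raise ValueError(
                f"strain_fraction must be in [0, 1], got {self.strain_fraction}"
            )
        if self.n_puncta < 0:
            raise ValueError(f"n_puncta must be >= 0, got {self.n_puncta}")
        if self.enrichment_rho < 0:
            raise ValueError(f"enrichment_rho must be >= 0, got {self.enrichment_rho}")
        if self.conserve_total and self.enrichment_rho > 1.0:
            raise ValueError(
                "enrichment_rho must be <= 1 when conserve_total is on "
                f"(it is a budget fraction), got {self.enrichment_rho}"
            )
        if self.read_sigma < 0:
            raise ValueError(f"read_sigma must be >= 0, got {self.read_sigma}")
        if not 0.0 <= self.hot_pixel_rate <= 1.0:
            raise ValueError(f"hot_pixel_rate must be in [0, 1], got {self.hot_pixel_rate}")
        if self.hot_pixel_amplitude < 0:
            raise ValueError(
                f"hot_pixel_amplitude must be >= 0, got {self.hot_pixel_amplitude}"
            )
        if self.bit_depth not in (8, 16, "float"):
            raise ValueError(f"bit_depth must be 8, 16 or 'float', got {self.bit_depth}")
        lo, hi = self.filament_length_frac
        if not (0 < lo <= hi <= 1):
            raise ValueError(
                f"filament_length_frac must satisfy 0 < lo <= hi <= 1, got {self.filament_length_frac}"
            )


@dataclass(frozen=True)
class TimeLapseSpec:
    """A single-channel (GFP) time-lapse built on a base scene.

    The filament-associated (strain-site) component of frame *t* is scaled
    by ``exp(-t * frame_interval / decay_tau)``; all other compartments stay
    constant.  ``decay_tau = inf`` models the DMSO control.
    """

    base: SceneSpec = field(default_factory=SceneSpec)
    n_frames: int = 16
    frame_interval: float = 1.0  # minutes
    decay_tau: float = math.inf  # minutes
    decay_target: str = "strain"

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.frame_interval <= 0:
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")
        if not self.decay_tau > 0:
            raise ValueError(f"decay_tau must be > 0 (inf = control), got {self.decay_tau}")
        if self.decay_target != "strain":
            raise ValueError(
                f"decay_target must be 'strain' (filament-associated signal), got {self.decay_target!r}"
            )

    @property
    def times(self) -> np.ndarray:
        """Acquisition times in minutes, frame 0 at t=0."""
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def decay_factors(self) -> np.ndarray:
        if math.isinf(self.decay_tau):
            return np.ones(self.n_frames)
        return np.exp(-self.times / self.decay_tau)


@dataclass(frozen=True)
class SceneTruth:
    """Noiseless ground truth of one scene: compartment masks (strain is
    always a subset of filament), the pre-noise channel images, and the spec
    that produced them."""

    filament_mask: np.ndarray
    strain_mask: np.ndarray
    puncta_mask: np.ndarray
    gfp_ideal: np.ndarray
    rfp_ideal: np.ndarray
    spec: SceneSpec


@dataclass(frozen=True)
class TimeLapseTruth:
    """Ground truth of a time-lapse: the base scene truth plus the static /
    decaying decomposition of the GFP channel (frame t's noiseless image is
    ``static + decay_factors[t] * decaying``)."""

    scene: SceneTruth
    static_gfp: np.ndarray
    decaying_gfp: np.ndarray
    times: np.ndarray
    decay_factors: np.ndarray

    def ideal_frame(self, t: int) -> np.ndarray:
        return self.static_gfp + self.decay_factors[t] * self.decaying_gfp


# ---------------------------------------------------------------------------


def _scene_layout(spec: SceneSpec, rng: np.random.Generator):
    """Geometry pass: filament/strain/puncta intensity profiles and masks.

    Filaments are random line segments with a Gaussian cross-section of
    ``filament_width_sigma``; each carries one contiguous strain sub-segment
    covering ``strain_fraction`` of its length.  Masks cut the profiles at
    two sigma from the centreline.
    """
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    sig = spec.filament_width_sigma
    r2_mask = (2.0 * sig) ** 2

    fil_profile = np.zeros((h, w))
    strain_profile = np.zeros((h, w))
    fil_mask = np.zeros((h, w), dtype=bool)
    strain_mask = np.zeros((h, w), dtype=bool)

    lo, hi = spec.filament_length_frac
    for _ in range(spec.n_filaments):
        cx = rng.uniform(0.15, 0.85) * w
        cy = rng.uniform(0.15, 0.85) * h
        theta = rng.uniform(0.0, np.pi)
        length = rng.uniform(lo, hi) * min(h, w)
        s0 = rng.uniform(0.0, max(1.0 - spec.strain_fraction, 0.0))

        ux, uy = np.cos(theta), np.sin(theta)
        p0x, p0y = cx - 0.5 * length * ux, cy - 0.5 * length * uy
        vx, vy = length * ux, length * uy

        t = ((xx - p0x) * vx + (yy - p0y) * vy) / (length * length)
        tc = np.clip(t, 0.0, 1.0)
        dx = xx - (p0x + tc * vx)
        dy = yy - (p0y + tc * vy)
        d2 = dx * dx + dy * dy

        prof = np.exp(-d2 / (2.0 * sig * sig))
        near = d2 <= r2_mask
        fil_profile += prof
        fil_mask |= near
        if spec.strain_fraction > 0:
            inside = (t >= s0) & (t <= s0 + spec.strain_fraction)
            strain_profile += np.where(inside, prof, 0.0)
            strain_mask |= near & inside

    puncta_profile = np.zeros((h, w))
    puncta_mask = np.zeros((h, w), dtype=bool)
    ps = spec.puncta_sigma
    for _ in range(spec.n_puncta):
        px = rng.uniform(0.05, 0.95) * w
        py = rng.uniform(0.05, 0.95) * h
        d2 = (xx - px) ** 2 + (yy - py) ** 2
        puncta_profile += np.exp(-d2 / (2.0 * ps * ps))
        puncta_mask |= d2 <= (2.0 * ps) ** 2

    return fil_profile, strain_profile, puncta_profile, fil_mask, strain_mask, puncta_mask


def _compose_truth(spec: SceneSpec, rng: np.random.Generator):
    """Composite the noiseless channels.

    Returns ``(truth, gfp_static, gfp_decaying)`` where the GFP channel
    splits into a static part (diffuse pool + puncta) and the
    filament-associated strain-site part that time-lapses decay.
    """
    fil_p, strain_p, punc_p, fil_m, strain_m, punc_m = _scene_layout(spec, rng)

    rfp = spec.rfp_background + spec.rfp_filament * fil_p + spec.rfp_strain * strain_p

    rho = spec.enrichment_rho
    strain_sum = float(strain_p.sum())
    if spec.conserve_total:
        budget = spec.gfp_diffuse * strain_p.size
        if rho > 0 and strain_sum > 0:
            diffuse_level = spec.gfp_diffuse * (1.0 - rho)
            strain_part = (rho * budget / strain_sum) * strain_p
        else:
            diffuse_level = spec.gfp_diffuse
            strain_part = np.zeros(strain_p.shape)
    else:
        diffuse_level = spec.gfp_diffuse
        strain_part = rho * spec.gfp_strain * strain_p
    static = diffuse_level + spec.puncta_amplitude * punc_p
    static = np.broadcast_to(np.asarray(static, dtype=np.float64), strain_p.shape).copy()
    gfp = static + strain_part

    truth = SceneTruth(
        filament_mask=fil_m,
        strain_mask=strain_m,
        puncta_mask=punc_m,
        gfp_ideal=np.asarray(gfp, dtype=np.float64),
        rfp_ideal=rfp,
        spec=spec,
    )
    return truth, static, strain_part


def render_noise(
    ideal,
    photon_noise: bool = True,
    read_sigma: float = 0.0,
    bit_depth: int | str = 16,
    rng: np.random.Generator | int | None = None,
    hot_pixel_rate: float = 0.0,
    hot_pixel_amplitude: float = 0.0,
) -> np.ndarray:
    """Apply the detector noise model and quantize.

    Per-pixel photon counts are Poisson with mean equal to the noiseless
    image; read noise is additive zero-mean Gaussian with ``read_sigma``;
    impulse ("hot pixel") noise replaces a small random fraction of pixels
    with bright outliers, as sCMOS cameras and PMT spikes do — in real
    16-bit data these outliers anchor the min–max intensity range that
    256-bin auto-thresholding operates on.  Integer bit depths are clipped
    to the representable range and rounded; ``bit_depth='float'`` returns
    float64 unquantized.
    """
    arr = np.asarray(ideal, dtype=np.float64)
    if np.any(arr < 0):
        raise ValueError("ideal image must be non-negative everywhere")
    if read_sigma < 0:
        raise ValueError(f"read_sigma must be >= 0, got {read_sigma}")
    if not 0.0 <= hot_pixel_rate <= 1.0:
        raise ValueError(f"hot_pixel_rate must be in [0, 1], got {hot_pixel_rate}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = rng.poisson(arr).astype(np.float64) if photon_noise else arr.copy()
    if read_sigma > 0:
        out += rng.normal(0.0, read_sigma, size=arr.shape)
    if hot_pixel_rate > 0 and hot_pixel_amplitude > 0:
        hot = rng.random(arr.shape) < hot_pixel_rate
        if hot.any():
            out[hot] = hot_pixel_amplitude * rng.uniform(0.5, 1.0, size=int(hot.sum()))
    if bit_depth == 8:
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    if bit_depth == 16:
        return np.clip(np.rint(out), 0, 65535).astype(np.uint16)
    if bit_depth == "float":
        return out
    raise ValueError(f"bit_depth must be 8, 16 or 'float', got {bit_depth}")


def make_scene(spec: SceneSpec | None = None, **overrides):
    """Render one two-channel scene.

    Returns ``(gfp, rfp, truth)``: the noisy quantized channel images and
    the :class:`SceneTruth` (noiseless images + compartment masks).
    Keyword overrides are applied to the spec (or the defaults) first.
    """
    if spec is None:
        spec = SceneSpec(**overrides)
    elif overrides:
        spec = replace(spec, **overrides)
    ss = np.random.SeedSequence(spec.seed)
    geom_ss, gfp_ss, rfp_ss = ss.spawn(3)
    truth, _, _ = _compose_truth(spec, np.random.default_rng(geom_ss))
    gfp = render_noise(
        truth.gfp_ideal, spec.photon_noise, spec.read_sigma, spec.bit_depth,
        np.random.default_rng(gfp_ss), spec.hot_pixel_rate, spec.hot_pixel_amplitude,
    )
    rfp = render_noise(
        truth.rfp_ideal, spec.photon_noise, spec.read_sigma, spec.bit_depth,
        np.random.default_rng(rfp_ss), spec.hot_pixel_rate, spec.hot_pixel_amplitude,
    )
    return gfp, rfp, truth


def make_timelapse(spec: TimeLapseSpec | None = None, **overrides):
    """Render a single-channel (GFP) time-lapse stack.

    Returns ``(stack, truth)`` with ``stack`` shaped (T, rows, cols).  The
    strain-site component decays as ``exp(-t/tau)``; diffuse signal and
    puncta are static.  Noise is drawn from an independent per-frame stream
    derived from the scene seed, so the control (``tau=inf``) produces
    statistically identical but independently noisy frames.
    """
    if spec is None:
        spec = TimeLapseSpec(**overrides)
    elif overrides:
        spec = replace(spec, **overrides)
    base = spec.base
    ss = np.random.SeedSequence(base.seed)
    streams = ss.spawn(1 + spec.n_frames)
    truth0, static, decaying = _compose_truth(base, np.random.default_rng(streams[0]))
    factors = spec.decay_factors
    frames = []
    for t in range(spec.n_frames):
        ideal = static + factors[t] * decaying
        frames.append(
            render_noise(
                ideal, base.photon_noise, base.read_sigma, base.bit_depth,
                np.random.default_rng(streams[1 + t]),
                base.hot_pixel_rate, base.hot_pixel_amplitude,
            )
        )
    stack = np.stack(frames)
    truth = TimeLapseTruth(
        scene=truth0,
        static_gfp=static,
        decaying_gfp=decaying,
        times=spec.times,
        decay_factors=factors,
    )
    return stack, truth
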