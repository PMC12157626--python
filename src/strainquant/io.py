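"""TIFF and tabular I/O plus run configuration.

Images travel as TIFF only: single frames, two-channel scenes (C axis) and
time-lapse stacks (T axis), with the axis order recorded in metadata so a
round trip is unambiguous.  :func:`read_image` normalizes everything to a
(T, C, rows, cols) array; the helpers :func:`as_frame` / :func:`as_stack`
squeeze back down for single-frame and single-channel uses.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .counting import CounterParams
from .enrichment import MaskParams
from .synthetic import SceneSpec, TimeLapseSpec

__all__ = [
    "read_image",
    "as_frame",
    "as_stack",
    "write_frame",
    "write_scene",
    "write_stack",
    "write_mask",
    "write_results",
    "RunConfig",
]

_KNOWN_AXES = set("TCYX")


class AmbiguousAxesError(ValueError):
    """The file's axis layout cannot be inferred; pass an explicit hint."""


def read_image(path, axes: str | None = None) -> np.ndarray:
    """Read a TIFF into a (T, C, rows, cols) array, native bit depth.

    ``axes`` overrides the file's metadata (e.g. ``"TYX"`` for a time-lapse
    stored as bare multi-page TIFF).  Files with sample (RGB) axes or
    unrecognized dimensions are rejected with a message naming the fix.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        file_axes = series.axes.upper()
    ax = (axes or file_axes).upper()
    if len(ax) != data.ndim:
        raise ValueError(
            f"axes hint {ax!r} has {len(ax)} letters but data has {data.ndim} dimensions"
        )
    if not set(ax) <= _KNOWN_AXES:
        bad = "".join(sorted(set(ax) - _KNOWN_AXES))
        raise AmbiguousAxesError(
            f"{path.name}: cannot interpret axes {ax!r} (unknown: {bad!r}); "
            "pass axes='TYX', 'CYX' or 'TCYX' to state the layout explicitly"
        )
    if ax[-2:] != "YX" or len(set(ax)) != len(ax):
        raise ValueError(f"axes must be a unique sequence ending in 'YX', got {ax!r}")
    # insert missing singleton axes, order to T, C, Y, X
    for letter, position in (("C", 0), ("T", 0)):
        if letter not in ax:
            data = np.expand_dims(data, 0)
            ax = letter + ax
    order = [ax.index(letter) for letter in "TCYX"]
    return np.transpose(data, order)


def as_frame(data: np.ndarray, channel: int = 0) -> np.ndarray:
    """Extract a single 2-D frame from a (T, C, rows, cols) array."""
    if data.shape[0] != 1:
        raise ValueError(f"expected a single time point, got T={data.shape[0]}")
    return data[0, channel]


def as_stack(data: np.ndarray, channel: int = 0) -> np.ndarray:
    """Extract a (T, rows, cols) single-channel stack."""
    return data[:, channel]


def write_frame(path, img: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(img), photometric="minisblack", metadata={"axes": "YX"})


def write_scene(path, gfp: np.ndarray, rfp: np.ndarray) -> None:
    """Write a two-channel scene as a C-axis TIFF (channel 0 = GFP)."""
    tifffile.imwrite(path, np.stack([gfp, rfp]), photometric="minisblack", metadata={"axes": "CYX"})


def write_stack(path, stack: np.ndarray) -> None:
    """Write a time-lapse as a multi-page (T axis) TIFF."""
    tifffile.imwrite(path, np.asarray(stack), photometric="minisblack", metadata={"axes": "TYX"})


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as 0/255 uint8 TIFF."""
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)), photometric="minisblack", metadata={"axes": "YX"})


# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Fully resolved run configuration; unspecified fields fall back to
    the published recipe's defaults.  The resolved config is written next
    to every output so a run is reproducible from its artifacts."""

    mask: MaskParams = field(default_factory=MaskParams)
    counter: CounterParams = field(default_factory=CounterParams)
    scene: SceneSpec = field(default_factory=SceneSpec)
    reference_group: str = "WT"
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = {}
        nested = {"mask": MaskParams, "counter": CounterParams, "scene": SceneSpec}
        for f in fields(cls):
            if f.name not in data:
                continue
            value = data[f.name]
            if f.name in nested and isinstance(value, dict):
                if f.name == "scene" and isinstance(value.get("filament_length_frac"), list):
                    value = dict(value, filament_length_frac=tuple(value["filament_length_frac"]))
                value = nested[f.name](**value)
            kwargs[f.name] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)


def _plain(obj):
    """Recursively convert to YAML/JSON-safe builtins."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_results(out_dir, tables=None, masks=None, config=None) -> list[str]:
    """Write result tables, QC masks and the resolved config.

    ``tables`` maps name -> DataFrame (written as ``<name>.csv`` with stable
    column order, no index), ``masks`` maps name -> boolean array (0/255
    TIFF), ``config`` is a dict or :class:`RunConfig` (YAML).  A
    ``manifest.json`` listing every artifact is written last; re-running
    with identical inputs overwrites deterministically.  Returns the list
    of paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    for name, df in (tables or {}).items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(str(p))
    for name, mask in (masks or {}).items():
        p = out / f"{name}.tif"
        write_mask(p, mask)
        written.append(str(p))
    if config is not None:
        p = out / "config.yaml"
        data = config.to_dict() if isinstance(config, RunConfig) else dict(config)
        with open(p, "w") as fh:
            yaml.safe_dump(_plain(data), fh, sort_keys=False)
        written.append(str(p))
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump({"files": sorted(written)}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(str(manifest_path))
    return written
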