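"""Image/table I/O, run configuration, and logging.

The pipeline operates on multi-channel 2-D fluorescence fields stored as
multi-page (or multi-sample) TIFF, with feature and result tables as CSV and
configuration as JSON.  All default parameters mirror the reference
processing chain (rolling-ball radius, unsharp mask, CLAHE, median filter,
probability threshold, particle-size filters, random-forest hyperparameters).

Conventions: raster coordinates are 0-based, row-major, origin top-left.
Spatial filter parameters are stored in pixels; object areas in µm²,
converted through ``pixels_per_micron**2``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "KNOWN_CHANNELS",
    "FieldImage",
    "RunConfig",
    "get_logger",
    "load_config",
    "read_field",
    "write_field",
    "write_table",
]

#: Channel names with a fixed meaning in the dual-reporter assay.
KNOWN_CHANNELS = ("gfp", "mcherry", "lamp1", "dapi")

DEFAULT_PIXELS_PER_MICRON = 9.7


def get_logger(name: str = "mitoqc") -> logging.Logger:
    """Package logger writing level-prefixed lines to standard error."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


@dataclass
class FieldImage:
    """One acquired or simulated multi-channel field.

    Parameters
    ----------
    channels
        Mapping channel-name -> 2-D non-negative intensity raster.  All
        rasters must share one shape.  Canonical names are ``gfp``,
        ``mcherry``, ``lamp1`` and ``dapi``; extra names are allowed.
    bit_depth
        8 or 16 — the acquisition bit depth (rasters themselves may be float
        while being processed).
    pixels_per_micron
        Lateral pixel scale, strictly positive.
    meta
        Free-form condition/timepoint/replicate metadata.
    """

    channels: dict
    bit_depth: int = 16
    pixels_per_micron: float = DEFAULT_PIXELS_PER_MICRON
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.channels:
            raise ValueError("FieldImage requires at least one channel")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not self.pixels_per_micron > 0:
            raise ValueError("pixels_per_micron must be positive")
        shapes = set()
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not a 2-D raster")
            self.channels[name] = arr
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise ValueError(f"channel rasters differ in shape: {sorted(shapes)}")

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not present; have {sorted(self.channels)}"
            ) from None


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their reference protocol defaults."""

    rolling_ball_radius_px: float = 10.0
    unsharp_radius_px: float = 1.0
    unsharp_weight: float = 0.6
    clahe_block_px: int = 127
    clahe_bins: int = 256
    clahe_max_slope: float = 3.0
    median_radius_px: float = 2.0
    prob_threshold_low: float = 0.31
    min_object_area_um2: float = 0.3   # mitochondria path
    min_puncta_area_um2: float = 0.0   # red-puncta path
    pixels_per_micron: float = DEFAULT_PIXELS_PER_MICRON
    min_nucleus_area_um2: float = 20.0
    rf_final_trees: int = 500
    rf_mtry: int = 2
    rf_tune_iters: int = 25
    train_fraction: float = 0.8
    pixel_rf_trees: int = 200
    random_seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.prob_threshold_low <= 1.0:
            raise ValueError(
                f"prob_threshold_low must lie in [0, 1], got {self.prob_threshold_low}"
            )
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(
                f"train_fraction must lie in (0, 1), got {self.train_fraction}"
            )
        for key in (
            "rolling_ball_radius_px",
            "unsharp_radius_px",
            "median_radius_px",
            "min_object_area_um2",
            "min_puncta_area_um2",
            "min_nucleus_area_um2",
        ):
            if getattr(self, key) < 0:
                raise ValueError(f"{key} must be >= 0, got {getattr(self, key)}")
        if not 0.0 <= self.unsharp_weight < 1.0:
            raise ValueError(
                f"unsharp_weight must lie in [0, 1), got {self.unsharp_weight}"
            )
        if self.clahe_bins < 2:
            raise ValueError(f"clahe_bins must be >= 2, got {self.clahe_bins}")
        if self.pixels_per_micron <= 0:
            raise ValueError("pixels_per_micron must be positive")
        for key in ("rf_final_trees", "rf_mtry", "rf_tune_iters", "pixel_rf_trees"):
            if getattr(self, key) < 1:
                raise ValueError(f"{key} must be >= 1, got {getattr(self, key)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path=None) -> RunConfig:
    """Resolve a :class:`RunConfig` from an optional JSON key-value file.

    Unspecified keys take the reference defaults.  Unknown keys and
    out-of-range values raise ``ValueError`` naming the offending key.
    """
    overrides: dict = {}
    if path is not None:
        with open(path) as fh:
            overrides = json.load(fh)
        if not isinstance(overrides, dict):
            raise ValueError(f"config file {path} must hold a JSON object")
        valid = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(overrides) - valid
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(**overrides)
    get_logger().info("resolved config: %s", json.dumps(cfg.to_dict(), sort_keys=True))
    return cfg


def _page_stack(path) -> np.ndarray:
    """Read a TIFF as a (n_channels, H, W) stack, accepting page- or
    sample-interleaved layouts."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 3:
        # samples-last layout (H, W, S) with few samples -> move to front
        if arr.shape[-1] <= 4 < arr.shape[0]:
            arr = np.moveaxis(arr, -1, 0)
    else:
        raise ValueError(f"{path}: expected 2-D pages, got array of ndim {arr.ndim}")
    return arr


def read_field(
    path,
    channel_names: Sequence[str] | None = None,
    scale: float | None = None,
    bit_depth: int | None = None,
    meta: Mapping | None = None,
) -> FieldImage:
    """Read a multi-channel TIFF into a :class:`FieldImage`.

    ``channel_names`` maps pages (in order) to channel names; if omitted, a
    JSON sidecar ``<path>.json`` with a ``"channels"`` list is consulted.
    Intensities are returned exactly as stored.  A missing ``scale`` falls
    back to the package default (9.7 px/µm).
    """
    path = Path(path)
    arr = _page_stack(path)
    if channel_names is None:
        sidecar = path.with_name(path.name + ".json")
        if sidecar.exists():
            with open(sidecar) as fh:
                side = json.load(fh)
            channel_names = side.get("channels")
            scale = scale if scale is not None else side.get("pixels_per_micron")
    if channel_names is None:
        raise ValueError(
            f"{path}: channel names must be given explicitly or via a "
            f"'{path.name}.json' sidecar (never inferred from page order)"
        )
    if len(channel_names) != arr.shape[0]:
        raise ValueError(
            f"{path}: {arr.shape[0]} pages but {len(channel_names)} channel names"
        )
    if bit_depth is None:
        bit_depth = 8 if arr.dtype == np.uint8 else 16
    return FieldImage(
        channels={name: arr[i] for i, name in enumerate(channel_names)},
        bit_depth=bit_depth,
        pixels_per_micron=float(scale) if scale is not None else DEFAULT_PIXELS_PER_MICRON,
        meta=dict(meta or {}),
    )


def write_field(field_img: FieldImage, path) -> None:
    """Write a FieldImage as a multi-page TIFF plus a JSON sidecar holding
    the channel order and pixel scale (lossless round-trip with
    :func:`read_field`)."""
    path = Path(path)
    names = list(field_img.channels)
    stack = np.stack([field_img.channels[n] for n in names])
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "channels": names,
        "pixels_per_micron": field_img.pixels_per_micron,
        "bit_depth": field_img.bit_depth,
        "meta": field_img.meta,
    }
    with open(path.with_name(path.name + ".json"), "w") as fh:
        json.dump(sidecar, fh)


def write_table(records, path, columns: Sequence[str] | None = None) -> None:
    """Write flat records (sequence of mappings or a DataFrame) to CSV.

    Column order is deterministic (first record's order, or ``columns`` for
    an empty sequence); floats keep full precision.  Heterogeneous schemas
    raise ``ValueError``.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records:
            schema = list(records[0].keys())
            for i, rec in enumerate(records):
                if list(rec.keys()) != schema:
                    raise ValueError(
                        f"record {i} schema {list(rec.keys())} != {schema}"
                    )
            df = pd.DataFrame(records, columns=schema)
        else:
            df = pd.DataFrame(columns=list(columns or []))
    df.to_csv(path, index=False, float_format="%.17g")
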