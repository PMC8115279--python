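"""Seeded synthetic dual-reporter microscopy scenes with ground truth.

The generator emulates fields of cultured neurons expressing a tandem
mCherry–GFP mitochondrial reporter: healthy mitochondria fluoresce in both
channels, while mitochondria inside acidic lysosomes lose GFP and appear as
mCherry-only puncta, each co-located with a LAMP1-positive lysosome
(~1.2 µm across).  Nuclei (DAPI) define the cells used for per-cell
normalization.

Four morphology archetypes are rendered:

========== =============================================================
network    branched skeleton (3–6 branches, 2–5 µm each) ~0.4 µm wide
unbranched smooth tubule, 2–8 µm long, ~0.4 µm wide
swollen    ellipse, 1.2–2.5 µm across
punctate   disc, 0.3–0.9 µm across (sequestered mitochondria are small)
========== =============================================================

Default class mixture (network 0.1 / unbranched 0.3 / swollen 0.1 /
punctate 0.5) and the punctate-dominated mitophagy preference follow the
composition reported for stressed primary neurons.  The camera model is
Poisson shot noise at a configurable photon scale plus Gaussian read noise
over a linear background gradient, after Gaussian PSF blurring.

Objects are placed with a minimum mutual gap so that ground-truth objects
remain resolvable components after PSF blurring — the property that makes
exact count recovery a meaningful end-to-end check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_config import FieldImage
from . import morphometry

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "generate_scene",
    "generate_labeled_feature_table",
    "generate_timecourse",
    "REFERENCE_LABEL_COUNTS",
]

#: Per-class label counts of the reference hand-labeled corpus.
REFERENCE_LABEL_COUNTS = {"network": 236, "unbranched": 851, "swollen": 458, "punctate": 797}

DEFAULT_MIXTURE = {"network": 0.1, "unbranched": 0.3, "swollen": 0.1, "punctate": 0.5}
DEFAULT_MITOPHAGY_PROB = {
    "network": 0.02,
    "unbranched": 0.05,
    "swollen": 0.2,
    "punctate": 0.5,
}
#: Relative mitophagy propensity per class used when a scene programs an
#: overall rate: punctate objects are preferentially flagged.
MITOPHAGY_CLASS_WEIGHT = {
    "network": 0.1,
    "unbranched": 0.2,
    "swollen": 0.5,
    "punctate": 1.0,
}


@dataclass
class SceneConfig:
    """Parameters of one synthetic field."""

    size_px: int = 512
    pixels_per_micron: float = 9.7
    n_cells: int = 4
    n_objects: int = 60
    class_mixture: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    mitophagy_prob: dict = field(default_factory=lambda: dict(DEFAULT_MITOPHAGY_PROB))
    n_mitophagy: int | None = None  # exact flagged count (overrides probabilities)
    n_lysosomes: int = 8            # free lysosomes beyond mitophagy-coupled ones
    lysosome_diameter_um: float = 1.2
    nucleus_diameter_um: float = 8.0
    psf_sigma_px: float = 1.0
    background: float = 8.0
    background_gradient: float = 4.0
    signal_amplitude: float = 150.0
    poisson_scale: float = 0.5      # photons per intensity unit; 0 = no shot noise
    gaussian_read_sd: float = 2.0   # read-noise SD in intensity units; 0 = off
    min_gap_px: int = 6
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.size_px < 64:
            raise ValueError("scene size must be >= 64 px")
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mixture must sum to 1, sums to {total}")
        for c, p in self.mitophagy_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"mitophagy probability for {c} outside [0, 1]: {p}")
        if self.pixels_per_micron <= 0:
            raise ValueError("pixels_per_micron must be positive")

    def noise_free(self) -> "SceneConfig":
        """Copy with shot and read noise disabled."""
        return replace(self, poisson_scale=0.0, gaussian_read_sd=0.0)


@dataclass
class SyntheticScene:
    field: FieldImage
    table: pd.DataFrame          # one row per ground-truth object
    masks: dict                  # named boolean ground-truth masks
    gt_labels: np.ndarray        # object-id raster (0 = background)
    cell_count: int
    cell_centers: np.ndarray     # (n_cells, 2) nucleus centers (y, x)
    config: SceneConfig


# ---------------------------------------------------------------------------
# archetype rendering


def _bezier_points(p0, p1, ctrl, n=200):
    t = np.linspace(0.0, 1.0, n)[:, None]
    return ((1 - t) ** 2) * p0 + 2 * t * (1 - t) * ctrl + t**2 * p1


def _thicken(points: np.ndarray, tile: int, radius_px: float) -> np.ndarray:
    m = np.zeros((tile, tile), bool)
    ij = np.round(points).astype(int)
    ok = (ij[:, 0] >= 0) & (ij[:, 0] < tile) & (ij[:, 1] >= 0) & (ij[:, 1] < tile)
    m[ij[ok, 0], ij[ok, 1]] = True
    if not m.any():
        return m
    dist = ndimage.distance_transform_edt(~m)
    return dist <= radius_px


def _render_archetype(rng: np.random.Generator, cls: str, s: float) -> np.ndarray:
    """Boolean mask of one object on a tight local tile (s = px per µm)."""
    tube_r = 0.2 * s  # 0.4 µm wide tubules
    if cls == "punctate":
        d_um = rng.uniform(0.3, 0.9)
        r = d_um * s / 2.0
        n = int(math.ceil(2 * r)) + 3
        y, x = np.mgrid[0:n, 0:n]
        c = (n - 1) / 2.0
        return ((y - c) ** 2 + (x - c) ** 2) <= r * r
    if cls == "swollen":
        major_um = rng.uniform(1.6, 2.5)
        minor_um = major_um / rng.uniform(1.0, 1.4)
        a, b = major_um * s / 2.0, minor_um * s / 2.0
        th = rng.uniform(0.0, np.pi)
        n = int(math.ceil(2 * a)) + 3
        y, x = np.mgrid[0:n, 0:n]
        c = (n - 1) / 2.0
        u = (x - c) * np.cos(th) + (y - c) * np.sin(th)
        v = -(x - c) * np.sin(th) + (y - c) * np.cos(th)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if cls == "unbranched":
        length = rng.uniform(2.0, 8.0) * s
        tile = int(math.ceil(length)) + int(6 * tube_r) + 4
        c = np.array([tile / 2.0, tile / 2.0])
        th = rng.uniform(0.0, np.pi)
        d = np.array([np.sin(th), np.cos(th)])
        p0, p1 = c - d * length / 2.0, c + d * length / 2.0
        perp = np.array([-d[1], d[0]])
        ctrl = c + perp * rng.uniform(-0.2, 0.2) * length
        return _thicken(_bezier_points(p0, p1, ctrl), tile, tube_r)
    if cls == "network":
        k = rng.integers(3, 7)
        blen = rng.uniform(2.0, 5.0, size=k) * s
        tile = int(math.ceil(2 * blen.max())) + int(6 * tube_r) + 4
        c = np.array([tile / 2.0, tile / 2.0])
        pts = []
        base = rng.uniform(0.0, 2 * np.pi)
        for i in range(k):
            th = base + 2 * np.pi * i / k + rng.uniform(-0.3, 0.3)
            d = np.array([np.sin(th), np.cos(th)])
            p1 = c + d * blen[i]
            perp = np.array([-d[1], d[0]])
            ctrl = c + d * blen[i] / 2.0 + perp * rng.uniform(-0.2, 0.2) * blen[i]
            pts.append(_bezier_points(c, p1, ctrl))
        return _thicken(np.concatenate(pts), tile, tube_r)
    raise ValueError(f"unknown morphology class {cls!r}")


def _crop(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    return mask[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]


def _place(rng, occupancy: np.ndarray, tile: np.ndarray, gap: int, tries: int = 200):
    """Random top-left position where ``tile`` does not come within ``gap``
    px of occupied pixels; returns (y, x) or None."""
    H, W = occupancy.shape
    th, tw = tile.shape
    if th >= H or tw >= W:
        return None
    grown = ndimage.binary_dilation(tile, iterations=gap) if gap else tile
    for _ in range(tries):
        y = int(rng.integers(0, H - th))
        x = int(rng.integers(0, W - tw))
        if not (occupancy[y : y + th, x : x + tw] & grown).any():
            return y, x
    return None


def _disc_mask(shape, center, radius) -> np.ndarray:
    y, x = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((y - center[0]) ** 2 + (x - center[1]) ** 2) <= radius * radius


# ---------------------------------------------------------------------------
# scene generation


def _quantize(img: np.ndarray, bit_depth: int) -> np.ndarray:
    hi = 255 if bit_depth == 8 else 65535
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return np.clip(np.round(img), 0, hi).astype(dtype)


def generate_scene(cfg: SceneConfig) -> SyntheticScene:
    """Render one scene; identical configs (including seed) give
    bit-identical rasters and tables."""
    rng = np.random.default_rng(int(cfg.seed))
    s = cfg.pixels_per_micron
    H = W = cfg.size_px

    # nuclei -> cells
    nuc_r = cfg.nucleus_diameter_um * s / 2.0
    centers = []
    nuclei = np.zeros((H, W), bool)
    margin = int(math.ceil(nuc_r)) + 2
    if 2 * margin >= H:
        raise ValueError(
            f"image too small ({H} px) for nuclei of diameter "
            f"{cfg.nucleus_diameter_um} µm at {s} px/µm"
        )
    for _ in range(cfg.n_cells):
        for _try in range(500):
            cy = rng.uniform(margin, H - margin)
            cx = rng.uniform(margin, W - margin)
            if all((cy - y) ** 2 + (cx - x) ** 2 > (2.2 * nuc_r) ** 2 for y, x in centers):
                centers.append((cy, cx))
                nuclei |= _disc_mask((H, W), (cy, cx), nuc_r)
                break
        else:
            raise ValueError("image too small to place the requested nuclei")
    centers = np.array(centers).reshape(-1, 2)

    # sample object classes from the mixture
    classes = list(cfg.class_mixture)
    probs = np.array([cfg.class_mixture[c] for c in classes], dtype=float)
    drawn = rng.choice(len(classes), size=cfg.n_objects, p=probs / probs.sum())

    occupancy = nuclei.copy()
    gt_labels = np.zeros((H, W), np.int32)
    rows = []
    for oid, ci in enumerate(drawn, start=1):
        cls = classes[ci]
        tile = _crop(_render_archetype(rng, cls, s))
        pos = _place(rng, occupancy, tile, cfg.min_gap_px)
        if pos is None:
            raise ValueError(
                f"image too small for requested object count "
                f"(placed {oid - 1} of {cfg.n_objects})"
            )
        y, x = pos
        region = (slice(y, y + tile.shape[0]), slice(x, x + tile.shape[1]))
        occupancy[region] |= tile
        gt_labels[region][tile] = oid
        ys, xs = np.nonzero(tile)
        cy, cx = y + ys.mean(), x + xs.mean()
        cell_id = int(np.argmin(((centers - [cy, cx]) ** 2).sum(axis=1)))
        rows.append(
            {
                "object_id": oid,
                "class": cls,
                "centroid_y": cy,
                "centroid_x": cx,
                "area_px": int(tile.sum()),
                "area_um2": tile.sum() / (s * s),
                "cell_id": cell_id,
            }
        )
    table = pd.DataFrame(rows)

    # mitophagy flags: exact count (class-weighted, no replacement) or
    # independent per-class Bernoulli draws
    if len(table):
        if cfg.n_mitophagy is not None:
            if cfg.n_mitophagy > len(table):
                raise ValueError("n_mitophagy exceeds the object count")
            w = table["class"].map(MITOPHAGY_CLASS_WEIGHT).to_numpy(float)
            pick = rng.choice(
                len(table), size=cfg.n_mitophagy, replace=False, p=w / w.sum()
            )
            flags = np.zeros(len(table), bool)
            flags[pick] = True
        else:
            p = table["class"].map(cfg.mitophagy_prob).to_numpy(float)
            flags = rng.random(len(table)) < p
        table["mitophagy"] = flags
    else:
        table["mitophagy"] = pd.Series(dtype=bool)

    flagged = set(table.loc[table["mitophagy"], "object_id"])
    red_only = np.isin(gt_labels, list(flagged)) if flagged else np.zeros((H, W), bool)
    mito_all = gt_labels > 0
    healthy = mito_all & ~red_only

    # lysosomes: one per mitophagy event plus free ones
    lyso_r = cfg.lysosome_diameter_um * s / 2.0
    lamp1_truth = np.zeros((H, W), bool)
    for _, row in table[table["mitophagy"]].iterrows():
        lamp1_truth |= _disc_mask((H, W), (row["centroid_y"], row["centroid_x"]), lyso_r)
    for _ in range(cfg.n_lysosomes):
        cy = rng.uniform(lyso_r, H - lyso_r)
        cx = rng.uniform(lyso_r, W - lyso_r)
        lamp1_truth |= _disc_mask((H, W), (cy, cx), lyso_r)

    # render intensity channels
    amp = cfg.signal_amplitude
    obj_amp = amp * rng.uniform(0.7, 1.3, size=max(len(table), 1))
    gfp = np.zeros((H, W))
    mch = np.zeros((H, W))
    for i, row in table.iterrows():
        m = gt_labels == row["object_id"]
        mch[m] += obj_amp[i]
        if not row["mitophagy"]:
            gfp[m] += obj_amp[i]
    lamp1 = np.where(lamp1_truth, amp * 0.9, 0.0)
    dapi = np.where(nuclei, amp * 0.8, 0.0)

    channels = {}
    for name, img in (("gfp", gfp), ("mcherry", mch), ("lamp1", lamp1), ("dapi", dapi)):
        img = ndimage.gaussian_filter(img, cfg.psf_sigma_px, mode="nearest")
        img = img + cfg.background + cfg.background_gradient * (
            np.arange(W, dtype=float)[None, :] / max(W - 1, 1)
        )
        if cfg.poisson_scale > 0:
            img = rng.poisson(np.clip(img, 0, None) * cfg.poisson_scale) / cfg.poisson_scale
        if cfg.gaussian_read_sd > 0:
            img = img + rng.normal(0.0, cfg.gaussian_read_sd, size=img.shape)
        channels[name] = _quantize(img, cfg.bit_depth)

    field_img = FieldImage(
        channels=channels,
        bit_depth=cfg.bit_depth,
        pixels_per_micron=s,
        meta={"synthetic": True, "seed": int(cfg.seed)},
    )
    return SyntheticScene(
        field=field_img,
        table=table,
        masks={
            "mito_all": mito_all,
            "red_only": red_only,
            "healthy": healthy,
            "lamp1": lamp1_truth,
            "nuclei": nuclei,
        },
        gt_labels=gt_labels,
        cell_count=cfg.n_cells,
        cell_centers=centers,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# labeled feature tables


def _largest_remainder(n: int, weights: dict) -> dict:
    total = sum(weights.values())
    quotas = {c: n * w / total for c, w in weights.items()}
    counts = {c: int(math.floor(q)) for c, q in quotas.items()}
    rem = n - sum(counts.values())
    order = sorted(quotas, key=lambda c: quotas[c] - counts[c], reverse=True)
    for c in order[:rem]:
        counts[c] += 1
    return counts


def generate_labeled_feature_table(
    n_objects: int,
    seed: int,
    proportions: dict | None = None,
    pixels_per_micron: float = 9.7,
) -> pd.DataFrame:
    """Labeled descriptor rows from isolated single-object clean tiles.

    Each object is rendered alone on a noise-free tile, morphometry runs on
    the exact mask, and the row gets the generating class as its label.
    Default class proportions follow the reference corpus (236 : 851 : 458 :
    797), so ``n_objects = 2342`` reproduces those counts exactly.
    """
    if n_objects < 8:
        raise ValueError("need at least 8 objects to cover the four classes")
    props = proportions or REFERENCE_LABEL_COUNTS
    counts = _largest_remainder(n_objects, props)
    rng = np.random.default_rng(int(seed))
    s = pixels_per_micron
    rows = []
    for cls in (c for c in REFERENCE_LABEL_COUNTS if c in counts):
        for _ in range(counts[cls]):
            tile = _crop(_render_archetype(rng, cls, s))
            padded = np.pad(tile, 2)
            objs = morphometry.LabeledObjects(padded.astype(np.int32), s)
            feats = morphometry.compute_features(objs, 1)
            rows.append({**feats, "class": cls})
    df = pd.DataFrame(rows, columns=list(morphometry.FEATURE_NAMES) + ["class"])
    return df.sample(frac=1.0, random_state=int(seed) % 2**32).reset_index(drop=True)


# ---------------------------------------------------------------------------
# timecourses


def rate_to_class_probabilities(rate: float, mixture: dict) -> dict:
    """Translate an overall programmed mitophagy rate into per-class flag
    probabilities with the punctate-preferring class weights, so that the
    expected flagged fraction over the mixture equals ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must lie in [0, 1], got {rate}")
    z = sum(mixture[c] * MITOPHAGY_CLASS_WEIGHT[c] for c in mixture)
    return {c: min(1.0, rate * MITOPHAGY_CLASS_WEIGHT[c] / z) for c in mixture}


def generate_timecourse(
    base: SceneConfig, mitophagy_rates: Sequence[float], seeds: Sequence[int]
):
    """One scene per (rate, seed) pair plus a manifest table mapping each
    scene to its nominal timepoint label and programmed rate."""
    rates = list(mitophagy_rates)
    if not rates:
        raise ValueError("at least one mitophagy rate is required")
    scenes = []
    manifest = []
    for t, rate in enumerate(rates):
        probs = rate_to_class_probabilities(rate, base.class_mixture)
        for seed in seeds:
            cfg = replace(base, mitophagy_prob=probs, n_mitophagy=None, seed=int(seed) + 10007 * t)
            scene = generate_scene(cfg)
            scenes.append(scene)
            manifest.append(
                {
                    "scene_id": len(scenes) - 1,
                    "timepoint": f"T{t}",
                    "programmed_rate": rate,
                    "seed": cfg.seed,
                    "n_objects": len(scene.table),
                    "n_flagged": int(scene.table["mitophagy"].sum()),
                }
            )
    return scenes, pd.DataFrame(manifest)
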