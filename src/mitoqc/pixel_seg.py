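"""Trainable random-forest pixel classification.

A pixel classifier turns a pre-processed field into per-class probability
maps.  Two instances are used in the pipeline:

* a three-class "puncta" model over the (gfp, mcherry) channels separating
  *mitophagy* (mCherry-positive / GFP-negative), *healthy* mitochondria
  (signal in both channels) and *background* — the red-only readout requires
  both channels so the forest can learn the GFP-negative condition;
* a two-class "mitochondria" model over the gfp channel separating
  mitochondrial signal from background.

Each pixel is described by a fixed 10-feature bank per input channel: raw
intensity, Gaussian blurs at sigma 1, 2, 4, 8, difference-of-Gaussians of
adjacent sigmas, gradient magnitude, and Laplacian.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .io_config import FieldImage

__all__ = [
    "FEATURE_SIGMAS",
    "PixelTrainingSet",
    "ProbabilityMap",
    "BinaryMask",
    "PixelModel",
    "pixel_features",
    "feature_names",
    "train_pixel_classifier",
    "predict_probabilities",
    "predict_labels",
    "threshold_probability",
    "normalize_mask_polarity",
    "training_set_from_masks",
    "read_annotation_csv",
    "save_pixel_model",
    "load_pixel_model",
]

FEATURE_SIGMAS = (1.0, 2.0, 4.0, 8.0)


def feature_names(channels) -> list:
    names = []
    for ch in channels:
        names.append(f"{ch}:raw")
        names.extend(f"{ch}:gauss{s:g}" for s in FEATURE_SIGMAS)
        names.extend(
            f"{ch}:dog{a:g}-{b:g}" for a, b in zip(FEATURE_SIGMAS[:-1], FEATURE_SIGMAS[1:])
        )
        names.append(f"{ch}:gradmag")
        names.append(f"{ch}:laplacian")
    return names


def pixel_features(field: FieldImage, channels) -> np.ndarray:
    """Per-pixel feature stack of shape (H, W, 10 * len(channels))."""
    planes = []
    for ch in channels:
        img = np.asarray(field.channel(ch), dtype=np.float64)
        blurs = [ndimage.gaussian_filter(img, s, mode="nearest") for s in FEATURE_SIGMAS]
        planes.append(img)
        planes.extend(blurs)
        planes.extend(b - a for a, b in zip(blurs[:-1], blurs[1:]))
        planes.append(ndimage.gaussian_gradient_magnitude(img, 1.0, mode="nearest"))
        planes.append(ndimage.gaussian_laplace(img, 1.0, mode="nearest"))
    return np.stack(planes, axis=-1)


@dataclass
class PixelTrainingSet:
    """Labelled pixel samples: X (n, f) feature matrix, y string labels."""

    X: np.ndarray
    y: np.ndarray
    class_names: list
    channels: list

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be (n, f) with one label per row")
        present = set(np.unique(self.y))
        if len(present) < 2:
            raise ValueError(
                f"training set must contain >= 2 distinct classes, got {sorted(present)}"
            )
        unknown = present - set(self.class_names)
        if unknown:
            raise ValueError(f"labels outside class_names: {sorted(unknown)}")


@dataclass
class ProbabilityMap:
    """Per-class probability rasters; at every pixel they sum to 1."""

    probabilities: dict  # class name -> (H, W) float raster
    class_names: list

    def stack(self) -> np.ndarray:
        return np.stack([self.probabilities[c] for c in self.class_names])


@dataclass
class BinaryMask:
    values: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)


@dataclass
class PixelModel:
    forest: RandomForestClassifier
    class_names: list
    channels: list
    seed: int
    training_accuracy: float
    metadata: dict = field(default_factory=dict)


def train_pixel_classifier(
    ts: PixelTrainingSet, seed: int, n_trees: int = 200
) -> PixelModel:
    """Fit a random-forest pixel model (sqrt-d features per split).

    The model stores its class list, input channels and training-set
    accuracy; identical data and seed give identical predictions.
    """
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=int(seed),
        n_jobs=1,
    )
    forest.fit(ts.X, ts.y)
    acc = float((forest.predict(ts.X) == ts.y).mean())
    return PixelModel(
        forest=forest,
        class_names=list(ts.class_names),
        channels=list(ts.channels),
        seed=int(seed),
        training_accuracy=acc,
        metadata={
            "n_trees": n_trees,
            "feature_bank": feature_names(ts.channels),
            "n_samples": int(len(ts.y)),
        },
    )


def predict_probabilities(model: PixelModel, field: FieldImage) -> ProbabilityMap:
    """Per-class probability rasters for a field (channels must match)."""
    missing = [c for c in model.channels if c not in field.channels]
    if missing:
        raise KeyError(f"field lacks channel(s) {missing} required by the model")
    feats = pixel_features(field, model.channels)
    h, w, f = feats.shape
    proba = model.forest.predict_proba(feats.reshape(-1, f))
    # order columns by the model's declared class order
    col = {c: i for i, c in enumerate(model.forest.classes_)}
    probs = {
        name: proba[:, col[name]].reshape(h, w) for name in model.class_names
    }
    return ProbabilityMap(probabilities=probs, class_names=list(model.class_names))


def predict_labels(model: PixelModel, field: FieldImage) -> np.ndarray:
    """Per-pixel argmax of :func:`predict_probabilities`; ties go to the
    lowest class index in ``model.class_names``."""
    pm = predict_probabilities(model, field)
    return np.argmax(pm.stack(), axis=0)


def threshold_probability(pm: ProbabilityMap, class_name: str, low: float) -> BinaryMask:
    """Mask of pixels whose class probability is >= ``low`` (inclusive lower
    bound, unbounded above)."""
    if class_name not in pm.probabilities:
        raise KeyError(f"unknown class {class_name!r}; have {pm.class_names}")
    if not 0.0 <= low <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {low}")
    return BinaryMask(
        pm.probabilities[class_name] >= low,
        provenance=f"class={class_name} threshold>={low}",
    )


def normalize_mask_polarity(mask: BinaryMask) -> BinaryMask:
    """Ensure objects are the foreground (minority) phase: invert the mask
    if more than half of the pixels are True."""
    vals = mask.values
    if vals.mean() > 0.5:
        return BinaryMask(~vals, provenance=mask.provenance + " inverted")
    return BinaryMask(vals.copy(), provenance=mask.provenance)


def training_set_from_masks(
    field: FieldImage,
    class_masks: dict,
    channels,
    seed: int,
    n_per_class: int = 2000,
) -> PixelTrainingSet:
    """Build a training set by sampling pixels from per-class boolean masks
    (e.g. a synthetic scene's ground truth, or rasterized annotations).

    A class may map to a single mask (``n_per_class`` pixels sampled) or to
    a list of ``(mask, n)`` pairs — useful for oversampling rare but
    decision-critical strata such as the blurred rim around objects.
    """
    rng = np.random.default_rng(int(seed))
    feats = pixel_features(field, channels)
    flat = feats.reshape(-1, feats.shape[-1])
    Xs, ys = [], []
    for name, spec in class_masks.items():
        parts = spec if isinstance(spec, list) else [(spec, n_per_class)]
        got = 0
        for m, n in parts:
            idx = np.flatnonzero(np.asarray(m, dtype=bool).ravel())
            if idx.size == 0:
                continue
            take = rng.choice(idx, size=min(n, idx.size), replace=False)
            Xs.append(flat[take])
            ys.append(np.full(take.size, name, dtype=object))
            got += take.size
        if got == 0:
            raise ValueError(f"class {name!r} has no labelled pixels")
    return PixelTrainingSet(
        X=np.concatenate(Xs),
        y=np.concatenate(ys),
        class_names=list(class_masks),
        channels=list(channels),
    )


def read_annotation_csv(path, field: FieldImage, channels, seed: int = 0) -> PixelTrainingSet:
    """Brush-annotation support for real data: CSV with columns x, y,
    class_name (0-based pixel coordinates)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"x", "y", "class_name"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation CSV needs columns {sorted(required)}")
    h, w = field.shape
    masks: dict = {}
    for name, grp in df.groupby("class_name", sort=True):
        m = np.zeros((h, w), bool)
        ys = grp["y"].to_numpy(int)
        xs = grp["x"].to_numpy(int)
        if (ys < 0).any() or (ys >= h).any() or (xs < 0).any() or (xs >= w).any():
            raise ValueError("annotation coordinates outside the image")
        m[ys, xs] = True
        masks[str(name)] = m
    return training_set_from_masks(field, masks, channels, seed, n_per_class=10**9)


def save_pixel_model(model: PixelModel, directory) -> None:
    """Persist as a directory: JSON metadata plus the serialized forest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "class_names": model.class_names,
        "channels": model.channels,
        "seed": model.seed,
        "training_accuracy": model.training_accuracy,
        **model.metadata,
    }
    with open(directory / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    joblib.dump(model.forest, directory / "forest.joblib")


def load_pixel_model(directory) -> PixelModel:
    directory = Path(directory)
    with open(directory / "metadata.json") as fh:
        meta = json.load(fh)
    forest = joblib.load(directory / "forest.joblib")
    return PixelModel(
        forest=forest,
        class_names=meta["class_names"],
        channels=meta["channels"],
        seed=meta["seed"],
        training_accuracy=meta["training_accuracy"],
        metadata={
            k: v
            for k, v in meta.items()
            if k not in {"class_names", "channels", "seed", "training_accuracy"}
        },
    )
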