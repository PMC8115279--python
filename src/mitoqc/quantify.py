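"""Measurement endpoints: puncta per cell, colocalization, morphology
summaries, mitophagy fraction by class, and the end-to-end per-field
pipeline.

The central readout is *mitophagic flux*: the number of mCherry-only
(GFP-quenched) puncta per cell.  Red-only object counts are additionally
normalized per morphology class by the total mitochondrial objects
(mCherry-positive plus GFP-positive) to ask which shapes are preferentially
delivered to lysosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from scipy import ndimage

from . import image_ops, morphometry, pixel_seg
from .classifier import MORPHOLOGY_CLASSES, predict_morphology
from .io_config import FieldImage, RunConfig

__all__ = [
    "PunctaResult",
    "ColocResult",
    "MorphologySummary",
    "UndefinedStatisticError",
    "count_puncta_per_cell",
    "count_cells",
    "pearson_colocalization",
    "manders_coefficients",
    "summarize_morphology",
    "mitophagy_fraction_by_class",
    "run_field_pipeline",
]


class UndefinedStatisticError(ValueError):
    """A statistic whose defining denominator or variance is zero."""


@dataclass
class PunctaResult:
    image_id: str
    puncta_count: int
    cell_count: int

    def __post_init__(self):
        if self.cell_count < 1:
            raise ValueError("cell_count must be >= 1")
        if self.puncta_count < 0:
            raise ValueError("puncta_count must be >= 0")

    @property
    def puncta_per_cell(self) -> float:
        return self.puncta_count / self.cell_count


@dataclass
class ColocResult:
    pearson_r: float | None
    manders_m1: float | None
    manders_m2: float | None
    threshold_1: float | None = None
    threshold_2: float | None = None


@dataclass
class MorphologySummary:
    object_counts: dict
    object_fractions: dict
    area_fractions: dict
    total_objects: int
    total_area_um2: float


def count_puncta_per_cell(
    mask: pixel_seg.BinaryMask, scale: float, cell_count: int, image_id: str = ""
) -> PunctaResult:
    """Count 8-connected components (no size filter — every above-threshold
    particle counts) and normalize to the number of cells analyzed."""
    if cell_count < 1:
        raise ValueError("cell_count must be >= 1")
    objs = morphometry.label_objects(mask.values, scale, min_area_um2=0.0)
    return PunctaResult(image_id=image_id, puncta_count=objs.n_objects, cell_count=cell_count)


def count_cells(
    field: FieldImage, explicit_count: int | None = None, min_nucleus_area_um2: float = 20.0
) -> int:
    """Count nuclei in the dapi channel: Otsu threshold, binary opening,
    minimum nucleus area.  ``explicit_count`` overrides the channel."""
    if explicit_count is not None:
        if explicit_count < 1:
            raise ValueError("explicit cell count must be >= 1")
        return int(explicit_count)
    if "dapi" not in field.channels:
        raise ValueError("no dapi channel and no explicit cell count supplied")
    img = np.asarray(field.channel("dapi"), dtype=np.float64)
    if img.max() == img.min():
        return 0
    mask = img > threshold_otsu(img)
    mask = ndimage.binary_opening(mask, structure=np.ones((3, 3)), iterations=2)
    objs = morphometry.label_objects(mask, field.pixels_per_micron, min_nucleus_area_um2)
    return objs.n_objects


def _roi_values(ch1, ch2, roi):
    a = np.asarray(ch1, dtype=np.float64)
    b = np.asarray(ch2, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"channel shapes differ: {a.shape} vs {b.shape}")
    if roi is not None:
        roi = np.asarray(roi.values if isinstance(roi, pixel_seg.BinaryMask) else roi, bool)
        if roi.shape != a.shape:
            raise ValueError("roi shape differs from the channels")
        a, b = a[roi], b[roi]
    else:
        a, b = a.ravel(), b.ravel()
    return a, b


def pearson_colocalization(ch1, ch2, roi=None) -> float:
    """Pearson product-moment correlation of the two channels over the ROI
    (whole field by default)."""
    a, b = _roi_values(ch1, ch2, roi)
    if a.size < 2:
        raise ValueError("need at least 2 pixels for a correlation")
    if a.std() == 0 or b.std() == 0:
        raise UndefinedStatisticError("zero variance in a channel: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def manders_coefficients(ch1, ch2, t1: float | None = None, t2: float | None = None):
    """Mander's thresholded overlap coefficients.

    ``m1`` is the fraction of channel-1 intensity (over its above-threshold
    support) that lies where channel 2 is above threshold; ``m2`` is the
    symmetric quantity.  Thresholds default to per-channel Otsu.
    """
    a, b = _roi_values(ch1, ch2, None)
    if t1 is None:
        t1 = float(threshold_otsu(a)) if a.max() > a.min() else float(a.max())
    if t2 is None:
        t2 = float(threshold_otsu(b)) if b.max() > b.min() else float(b.max())
    if t1 < 0 or t2 < 0:
        raise ValueError("thresholds must be >= 0")
    sup1, sup2 = a > t1, b > t2
    denom1, denom2 = a[sup1].sum(), b[sup2].sum()
    if denom1 <= 0 or denom2 <= 0:
        raise UndefinedStatisticError("no above-threshold signal in a channel")
    m1 = float(a[sup1 & sup2].sum() / denom1)
    m2 = float(b[sup1 & sup2].sum() / denom2)
    return m1, m2, t1, t2


def summarize_morphology(records: pd.DataFrame) -> MorphologySummary:
    """Per-class object counts and object/area fractions.

    ``records`` needs ``class`` and ``area`` columns (area in µm²).  Absent
    classes report 0; an empty table reports all zeros.
    """
    counts = {c: 0 for c in MORPHOLOGY_CLASSES}
    areas = {c: 0.0 for c in MORPHOLOGY_CLASSES}
    if len(records):
        for c, grp in records.groupby("class"):
            counts[c] = int(len(grp))
            areas[c] = float(grp["area"].sum())
    n = sum(counts.values())
    total_area = sum(areas.values())
    return MorphologySummary(
        object_counts=counts,
        object_fractions={c: (counts[c] / n if n else 0.0) for c in MORPHOLOGY_CLASSES},
        area_fractions={
            c: (areas[c] / total_area if total_area else 0.0) for c in MORPHOLOGY_CLASSES
        },
        total_objects=n,
        total_area_um2=total_area,
    )


def mitophagy_fraction_by_class(red_only: dict, total: dict) -> dict:
    """Fraction of each class's mitochondrial objects that are red-only
    (mCherry-positive / GFP-negative), i.e. undergoing mitophagy.

    ``total`` is red-only plus healthy counts per class.  Classes with zero
    total report ``None`` (undefined), not 0.
    """
    out = {}
    for c in MORPHOLOGY_CLASSES:
        r = int(red_only.get(c, 0))
        t = int(total.get(c, 0))
        if r > t:
            raise ValueError(f"class {c!r}: red-only count {r} exceeds total {t}")
        out[c] = (r / t) if t > 0 else None
    return out


def _preprocessed_field(field: FieldImage, cfg: RunConfig, channels) -> FieldImage:
    return FieldImage(
        channels={c: image_ops.preprocess(field.channel(c), cfg) for c in channels},
        bit_depth=field.bit_depth,
        pixels_per_micron=field.pixels_per_micron,
        meta=dict(field.meta),
    )


def run_field_pipeline(
    field: FieldImage,
    models: dict,
    cfg: RunConfig,
    cell_count: int | None = None,
    image_id: str = "",
):
    """Full measurement chain for one field.

    ``models`` holds ``puncta_model`` (3-class pixel model over gfp+mcherry),
    optionally ``mito_model`` (2-class pixel model over gfp) and
    ``morphology_model`` (the object classifier).  Steps: preprocess ->
    pixel classification -> probability threshold -> connected components ->
    morphometry -> morphology classification -> per-cell and colocalization
    statistics.  Returns ``(record, per_object_table)``.

    Errors are re-raised with the failing stage named.
    """
    stage = "setup"
    try:
        scale = field.pixels_per_micron
        stage = "cell counting"
        n_cells = count_cells(field, cell_count, cfg.min_nucleus_area_um2)
        if n_cells < 1:
            raise ValueError("no cells found (blank dapi?) and no explicit count")

        stage = "preprocessing"
        puncta_model: pixel_seg.PixelModel = models["puncta_model"]
        proc = _preprocessed_field(
            field, cfg, [c for c in ("gfp", "mcherry", "lamp1") if c in field.channels]
        )

        stage = "red puncta segmentation"
        pm = pixel_seg.predict_probabilities(puncta_model, proc)
        red_mask = pixel_seg.normalize_mask_polarity(
            pixel_seg.threshold_probability(pm, "mitophagy", cfg.prob_threshold_low)
        )
        red_objs = morphometry.label_objects(red_mask.values, scale, cfg.min_puncta_area_um2)
        puncta = PunctaResult(image_id, red_objs.n_objects, n_cells)

        stage = "red puncta morphometry"
        red_table = morphometry.feature_table(red_objs, image_id)
        red_table["red_only"] = True

        per_object = [red_table]
        record = {
            "image_id": image_id,
            "cell_count": n_cells,
            "puncta_count": puncta.puncta_count,
            "puncta_per_cell": puncta.puncta_per_cell,
        }

        stage = "mitochondria segmentation"
        mito_model = models.get("mito_model")
        healthy_table = None
        healthy_unfiltered = None
        if mito_model is not None:
            labels = pixel_seg.predict_labels(mito_model, proc)
            mito_idx = mito_model.class_names.index("mitochondria")
            mito_mask = pixel_seg.normalize_mask_polarity(
                pixel_seg.BinaryMask(labels == mito_idx, provenance="labels==mitochondria")
            )
            mito_objs = morphometry.label_objects(
                mito_mask.values, scale, cfg.min_object_area_um2
            )
            healthy_table = morphometry.feature_table(mito_objs, image_id)
            healthy_table["red_only"] = False
            per_object.append(healthy_table)
            # unfiltered counts for the mitophagy-fraction denominator: the
            # red-only numerator path counts every particle (no size
            # filter), so the per-class totals must too
            if cfg.min_object_area_um2 > cfg.min_puncta_area_um2:
                unf = morphometry.label_objects(
                    mito_mask.values, scale, cfg.min_puncta_area_um2
                )
                healthy_unfiltered = morphometry.feature_table(unf, image_id)
            else:
                healthy_unfiltered = healthy_table

        stage = "morphology classification"
        morph_model = models.get("morphology_model")
        if morph_model is not None:
            for tbl in per_object:
                if len(tbl):
                    tbl["class"] = predict_morphology(morph_model, tbl)["class"].to_numpy()
                else:
                    tbl["class"] = pd.Series(dtype=object)
            red_summary = summarize_morphology(red_table)
            for c in MORPHOLOGY_CLASSES:
                record[f"red_frac_{c}"] = red_summary.object_fractions[c]
            if healthy_table is not None:
                filled = [t for t in per_object if len(t)]
                all_table = (
                    pd.concat(filled, ignore_index=True) if filled else per_object[0]
                )
                summary = summarize_morphology(all_table)
                for c in MORPHOLOGY_CLASSES:
                    record[f"objects_frac_{c}"] = summary.object_fractions[c]
                    record[f"area_frac_{c}"] = summary.area_fractions[c]
                if len(healthy_unfiltered):
                    healthy_unfiltered = healthy_unfiltered.copy()
                    healthy_unfiltered["class"] = predict_morphology(
                        morph_model, healthy_unfiltered
                    )["class"].to_numpy()
                parts = [t for t in (red_table, healthy_unfiltered) if len(t)]
                totals = summarize_morphology(
                    pd.concat(parts, ignore_index=True)
                    if parts
                    else red_table
                ).object_counts
                fractions = mitophagy_fraction_by_class(
                    red_summary.object_counts, totals
                )
                for c in MORPHOLOGY_CLASSES:
                    record[f"mitophagy_frac_{c}"] = fractions[c]
                    record[f"red_count_{c}"] = red_summary.object_counts[c]
                    record[f"total_count_{c}"] = totals[c]

        stage = "lamp1 puncta"
        if "lamp1" in field.channels:
            lam = proc.channel("lamp1")
            if lam.max() > lam.min():
                lmask = pixel_seg.BinaryMask(lam > threshold_otsu(lam), "lamp1>otsu")
                lmask = pixel_seg.normalize_mask_polarity(lmask)
                lobjs = morphometry.label_objects(lmask.values, scale, 0.0)
                record["lamp1_count"] = lobjs.n_objects
                record["lamp1_per_cell"] = lobjs.n_objects / n_cells
            else:
                record["lamp1_count"] = 0
                record["lamp1_per_cell"] = 0.0

        stage = "colocalization"
        if "lamp1" in field.channels and "mcherry" in field.channels:
            mch_raw = np.asarray(field.channel("mcherry"), float)
            lam_raw = np.asarray(field.channel("lamp1"), float)
            try:
                record["pearson_r"] = pearson_colocalization(mch_raw, lam_raw)
            except UndefinedStatisticError:
                record["pearson_r"] = None
            try:
                m1, m2, t1, t2 = manders_coefficients(mch_raw, lam_raw)
                record["manders_m1"], record["manders_m2"] = m1, m2
            except UndefinedStatisticError:
                record["manders_m1"] = record["manders_m2"] = None

        nonempty = [t for t in per_object if len(t)]
        table = pd.concat(nonempty, ignore_index=True) if nonempty else per_object[0]
        return record, table
    except Exception as exc:
        try:
            wrapped = type(exc)(f"[stage: {stage}] {exc}")
        except Exception:
            wrapped = RuntimeError(f"[stage: {stage}] {exc}")
        raise wrapped from exc


def train_models_from_scene(scene, cfg: RunConfig, seed: int, n_per_class: int = 1500):
    """Train the two pixel models from one synthetic scene's ground truth.

    The puncta model (gfp + mcherry) learns *mitophagy* (red-only) vs
    *healthy* vs *background* pixels; the mitochondria model (gfp) learns
    *mitochondria* vs *background*.  Training runs on the pre-processed
    channels, matching what the pipeline predicts on.
    """
    proc = _preprocessed_field(scene.field, cfg, ["gfp", "mcherry"])
    objects = scene.masks["mito_all"] | scene.masks["lamp1"] | scene.masks["nuclei"]
    bg = ~objects
    # the 3-px band around objects carries PSF-blurred intermediate
    # intensities; without explicit rim examples the forest extrapolates
    # there and sprinkles spurious red-only detections along object edges
    rim = ndimage.binary_dilation(objects, iterations=3) & bg
    bg_far = bg & ~rim
    bg_spec = [(bg_far, n_per_class), (rim, n_per_class)]

    def _with_edge(mask):
        # object borders carry partial-volume intensities; oversampling them
        # keeps edge pixels from flipping class and fragmenting components
        edge = mask & ~ndimage.binary_erosion(mask, iterations=2)
        return [(mask, n_per_class), (edge, n_per_class)]

    puncta_ts = pixel_seg.training_set_from_masks(
        proc,
        {
            "mitophagy": _with_edge(scene.masks["red_only"]),
            "healthy": _with_edge(scene.masks["healthy"]),
            "background": bg_spec,
        },
        channels=["gfp", "mcherry"],
        seed=seed,
        n_per_class=n_per_class,
    )
    puncta_model = pixel_seg.train_pixel_classifier(puncta_ts, seed, cfg.pixel_rf_trees)
    mito_ts = pixel_seg.training_set_from_masks(
        proc,
        {"mitochondria": _with_edge(scene.masks["healthy"]), "background": bg_spec},
        channels=["gfp"],
        seed=seed + 1,
        n_per_class=n_per_class,
    )
    mito_model = pixel_seg.train_pixel_classifier(mito_ts, seed + 1, cfg.pixel_rf_trees)
    return {"puncta_model": puncta_model, "mito_model": mito_model}
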