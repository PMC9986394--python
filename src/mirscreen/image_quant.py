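"""Per-field and per-well apoptotic scoring from two-channel images.

The screen's readout is the fraction of nuclei per field whose nuclear
caspase-3/7 reporter signal is positive: nuclei are segmented from the
Hoechst channel, the caspase channel is measured within each nucleus mask
only, positives are called against a threshold, and field fractions are
averaged across the fields of a well.

The segmentation stack is a standard transparent pipeline (Gaussian
smoothing, global Otsu threshold, hole filling, size filtering, optional
distance-transform watershed split); all steps are parameterized through
:class:`SegmentationParams`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import feature, filters, measure, morphology, segmentation

from .synthetic_data import FieldImage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the nuclear segmentation pipeline (pixel units)."""

    smooth_sigma: float = 2.0
    threshold_method: str = "otsu"  # or "fixed"
    fixed_threshold: float | None = None
    min_area: int = 15
    max_area: int = 10_000
    split_touching: bool = False
    watershed_min_distance: int = 7
    # foreground must separate from background by this many robust SDs,
    # otherwise the field is treated as empty rather than noise-segmented
    min_contrast_sds: float = 5.0


@dataclass(frozen=True)
class NucleusRecord:
    label: int
    centroid: tuple[float, float]  # (row, col), 0-based
    area: int
    mean_caspase: float
    is_apoptotic: bool | None = None


@dataclass(frozen=True)
class FieldScore:
    n_cells: int
    n_apoptotic: int

    @property
    def apoptotic_score(self) -> float | None:
        if self.n_cells == 0:
            return None
        return self.n_apoptotic / self.n_cells


@dataclass(frozen=True)
class WellScore:
    well: str
    cell_line: str
    inhibitor_id: str
    replicate: int
    apoptotic_score: float | None
    total_cells: int
    n_fields: int
    missing: bool = False


def _foreground_mask(hoechst: np.ndarray, params: SegmentationParams) -> np.ndarray:
    img = hoechst.astype(np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    if np.ptp(img) == 0:  # all-constant channel: no foreground
        return np.zeros_like(img, dtype=bool)
    smoothed = ndi.gaussian_filter(img, params.smooth_sigma)
    if params.threshold_method == "fixed":
        if params.fixed_threshold is None:
            raise ValueError("fixed threshold method requires fixed_threshold")
        thr = params.fixed_threshold
    elif params.threshold_method == "otsu":
        thr = filters.threshold_otsu(smoothed)
        med = np.median(smoothed)
        mad_sd = 1.4826 * np.median(np.abs(smoothed - med))
        if thr <= med + params.min_contrast_sds * max(mad_sd, 1e-12):
            return np.zeros_like(img, dtype=bool)  # unimodal noise, no nuclei
    else:
        raise ValueError(f"unknown threshold method {params.threshold_method!r}")
    mask = smoothed > thr
    mask = ndi.binary_fill_holes(mask)
    return mask


def _label_nuclei(mask: np.ndarray, params: SegmentationParams) -> np.ndarray:
    if params.split_touching:
        distance = ndi.distance_transform_edt(mask)
        coords = feature.peak_local_max(
            distance, min_distance=params.watershed_min_distance, labels=mask
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        labels = segmentation.watershed(-distance, markers, mask=mask)
    else:
        labels, _ = ndi.label(mask)
    return labels


def segment_nuclei(
    image: FieldImage, params: SegmentationParams | None = None
) -> list[NucleusRecord]:
    """Segment nuclei from the Hoechst channel; measure caspase per nucleus.

    Returns one record per detected nucleus with area inside
    [min_area, max_area]; ``mean_caspase`` is the mean caspase-channel
    intensity over the nucleus pixel mask. ``is_apoptotic`` is left unset.
    """
    params = params or SegmentationParams()
    if image.hoechst.shape != image.caspase.shape:
        raise ValueError("channel shapes differ")
    mask = _foreground_mask(image.hoechst, params)
    if not mask.any():
        return []
    labels = _label_nuclei(mask, params)
    records: list[NucleusRecord] = []
    out_label = 0
    for prop in measure.regionprops(labels, intensity_image=image.caspase.astype(np.float64)):
        if not (params.min_area <= prop.area <= params.max_area):
            continue
        out_label += 1
        records.append(
            NucleusRecord(
                label=out_label,
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                area=int(prop.area),
                mean_caspase=float(prop.intensity_mean),
            )
        )
    return records


def call_apoptotic(
    nuclei: Sequence[NucleusRecord],
    fixed_threshold: float = 3000.0,
    otsu_on_nuclei: bool = False,
) -> list[NucleusRecord]:
    """Flag each nucleus apoptotic if mean_caspase >= threshold.

    With ``otsu_on_nuclei`` the threshold is derived from the per-nucleus
    caspase means by Otsu's method; with fewer than 2 nuclei this falls back
    to the fixed threshold (warning logged). Raising the threshold can never
    increase the number of positives.
    """
    thr = fixed_threshold
    if otsu_on_nuclei:
        if len(nuclei) < 2:
            logger.warning(
                "otsu_on_nuclei needs >=2 nuclei (got %d); using fixed threshold %g",
                len(nuclei),
                fixed_threshold,
            )
        else:
            vals = np.array([n.mean_caspase for n in nuclei])
            thr = float(filters.threshold_otsu(vals)) if np.ptp(vals) > 0 else fixed_threshold
    return [replace(n, is_apoptotic=bool(n.mean_caspase >= thr)) for n in nuclei]


def score_field(nuclei: Sequence[NucleusRecord]) -> FieldScore:
    """Fraction of apoptotic nuclei in one field (the apoptotic score)."""
    for n in nuclei:
        if n.is_apoptotic is None:
            raise ValueError("is_apoptotic unset; run call_apoptotic first")
    return FieldScore(
        n_cells=len(nuclei), n_apoptotic=sum(1 for n in nuclei if n.is_apoptotic)
    )


def aggregate_well(
    field_scores: Iterable[FieldScore],
    well: str = "",
    cell_line: str = "",
    inhibitor_id: str = "",
    replicate: int = 1,
) -> WellScore:
    """Average defined field scores into one per-well apoptotic score.

    Fields with no cells are skipped; a well where every field is empty is
    returned flagged missing (score None) so callers can exclude it with a
    logged reason rather than treat it as zero apoptosis.
    """
    scores = list(field_scores)
    defined = [f.apoptotic_score for f in scores if f.n_cells > 0]
    total_cells = sum(f.n_cells for f in scores)
    if not defined:
        logger.warning("well %s: all %d fields empty, flagged missing", well, len(scores))
        return WellScore(well, cell_line, inhibitor_id, replicate, None, 0, len(scores), missing=True)
    return WellScore(
        well,
        cell_line,
        inhibitor_id,
        replicate,
        float(np.mean(defined)),
        total_cells,
        len(scores),
    )


def quantify_field(
    image: FieldImage,
    params: SegmentationParams | None = None,
    fixed_threshold: float = 3000.0,
    otsu_on_nuclei: bool = False,
) -> tuple[FieldScore, list[NucleusRecord]]:
    """Full per-field pipeline: segment, call positives, score."""
    nuclei = call_apoptotic(
        segment_nuclei(image, params),
        fixed_threshold=fixed_threshold,
        otsu_on_nuclei=otsu_on_nuclei,
    )
    return score_field(nuclei), nuclei


def well_scores_frame(wells: Iterable[WellScore]) -> pd.DataFrame:
    rows = [
        {
            "well": w.well,
            "cell_line": w.cell_line,
            "inhibitor_id": w.inhibitor_id,
            "role": "sample",
            "replicate": w.replicate,
            "apoptotic_score": w.apoptotic_score,
            "total_cells": w.total_cells,
            "n_fields": w.n_fields,
        }
        for w in wells
        if not w.missing
    ]
    return pd.DataFrame(rows)
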