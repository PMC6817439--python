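"""Histologic grading and per-lesion ROI summaries.

The histologic index is the expected differentiation score of a tissue
sample: a weighted sum over the four differentiation classes with
weights 0 (normal), 1 (well-differentiated), 2 (moderately
well-differentiated) and 3 (poorly differentiated).  Lesions are
dichotomized at the clinical-style cutoff: index ≤ 2 is low grade,
index > 2 high grade.  Voxel selection requires at least half of the
voxel footprint to be tumor, and ROI summaries report mean/min pH,
mean/max Lac/Pyr and mean ADC over selected, modality-valid voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .adc import AdcMap
from .metabolite import LacPyrMap
from .ph import PhMap

__all__ = [
    "LesionRecord",
    "INDEX_WEIGHTS",
    "GRADE_CUTOFF",
    "histology_index",
    "dichotomize_grade",
    "select_voxels",
    "roi_summary",
]

INDEX_WEIGHTS = {"normal": 0.0, "well": 1.0, "moderate": 2.0, "poor": 3.0}
GRADE_CUTOFF = 2.0


@dataclass
class LesionRecord:
    """Per-lesion summary row: imaging statistics, grade and expression."""

    lesion_id: str
    mouse_id: str
    grade: str
    histology_index: float
    mean_ph: float = np.nan
    min_ph: float = np.nan
    mean_lacpyr: float = np.nan
    max_lacpyr: float = np.nan
    mean_adc: float = np.nan
    expression: dict[str, float] = field(default_factory=dict)
    n_voxels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.grade not in ("low", "high"):
            raise ValueError("grade must be 'low' or 'high'")
        if np.isfinite(self.mean_ph) and np.isfinite(self.min_ph):
            if self.min_ph > self.mean_ph + 1e-12:
                raise ValueError("minimum pH cannot exceed mean pH")
        if np.isfinite(self.mean_lacpyr) and np.isfinite(self.max_lacpyr):
            if self.max_lacpyr < self.mean_lacpyr - 1e-12:
                raise ValueError("maximum Lac/Pyr cannot be below the mean")

    def to_dict(self) -> dict:
        row = {
            "lesion_id": self.lesion_id,
            "mouse_id": self.mouse_id,
            "grade": self.grade,
            "histology_index": self.histology_index,
            "mean_ph": self.mean_ph,
            "min_ph": self.min_ph,
            "mean_lacpyr": self.mean_lacpyr,
            "max_lacpyr": self.max_lacpyr,
            "mean_adc": self.mean_adc,
        }
        for gene, level in self.expression.items():
            row[f"expr_{gene}"] = level
        for modality, n in self.n_voxels.items():
            row[f"n_voxels_{modality}"] = n
        return row


def histology_index(composition: Mapping[str, float]) -> float:
    """Weighted differentiation index in [0, 3].

    index = 0·f_normal + 1·f_well + 2·f_moderate + 3·f_poor, with the
    fractions summing to 1.
    """
    fracs = {k: float(composition.get(k, 0.0)) for k in INDEX_WEIGHTS}
    if any(f < 0 or f > 1 for f in fracs.values()):
        raise ValueError("composition fractions must lie in [0, 1]")
    if abs(sum(fracs.values()) - 1.0) > 1e-9:
        raise ValueError("composition fractions must sum to 1")
    return sum(INDEX_WEIGHTS[k] * f for k, f in fracs.items())


def dichotomize_grade(index: float) -> str:
    """Dichotomize the histologic index: low iff index ≤ 2, else high."""
    if not 0.0 <= index <= 3.0:
        raise ValueError("histologic index must lie in [0, 3]")
    return "low" if index <= GRADE_CUTOFF else "high"


def select_voxels(roi_mask: np.ndarray, tumor_fraction: np.ndarray,
                  threshold: float = 0.5) -> np.ndarray:
    """Voxels inside the ROI with at least ``threshold`` tumor content.

    The comparison is inclusive ("at least 50% tumor").  An empty
    selection is allowed but flagged with a warning.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    roi_mask = np.asarray(roi_mask, dtype=bool)
    tumor_fraction = np.asarray(tumor_fraction, dtype=float)
    if roi_mask.shape != tumor_fraction.shape:
        raise ValueError("mask and tumor-fraction grids differ")
    sel = roi_mask & (tumor_fraction >= threshold)
    if not sel.any():
        warnings.warn("voxel selection is empty", stacklevel=2)
    return sel


def _masked_stats(values: np.ndarray, sel: np.ndarray):
    vals = values[sel & np.isfinite(values)]
    if vals.size == 0:
        return np.nan, np.nan, np.nan, 0
    return float(vals.mean()), float(vals.min()), float(vals.max()), int(vals.size)


def roi_summary(
    ph: PhMap | None,
    lacpyr: LacPyrMap | None,
    adc: AdcMap | None,
    voxels: np.ndarray | Mapping[str, np.ndarray],
    *,
    lesion_id: str,
    mouse_id: str,
    grade: str,
    histology_index: float,
    expression: Mapping[str, float] | None = None,
) -> LesionRecord:
    """Summarize a lesion into a :class:`LesionRecord`.

    ``voxels`` is either one boolean selection shared by all modalities
    (common grid) or a mapping with keys ``"ph"``, ``"lacpyr"``,
    ``"adc"`` when the modalities live on different grids.  Statistics
    run over the intersection of the selection and each modality's
    validity mask; a modality with no surviving voxel reports NaN.
    """
    def sel_for(name: str) -> np.ndarray | None:
        if isinstance(voxels, Mapping):
            return np.asarray(voxels[name], dtype=bool) if name in voxels else None
        return np.asarray(voxels, dtype=bool)

    record = LesionRecord(
        lesion_id=lesion_id, mouse_id=mouse_id, grade=grade,
        histology_index=histology_index,
        expression=dict(expression or {}),
    )
    if ph is not None and sel_for("ph") is not None:
        mean, mn, _, n = _masked_stats(ph.ph, sel_for("ph") & ph.valid)
        record.mean_ph, record.min_ph = mean, mn
        record.n_voxels["ph"] = n
    if lacpyr is not None and sel_for("lacpyr") is not None:
        mean, _, mx, n = _masked_stats(lacpyr.ratio, sel_for("lacpyr") & lacpyr.valid)
        record.mean_lacpyr, record.max_lacpyr = mean, mx
        record.n_voxels["lacpyr"] = n
    if adc is not None and sel_for("adc") is not None:
        mean, _, _, n = _masked_stats(adc.adc, sel_for("adc") & adc.valid)
        record.mean_adc = mean
        record.n_voxels["adc"] = n
    return record
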