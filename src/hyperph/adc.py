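"""Apparent diffusion coefficient mapping from multi-b-value DWI.

Per voxel the mono-exponential decay S(b) = S0·exp(−b·ADC) is fit by
weighted log-linear least squares with weights ∝ S², which approximates
direct signal-domain least squares while staying closed-form and
deterministic.  The residual reported per voxel is the root-mean-square
misfit in the signal domain.  Filtering follows two exclusion rules:
an upper limit on the RMS residual (default 500, in the scanner's
arbitrary signal units) and the free-water ceiling ADC > 3.0×10⁻³ mm²/s
at 37 °C; both comparisons are strict, so boundary voxels are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import DwiStack

__all__ = ["AdcMap", "fit_adc", "filter_adc", "FREE_WATER_ADC"]

#: Diffusion coefficient of free water at 37 °C, mm²/s.
FREE_WATER_ADC = 3.0e-3


@dataclass
class AdcMap:
    """Per-voxel ADC fit results with validity mask and QC counters."""

    adc: np.ndarray  # mm²/s
    s0: np.ndarray
    rms_residual: np.ndarray
    valid: np.ndarray
    exclusions: dict[str, int] = field(default_factory=dict)


def fit_adc(stack: DwiStack) -> AdcMap:
    """Fit S(b) = S0·exp(−b·ADC) per voxel.

    Log-linear weighted least squares (weights ∝ S²); voxels with any
    non-positive signal are flagged unfittable and masked.  Requires at
    least 3 b-values.
    """
    b = stack.b_values
    if b.size < 3:
        raise ValueError("need at least 3 b-values to fit ADC")
    sig = np.asarray(stack.signal, dtype=float)
    fittable = np.all(sig > 0, axis=-1)
    safe = np.where(sig > 0, sig, 1.0)
    y = np.log(safe)
    w = safe**2
    # closed-form weighted linear fit of y = a + m·b per voxel
    sw = w.sum(axis=-1)
    sb = (w * b).sum(axis=-1) / sw
    sy = (w * y).sum(axis=-1) / sw
    cov_by = (w * (b - sb[..., None]) * (y - sy[..., None])).sum(axis=-1)
    var_b = (w * (b - sb[..., None]) ** 2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(var_b > 0, cov_by / var_b, 0.0)
    intercept = sy - slope * sb
    adc = -slope
    s0 = np.exp(intercept)
    pred = s0[..., None] * np.exp(-np.asarray(b) * adc[..., None])
    rms = np.sqrt(np.mean((sig - pred) ** 2, axis=-1))
    adc = np.where(fittable, adc, np.nan)
    s0 = np.where(fittable, s0, np.nan)
    rms = np.where(fittable, rms, np.nan)
    return AdcMap(adc=adc, s0=s0, rms_residual=rms, valid=fittable,
                  exclusions={"unfittable": int((~fittable).sum())})


def filter_adc(adc_map: AdcMap, residual_limit: float = 500.0,
               adc_limit: float = FREE_WATER_ADC) -> AdcMap:
    """Apply the residual and free-water exclusion rules.

    Voxels with rms_residual > residual_limit or ADC > adc_limit are
    masked invalid (strict inequalities: values exactly at a limit are
    retained).  Exclusion counts by reason are recorded; the operation
    is idempotent.
    """
    if residual_limit <= 0 or adc_limit <= 0:
        raise ValueError("limits must be positive")
    with np.errstate(invalid="ignore"):
        bad_resid = adc_map.valid & (adc_map.rms_residual > residual_limit)
        bad_adc = adc_map.valid & (adc_map.adc > adc_limit)
    valid = adc_map.valid & ~bad_resid & ~bad_adc
    exclusions = dict(adc_map.exclusions)
    exclusions["residual"] = int(bad_resid.sum())
    exclusions["free_water"] = int(bad_adc.sum())
    return AdcMap(adc=adc_map.adc, s0=adc_map.s0,
                  rms_residual=adc_map.rms_residual, valid=valid,
                  exclusions=exclusions)
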