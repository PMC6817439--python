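"""Lactate-to-pyruvate ratio maps with the asymmetric SNR rules.

The pyruvate/lactate volume (12×12×16 over 40 mm) and the CSI slab
(8×8 over 32 mm, 6.5 or 10 mm thick) live on different grids; analysis
happens on a common 2×2 mm² in-plane grid in scanner coordinates with
the origin at isocenter.  Axial slices are averaged to match the CSI
slab, in-plane resampling is Fourier (zero-fill) interpolation — the
natural interpolant for k-space-limited data, and exactly
signal-conserving — and the ratio applies asymmetric SNR thresholds:
lactate voxels below SNR 4 are excluded, pyruvate voxels below SNR 4
are replaced by the mean noise magnitude before division (a noise-floor
denominator rather than a hole in the map).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import resample

from .csi import MetaboliteMap, RAYLEIGH_MEAN

__all__ = [
    "LacPyrMap",
    "match_slices",
    "regrid_inplane",
    "crop_to_fov",
    "lac_pyr_ratio",
    "mean_noise_magnitude",
]


@dataclass
class LacPyrMap:
    """Per-voxel Lac/Pyr ratio with QC mask and source SNRs."""

    ratio: np.ndarray
    valid: np.ndarray
    snr_lac: np.ndarray
    snr_pyr: np.ndarray
    snr_min: float = 4.0

    def __post_init__(self) -> None:
        if np.any(self.ratio[self.valid] < 0):
            raise ValueError("valid Lac/Pyr ratios must be non-negative")


def slice_centers(n_slices: int, extent_mm: float) -> np.ndarray:
    """Axial slice-center coordinates for a volume centered on isocenter."""
    dz = extent_mm / n_slices
    return -extent_mm / 2.0 + (np.arange(n_slices) + 0.5) * dz


def match_slices(volume: np.ndarray, slab_center_mm: float,
                 slab_thickness_mm: float, extent_mm: float) -> np.ndarray:
    """Average the axial slices whose centers fall inside a slab.

    The slab interval is half-open on the superior edge:
    centers in [center − t/2, center + t/2).  Used to collapse the 3D
    metabolite volume onto the 2D CSI slab before ratio computation.
    """
    if volume.ndim != 3:
        raise ValueError("expected a 3D volume (x, y, z)")
    if slab_thickness_mm <= 0:
        raise ValueError("slab thickness must be positive")
    zc = slice_centers(volume.shape[2], extent_mm)
    lo = slab_center_mm - slab_thickness_mm / 2.0
    hi = slab_center_mm + slab_thickness_mm / 2.0
    sel = (zc >= lo) & (zc < hi)
    if not sel.any():
        raise ValueError("slab captures no slices")
    return volume[:, :, sel].mean(axis=2)


def regrid_inplane(map2d: np.ndarray, fov_mm: float,
                   target_spacing_mm: float) -> np.ndarray:
    """Fourier (zero-fill) interpolation of a 2D map onto a finer grid.

    The target spacing must divide the FOV.  Total signal — sum times
    voxel area — is conserved exactly, because zero-filling preserves
    the DC Fourier coefficient.
    """
    if map2d.ndim != 2:
        raise ValueError("expected a 2D map")
    n_target = fov_mm / target_spacing_mm
    if abs(n_target - round(n_target)) > 1e-9:
        raise ValueError("target spacing must divide the field of view")
    n_target = int(round(n_target))
    if n_target == map2d.shape[0] == map2d.shape[1]:
        return map2d.astype(float, copy=True)
    out = resample(map2d.astype(float), n_target, axis=0)
    out = resample(out, n_target, axis=1)
    return out


def crop_to_fov(map2d: np.ndarray, fov_mm: float, target_fov_mm: float,
                spacing_mm: float) -> np.ndarray:
    """Crop a centered 2D map to a smaller centered FOV (voxel centers
    strictly inside the target extent are kept)."""
    centers = slice_centers(map2d.shape[0], fov_mm)
    keep = np.abs(centers) < target_fov_mm / 2.0
    expected = int(round(target_fov_mm / spacing_mm))
    if keep.sum() != expected:
        raise ValueError("target FOV not commensurate with the grid")
    return map2d[np.ix_(keep, keep)]


def mean_noise_magnitude(noise_sigma: float) -> float:
    """Mean magnitude of pure complex noise (Rayleigh mean) at Gaussian σ."""
    return float(noise_sigma) * RAYLEIGH_MEAN


def lac_pyr_ratio(lac: MetaboliteMap, pyr: MetaboliteMap,
                  snr_min: float = 4.0) -> LacPyrMap:
    """Lac/Pyr ratio map under the asymmetric SNR rules.

    Lactate voxels with SNR < ``snr_min`` are masked invalid; pyruvate
    voxels with SNR < ``snr_min`` have their value replaced by the mean
    noise magnitude (Rayleigh mean of the noise) before division, which
    bounds the ratio without discarding high-lactate voxels.
    """
    if lac.value.shape != pyr.value.shape:
        raise ValueError("lactate and pyruvate maps must share a grid")
    snr_l, snr_p = lac.snr, pyr.snr
    low_p = snr_p < snr_min
    floor = mean_noise_magnitude(pyr.noise_sigma)
    valid = (snr_l >= snr_min) & np.asarray(lac.valid) & np.asarray(pyr.valid)
    if floor <= 0 and np.any(valid & low_p & (pyr.value == 0)):
        raise ValueError(
            "zero noise level with zero pyruvate: ratio floor undefined"
        )
    denom = np.where(low_p & (floor > 0), floor, pyr.value)
    valid = valid & (denom > 0)  # e.g. Gibbs-ringing negatives at zero noise
    ratio = np.full(lac.value.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio[valid] = lac.value[valid] / denom[valid]
    ratio[valid] = np.maximum(ratio[valid], 0.0)
    return LacPyrMap(ratio=ratio, valid=valid, snr_lac=snr_l, snr_pyr=snr_p,
                     snr_min=snr_min)
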