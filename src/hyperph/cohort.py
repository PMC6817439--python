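"""Digital TRAMP cohort: ground-truth lesions and simulated acquisitions.

This module builds a fully synthetic stand-in for a hyperpolarized-¹³C
multiparametric mouse imaging study.  Each digital lesion carries known
ground-truth fields -- extracellular pH, lactate-to-pyruvate ratio,
apparent diffusion coefficient, tumor fraction, histologic composition and
glycolytic gene expression -- laid out on the native grid of the
acquisition that measures it:

* a 2D chemical-shift-imaging (CSI) slab, 8×8 voxels over a 32×32 mm² FOV,
  256 spectral points over an 8013 Hz width, carrying the bicarbonate and
  CO₂ resonances excited by a two-band pulse (2.78° / 25° nominal tips);
* a 3D pyruvate/lactate magnitude volume, 12×12×16 voxels over 40×40×40 mm³;
* a diffusion-weighted stack at four b-values between 0 and 515 s/mm².

Simulators are deterministic given a seed.  Noise models are the standard
MR ones: circular complex Gaussian noise in k-space for the spectroscopic
acquisition, Rician noise for magnitude volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from scipy import stats

__all__ = [
    "AcquisitionParams",
    "GradeParams",
    "GroundTruthLesion",
    "FidGrid",
    "DwiStack",
    "DEFAULT_GRADE_PARAMS",
    "BACKGROUND_PH",
    "generate_cohort",
    "simulate_csi",
    "simulate_phantom_csi",
    "simulate_grase",
    "simulate_dwi",
    "simulate_expression",
    "make_voxel_table",
    "child_seed",
]

#: pH of non-tumor prostate/stromal background tissue.
BACKGROUND_PH = 7.4
#: ADC of non-tumor background, mm²/s (below the 3.0e-3 free-water cutoff).
BACKGROUND_ADC = 1.8e-3
#: Lac/Pyr of non-tumor background (little LDH flux outside lesions).
BACKGROUND_LACPYR = 0.1

DIFFERENTIATION_CLASSES = ("normal", "well", "moderate", "poor")

GradeLabel = Literal["low", "high"]


def child_seed(seed: int, *path: int) -> int:
    """Deterministically derive a sub-seed below 2**31 from a root seed.

    A single cohort seed fans out to per-lesion and per-acquisition seeds
    so that regenerating one lesion never perturbs another.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(p) for p in path))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass(frozen=True)
class AcquisitionParams:
    """Geometry, timing and noise of the three simulated acquisitions."""

    csi_matrix: tuple[int, int] = (8, 8)
    spectral_points: int = 256
    spectral_width_hz: float = 8013.0
    field_strength_mhz: float = 150.0  # ¹³C Larmor frequency at 14 T
    csi_fov_mm: float = 32.0
    csi_slice_thickness_mm: float = 6.5
    tip_co2_deg: float = 25.0
    tip_bic_deg: float = 2.78
    freq_bic_hz: float = 2000.0
    freq_co2_hz: float = -2000.0
    t2_star_s: float = 0.020
    grase_matrix: tuple[int, int, int] = (12, 12, 16)
    volume_fov_mm: tuple[float, float, float] = (40.0, 40.0, 40.0)
    dwi_matrix: tuple[int, int, int] = (20, 20, 16)
    b_values: tuple[float, ...] = (0.0, 170.0, 340.0, 515.0)
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.csi_matrix + self.grase_matrix + self.dwi_matrix):
            raise ValueError("matrix sizes must be positive")
        if self.spectral_points <= 0:
            raise ValueError("spectral_points must be positive")
        if self.spectral_width_hz <= 0:
            raise ValueError("spectral_width_hz must be positive")
        for tip in (self.tip_co2_deg, self.tip_bic_deg):
            if not 0.0 < tip < 90.0:
                raise ValueError(f"tip angle {tip} outside (0, 90) degrees")
        b = np.asarray(self.b_values, dtype=float)
        if b.size < 2 or b[0] != 0.0 or np.any(np.diff(b) <= 0):
            raise ValueError("b_values must be strictly increasing and start at 0")
        if np.any(b < 0):
            raise ValueError("negative b-values rejected")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @property
    def kappa_ideal(self) -> float:
        """Ideal band excitation ratio sin(tip_co2)/sin(tip_bic)."""
        return math.sin(math.radians(self.tip_co2_deg)) / math.sin(
            math.radians(self.tip_bic_deg)
        )


@dataclass(frozen=True)
class GradeParams:
    """Group-level ground-truth distribution for one histologic grade.

    pH means/SDs and the mean-to-regional-minimum gap default to the
    study-cohort values; Lac/Pyr and ADC group parameters are realistic
    for low- vs high-grade murine prostate tumors (high grade: more
    glycolytic, more cellular hence lower ADC).
    """

    ph_mean: float
    ph_sd: float
    ph_min_gap: float  # lesion regional-minimum pH = mean - gap
    lacpyr_mean: float
    lacpyr_sd: float
    adc_mean: float  # mm²/s
    adc_sd: float
    poor_fraction_range: tuple[float, float]  # histology poorly-diff. fraction


DEFAULT_GRADE_PARAMS: dict[GradeLabel, GradeParams] = {
    "low": GradeParams(
        ph_mean=7.53, ph_sd=0.17, ph_min_gap=0.10,
        lacpyr_mean=0.8, lacpyr_sd=0.30,
        adc_mean=1.35e-3, adc_sd=0.15e-3,
        poor_fraction_range=(0.0, 0.20),
    ),
    "high": GradeParams(
        ph_mean=7.22, ph_sd=0.14, ph_min_gap=0.16,
        lacpyr_mean=2.0, lacpyr_sd=0.60,
        adc_mean=0.80e-3, adc_sd=0.10e-3,
        poor_fraction_range=(0.70, 0.95),
    ),
}


@dataclass
class GroundTruthLesion:
    """One digital lesion with ground truth on every acquisition grid."""

    lesion_id: str
    mouse_id: str
    grade_label: GradeLabel
    center_mm: tuple[float, float]
    radius_mm: float
    ph_field: np.ndarray  # (nx, ny) on the CSI grid, pH units
    lacpyr_field: np.ndarray  # (nx, ny, nz) on the GRASE grid
    adc_field: np.ndarray  # (nx, ny, nz) on the DWI grid, mm²/s
    tumor_fraction: np.ndarray  # (nx, ny) on the CSI grid, [0, 1]
    roi_mask_grase: np.ndarray  # bool, GRASE grid
    roi_mask_dwi: np.ndarray  # bool, DWI grid
    histology_composition: dict[str, float]
    ph_mean: float = 0.0  # realized ROI-mean ground truth
    ph_min: float = 0.0
    lacpyr_roi_mean: float = 0.0
    adc_roi_mean: float = 0.0
    expression: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.ph_field < 6.0) or np.any(self.ph_field > 8.0):
            raise ValueError("ph_field outside [6.0, 8.0]")
        if np.any(self.adc_field <= 0) or np.any(self.adc_field > 3.0e-3):
            raise ValueError("adc_field outside (0, 3.0e-3] mm²/s")
        total = sum(self.histology_composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("histology composition must sum to 1")


@dataclass
class FidGrid:
    """Raw 2D CSI data: complex free-induction decays over (kx, ky, t)."""

    data: np.ndarray  # complex, (nkx, nky, nt)
    params: AcquisitionParams
    reference_frequencies: dict[str, float]  # Hz offsets of each resonance

    def __post_init__(self) -> None:
        nkx, nky = self.params.csi_matrix
        if self.data.shape != (nkx, nky, self.params.spectral_points):
            raise ValueError(
                f"FID data shape {self.data.shape} does not match params "
                f"({nkx}, {nky}, {self.params.spectral_points})"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("FID data must be finite")


@dataclass
class DwiStack:
    """Diffusion-weighted magnitude images, last axis indexes b-values."""

    signal: np.ndarray  # (..., n_b), magnitude
    b_values: np.ndarray  # s/mm², increasing

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=float)
        if self.signal.shape[-1] != self.b_values.size:
            raise ValueError("signal last axis must match number of b-values")
        if np.any(self.b_values < 0):
            raise ValueError("negative b-values rejected")
        if np.any(self.signal < 0):
            raise ValueError("magnitude signal must be non-negative")


# ---------------------------------------------------------------------------
# grid geometry helpers

def grid_centers(n: int, fov: float) -> np.ndarray:
    """Voxel-center coordinates for n voxels spanning [-fov/2, fov/2)."""
    spacing = fov / n
    return -fov / 2.0 + (np.arange(n) + 0.5) * spacing


def _disc_fraction(nx: int, ny: int, fov: float, center: tuple[float, float],
                   radius: float, subsamples: int = 8) -> np.ndarray:
    """Area fraction of each voxel inside a disc, by sub-voxel sampling."""
    spacing = fov / nx
    xc = grid_centers(nx, fov)
    yc = grid_centers(ny, fov)
    off = (np.arange(subsamples) + 0.5) / subsamples - 0.5
    sx = xc[:, None] + off[None, :] * spacing  # (nx, s)
    sy = yc[:, None] + off[None, :] * spacing
    dx2 = (sx[:, None, :, None] - center[0]) ** 2  # (nx, 1, s, 1)
    dy2 = (sy[None, :, None, :] - center[1]) ** 2  # (1, ny, 1, s)
    inside = (dx2 + dy2) <= radius**2
    return inside.mean(axis=(2, 3))


def _ramp(n: int, lo: float, hi: float) -> np.ndarray:
    """n evenly spaced values from lo to hi; mean is (lo+hi)/2 exactly."""
    if n == 1:
        return np.array([(lo + hi) / 2.0])
    return np.linspace(lo, hi, n)


# ---------------------------------------------------------------------------
# cohort generation

def _draw_group_values(rng: np.random.Generator, n: int, mean: float, sd: float,
                       sampling: str) -> np.ndarray:
    """Draw n lesion-level values from N(mean, sd).

    ``sampling="random"`` draws iid; ``sampling="stratified"`` places the
    values at the symmetric quantiles (i+0.5)/n of the group distribution
    (then shuffles), so the realized cohort mean equals the group mean
    exactly -- the right design when the cohort is meant to *represent*
    stated group statistics in a recovery experiment.
    """
    if n == 0:
        return np.empty(0)
    if sampling == "random":
        return rng.normal(mean, sd, size=n)
    if sampling == "stratified":
        q = (np.arange(n) + 0.5) / n
        vals = mean + sd * stats.norm.ppf(q)
        return rng.permutation(vals)
    raise ValueError(f"unknown sampling mode {sampling!r}")


def _build_lesion(idx: int, grade: GradeLabel, ph_mean: float, lacpyr: float,
                  adc: float, params: AcquisitionParams, gp: GradeParams,
                  rng: np.random.Generator) -> GroundTruthLesion:
    nx, ny = params.csi_matrix
    # lesion disc: jittered center near isocenter, radius covering ~12 CSI voxels
    center = (float(rng.uniform(-2.0, 2.0)), float(rng.uniform(-2.0, 2.0)))
    radius = float(rng.uniform(7.5, 9.0))

    frac = _disc_fraction(nx, ny, params.csi_fov_mm, center, radius)
    roi = frac >= 0.5  # voxels counted as tumor at the analysis threshold

    ph_min = ph_mean - gp.ph_min_gap
    ph_field = np.full((nx, ny), BACKGROUND_PH)
    n_roi = int(roi.sum())
    vals = np.clip(_ramp(n_roi, ph_min, 2.0 * ph_mean - ph_min), 6.0, 8.0)
    # order the ramp along a spatial gradient so the minimum is one region
    xc = grid_centers(nx, params.csi_fov_mm)
    yc = grid_centers(ny, params.csi_fov_mm)
    order_key = (xc[:, None] + yc[None, :])[roi]
    ph_roi = np.empty(n_roi)
    ph_roi[np.argsort(order_key)] = vals
    ph_field[roi] = ph_roi

    # GRASE-grid Lac/Pyr cylinder spanning the central slab
    gx, gy, gz = params.grase_matrix
    fovx, fovy, fovz = params.volume_fov_mm
    gfrac = _disc_fraction(gx, gy, fovx, center, radius)
    zc = grid_centers(gz, fovz)
    in_slab = np.abs(zc) <= 10.0  # lesion extends 20 mm axially
    mask_g = (gfrac >= 0.5)[:, :, None] & in_slab[None, None, :]
    lacpyr_field = np.full((gx, gy, gz), BACKGROUND_LACPYR)
    n_g = int(mask_g.sum())
    # anti-aligned with the pH gradient: the acidic pole of the lesion is
    # the high-lactate pole (lactic-acid export drives the acidification)
    xcg = grid_centers(gx, fovx)
    ycg = grid_centers(gy, fovy)
    key_g = np.broadcast_to((xcg[:, None] + ycg[None, :])[:, :, None],
                            (gx, gy, gz))[mask_g]
    vals_g = np.maximum(_ramp(n_g, 1.3 * lacpyr, 0.7 * lacpyr), 0.0)
    lac_roi = np.empty(n_g)
    lac_roi[np.argsort(key_g, kind="stable")] = vals_g
    lacpyr_field[mask_g] = lac_roi

    # DWI-grid ADC cylinder
    dx, dy, dz = params.dwi_matrix
    dfrac = _disc_fraction(dx, dy, fovx, center, radius)
    zc_d = grid_centers(dz, fovz)
    mask_d = (dfrac >= 0.5)[:, :, None] & (np.abs(zc_d) <= 10.0)[None, None, :]
    adc_field = np.full((dx, dy, dz), BACKGROUND_ADC)
    n_d = int(mask_d.sum())
    adc_field[mask_d] = np.clip(_ramp(n_d, 0.9 * adc, 1.1 * adc), 1e-5, 3.0e-3)

    # histology composition straddling the grade cutoff at index 2
    poor = float(rng.uniform(*gp.poor_fraction_range))
    rest = 1.0 - poor
    if grade == "low":
        w = rng.dirichlet([2.0, 3.0, 3.0])  # normal/well/moderate split
        comp = {"normal": rest * w[0], "well": rest * w[1],
                "moderate": rest * w[2], "poor": poor}
    else:
        w = rng.dirichlet([1.0, 1.0, 3.0])
        comp = {"normal": rest * w[0], "well": rest * w[1],
                "moderate": rest * w[2], "poor": poor}
    total = sum(comp.values())
    comp = {k: v / total for k, v in comp.items()}

    lesion = GroundTruthLesion(
        lesion_id=f"L{idx:02d}",
        mouse_id=f"M{idx:02d}",
        grade_label=grade,
        center_mm=center,
        radius_mm=radius,
        ph_field=ph_field,
        lacpyr_field=lacpyr_field,
        adc_field=adc_field,
        tumor_fraction=frac,
        roi_mask_grase=mask_g,
        roi_mask_dwi=mask_d,
        histology_composition=comp,
    )
    lesion.ph_mean = float(ph_field[roi].mean()) if n_roi else float("nan")
    lesion.ph_min = float(ph_field[roi].min()) if n_roi else float("nan")
    lesion.lacpyr_roi_mean = float(lacpyr_field[mask_g].mean()) if n_g else float("nan")
    lesion.adc_roi_mean = float(adc_field[mask_d].mean()) if n_d else float("nan")
    return lesion


def generate_cohort(
    n_low: int,
    n_high: int,
    params: AcquisitionParams | None = None,
    seed: int = 0,
    group_params: Mapping[GradeLabel, GradeParams] = DEFAULT_GRADE_PARAMS,
    sampling: str = "random",
    shared_mice: int = 0,
) -> list[GroundTruthLesion]:
    """Generate a seeded cohort of digital lesions, low grades first.

    Lesion-level pH / Lac/Pyr / ADC are drawn from the per-grade group
    distributions (see :data:`DEFAULT_GRADE_PARAMS`); each lesion is
    assigned its own mouse, except that the first ``shared_mice``
    low-grade lesions share a mouse with a high-grade lesion (animals
    carrying distinctly separate low- and high-grade regions).
    ``sampling`` is ``"random"`` (iid draws) or ``"stratified"``
    (quantile-matched to the group statistics).
    """
    if n_low < 0 or n_high < 0:
        raise ValueError("cohort sizes must be non-negative")
    if shared_mice > min(n_low, n_high):
        raise ValueError("shared_mice cannot exceed either group size")
    params = params or AcquisitionParams()
    lesions: list[GroundTruthLesion] = []
    idx = 0
    for grade, n in (("low", n_low), ("high", n_high)):
        gp = group_params[grade]
        rng = np.random.default_rng(child_seed(seed, 0 if grade == "low" else 1))
        ph_means = _draw_group_values(rng, n, gp.ph_mean, gp.ph_sd, sampling)
        lacs = np.maximum(_draw_group_values(rng, n, gp.lacpyr_mean, gp.lacpyr_sd, sampling), 0.05)
        adcs = np.clip(_draw_group_values(rng, n, gp.adc_mean, gp.adc_sd, sampling),
                       1e-4, 2.7e-3)
        for i in range(n):
            lesion_rng = np.random.default_rng(child_seed(seed, 2, idx))
            ph_i = float(np.clip(ph_means[i], 6.0 + gp.ph_min_gap, 8.0 - gp.ph_min_gap))
            lesions.append(
                _build_lesion(idx, grade, ph_i, float(lacs[i]), float(adcs[i]),
                              params, gp, lesion_rng)
            )
            idx += 1
    for k in range(shared_mice):
        lesions[k].mouse_id = lesions[n_low + k].mouse_id
    return lesions


# ---------------------------------------------------------------------------
# acquisition simulators

def _voxel_fids(amp_bic: np.ndarray, amp_co2: np.ndarray,
                params: AcquisitionParams) -> np.ndarray:
    """Noiseless complex voxel-domain FIDs for two resonances with T2* decay."""
    t = np.arange(params.spectral_points) / params.spectral_width_hz
    decay = np.exp(-t / params.t2_star_s)
    ph_bic = np.exp(2j * np.pi * params.freq_bic_hz * t) * decay
    ph_co2 = np.exp(2j * np.pi * params.freq_co2_hz * t) * decay
    return amp_bic[..., None] * ph_bic + amp_co2[..., None] * ph_co2


def simulate_csi(
    lesion: GroundTruthLesion,
    params: AcquisitionParams | None = None,
    seed: int = 0,
    pka: float = 6.17,
    pool_amplitude: float = 1.0,
    background_amplitude: float = 0.5,
    noise_sigma: float | None = None,
) -> FidGrid:
    """Simulate the two-band bicarbonate/CO₂ 2D CSI acquisition.

    Per voxel the bicarbonate and CO₂ pool sizes satisfy the
    Henderson–Hasselbalch relation B/C = 10**(pH − pKa); the observed
    transverse signals are B·sin(tip_bic) and C·sin(tip_co2) (each band
    tips only its own resonance).  k-space is the 2D DFT of the voxel
    image at every time point, with iid circular complex Gaussian noise
    of per-component sd ``noise_sigma`` added to every k-space sample.
    """
    params = params or AcquisitionParams()
    ph = np.asarray(lesion.ph_field, dtype=float)
    if np.any(ph < 5.0) or np.any(ph > 9.0):
        raise ValueError("pH outside [5, 9] is unphysiological")
    sigma = params.noise_sigma if noise_sigma is None else float(noise_sigma)

    total = np.where(lesion.tumor_fraction >= 0.5, pool_amplitude,
                     background_amplitude)
    ratio = 10.0 ** (ph - pka)  # B/C
    pool_co2 = total / (1.0 + ratio)
    pool_bic = total - pool_co2
    amp_bic = pool_bic * math.sin(math.radians(params.tip_bic_deg))
    amp_co2 = pool_co2 * math.sin(math.radians(params.tip_co2_deg))

    fids = _voxel_fids(amp_bic, amp_co2, params)
    kspace = np.fft.fft2(fids, axes=(0, 1))
    if sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, sigma, size=kspace.shape + (2,))
        kspace = kspace + noise[..., 0] + 1j * noise[..., 1]
    return FidGrid(
        data=kspace,
        params=params,
        reference_frequencies={"bicarbonate": params.freq_bic_hz,
                               "co2": params.freq_co2_hz},
    )


def simulate_phantom_csi(
    params: AcquisitionParams | None = None,
    seed: int = 0,
    pool_amplitude: float = 1.0,
    noise_sigma: float | None = None,
) -> FidGrid:
    """Simulate a uniform phantom in which both bands excite a common pool.

    Models the urea-phantom calibration scan: one chemical pool of unit
    true ratio seen through both excitation bands, so the band-1/band-2
    signal ratio directly measures the excitation ratio κ.
    """
    params = params or AcquisitionParams()
    sigma = params.noise_sigma if noise_sigma is None else float(noise_sigma)
    nx, ny = params.csi_matrix
    pool = np.full((nx, ny), pool_amplitude)
    amp_bic = pool * math.sin(math.radians(params.tip_bic_deg))
    amp_co2 = pool * math.sin(math.radians(params.tip_co2_deg))
    fids = _voxel_fids(amp_bic, amp_co2, params)
    kspace = np.fft.fft2(fids, axes=(0, 1))
    if sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, sigma, size=kspace.shape + (2,))
        kspace = kspace + noise[..., 0] + 1j * noise[..., 1]
    return FidGrid(
        data=kspace,
        params=params,
        reference_frequencies={"bicarbonate": params.freq_bic_hz,
                               "co2": params.freq_co2_hz},
    )


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return signal.copy()
    re = signal + rng.normal(0.0, sigma, size=signal.shape)
    im = rng.normal(0.0, sigma, size=signal.shape)
    return np.hypot(re, im)


def simulate_grase(
    lesion: GroundTruthLesion,
    params: AcquisitionParams | None = None,
    seed: int = 0,
    s0_pyruvate: float = 100.0,
    background_pyruvate: float = 100.0,
    body_radius_mm: float = 16.0,
    noise_sigma: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate 3D pyruvate and lactate magnitude volumes with Rician noise.

    Noiselessly the lactate/pyruvate voxel ratio equals the ground-truth
    ``lacpyr_field``.  Pyruvate models delivery: uniform across the
    animal's body by default (lesion conspicuity lives in the lactate
    channel) and zero outside it, so the FOV corners are signal-free and
    usable for noise estimation.
    """
    params = params or AcquisitionParams()
    if np.any(lesion.lacpyr_field < 0):
        raise ValueError("negative Lac/Pyr ratio field rejected")
    sigma = params.noise_sigma if noise_sigma is None else float(noise_sigma)
    gx, gy, _ = params.grase_matrix
    xc = grid_centers(gx, params.volume_fov_mm[0])
    yc = grid_centers(gy, params.volume_fov_mm[1])
    body = (np.hypot(xc[:, None], yc[None, :]) <= body_radius_mm)[:, :, None]
    pyr = np.where(lesion.roi_mask_grase, s0_pyruvate,
                   np.where(body, background_pyruvate, 0.0)).astype(float)
    lac = pyr * lesion.lacpyr_field
    rng = np.random.default_rng(seed)
    return _rician(pyr, sigma, rng), _rician(lac, sigma, rng)


def simulate_dwi(
    lesion: GroundTruthLesion,
    s0: float = 1000.0,
    params: AcquisitionParams | None = None,
    seed: int = 0,
    noise_sigma: float | None = None,
) -> DwiStack:
    """Simulate the diffusion-weighted stack: S(b) = S0·exp(−b·ADC) + noise."""
    params = params or AcquisitionParams()
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    sigma = params.noise_sigma if noise_sigma is None else float(noise_sigma)
    b = np.asarray(params.b_values, dtype=float)
    clean = s0 * np.exp(-b[None, None, None, :] * lesion.adc_field[..., None])
    rng = np.random.default_rng(seed)
    return DwiStack(signal=_rician(clean, sigma, rng), b_values=b)


DEFAULT_EXPRESSION_PARAMS: dict[str, dict[GradeLabel, float]] = {
    # grade-level mean expression relative to housekeeping = 1.0
    "Ldha": {"low": 1.2, "high": 1.8},
    "Mct1": {"low": 1.0, "high": 1.5},
    "Hif1a": {"low": 1.0, "high": 2.0},
}


def simulate_expression(
    lesion: GroundTruthLesion,
    seed: int = 0,
    noise_sd: float = 0.25,
    mct4_scale: float = 2.0,
    mct4_ph_slope: float = 1.5,
    mct4_ph_ref: float = 7.3,
) -> dict[str, float]:
    """Simulate qRT-PCR expression normalized to a housekeeping gene.

    Mct4 (the lactic-acid exporter) decreases monotonically with the
    lesion's mean extracellular pH: Mct4 = scale·10**(−slope·(pH − ref)),
    times log-normal noise.  Ldha/Mct1/Hif1a are elevated in high-grade
    lesions.  With ``noise_sd=0`` the pH→Mct4 map is strictly monotone.
    """
    if not np.isfinite(lesion.ph_mean):
        raise ValueError("lesion must have a defined mean pH")
    rng = np.random.default_rng(seed)
    expr: dict[str, float] = {}
    mct4 = mct4_scale * 10.0 ** (-mct4_ph_slope * (lesion.ph_mean - mct4_ph_ref))
    expr["Mct4"] = float(mct4 * np.exp(rng.normal(0.0, noise_sd)))
    for gene, levels in DEFAULT_EXPRESSION_PARAMS.items():
        expr[gene] = float(levels[lesion.grade_label] * np.exp(rng.normal(0.0, noise_sd)))
    lesion.expression = expr
    return expr


def make_voxel_table(
    n_voxels: int = 153,
    n_lesions: int = 12,
    n_mice: int = 10,
    slope: float = -0.151,
    intercept: float = 7.5,
    lesion_sd: float = 0.10,
    mouse_sd: float = 0.0,
    resid_sd: float = 0.05,
    lacpyr_range: tuple[float, float] = (0.0, 3.0),
    seed: int = 42,
):
    """Synthetic voxel-level (mouse, lesion, pH, Lac/Pyr) long table.

    pH is linear in Lac/Pyr with random intercepts per lesion (nested in
    mouse) plus iid residual noise -- the generative model matched by the
    mixed-effects fit.  Lesions are dealt to mice round-robin, so some
    mice carry two lesions as in a cohort with mixed-grade animals.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    lesion_of_voxel = np.sort(rng.integers(0, n_lesions, size=n_voxels))
    # ensure every lesion appears at least once
    lesion_of_voxel[:n_lesions] = np.arange(n_lesions)
    mouse_of_lesion = np.arange(n_lesions) % n_mice
    lesion_eff = rng.normal(0.0, lesion_sd, size=n_lesions)
    mouse_eff = rng.normal(0.0, mouse_sd, size=n_mice) if mouse_sd > 0 else np.zeros(n_mice)
    lacpyr = rng.uniform(*lacpyr_range, size=n_voxels)
    ph = (
        intercept
        + slope * lacpyr
        + lesion_eff[lesion_of_voxel]
        + mouse_eff[mouse_of_lesion[lesion_of_voxel]]
        + rng.normal(0.0, resid_sd, size=n_voxels)
    )
    return pd.DataFrame(
        {
            "mouse_id": [f"M{m:02d}" for m in mouse_of_lesion[lesion_of_voxel]],
            "lesion_id": [f"L{l:02d}" for l in lesion_of_voxel],
            "voxel_id": np.arange(n_voxels),
            "ph": ph,
            "lacpyr": lacpyr,
        }
    )
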