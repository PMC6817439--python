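# Methods

This note records the models, parameter choices and numerical decisions
behind `hyperph`, and what the synthetic-cohort tests do and do not
demonstrate about real data.

## The measurement model

### Bicarbonate/CO₂ pH imaging

Each CSI voxel holds a bicarbonate pool B and a CO₂ pool C in chemical
exchange; at equilibrium their ratio encodes extracellular pH through
Henderson–Hasselbalch, B/C = 10^(pH − pKa).  The two-band excitation tips
CO₂ by 25° and bicarbonate by only 2.78°, so the observed transverse
signals are S_bic = B·sin(2.78°) and S_CO2 = C·sin(25°), and the pH
estimate multiplies the signal ratio by the band excitation ratio
κ = sin(25°)/sin(2.78°) ≈ 8.714 before the logarithm.  κ is taken from a
phantom calibration when one is supplied (both bands exciting a common
pool, so the measured band ratio is κ itself); otherwise the ideal sine
ratio is used.

* **pKa = 6.17** (default, configurable).  The physiological
  bicarbonate/CO₂ pKa at 37 °C used throughout the hyperpolarized
  bicarbonate literature.  Reported in every map's sidecar because pH
  values shift one-for-one with it.
* **SNR mask**: voxels need both metabolites at SNR ≥ 3; the QC mask
  distinguishes which species failed (CO₂, the ~9×-smaller signal,
  dominates failures).
* **Exchange timing**: a first-order approach to equilibrium at the
  measured rate k = 1.56 s⁻¹ reaches a fraction f at t = −ln(1−f)/k;
  95% in ≈ 1.9 s, fast relative to acquisition, which is what licenses
  the equilibrium pH interpretation.

### Spectral processing

Reconstruction is the exact inverse of Cartesian phase encoding (2D
spatial inverse DFT; centric ordering is metadata only, and RF/T₁
depletion across the ~4 s encoding train is not modeled), followed by
exponential apodization exp(−π·lb·t) with lb = 10 Hz default and a
spectral FFT.  Bicarbonate and CO₂ sit at ±2000 Hz (only their
separation matters; 4000 Hz is well resolved within the 8013 Hz width),
T₂* = 20 ms, giving ~26 Hz apodized linewidths.  Peak integrals sum
magnitude over ±150 Hz half-open windows.

Two optional integral corrections exist, used where each matters:

* **Power-domain Rician correction** (in-vivo path): magnitude spectra
  of noisy data carry a positive noise floor; each point is replaced by
  sqrt(max(|X|² − 2σ², 0)) with σ the pooled robust noise estimate.  At
  the working SNR this reduces the ROI-mean pH bias from ≈ −0.01/+0.04
  (uncorrected / naively floor-subtracted) to ≈ +0.001.
* **Edge-baseline subtraction** (phantom path): the magnitude tail of a
  distant strong peak decays only as 1/Δf and contributes ~5% to the
  weak-band window when band amplitudes differ ~9×; a per-voxel flat
  baseline from flanking guard bands removes it (κ error 0.7% instead
  of 5%).  Not used in vivo, where amplitude asymmetry is mild and the
  guard bands are noise-dominated.

Noise is estimated from the outer 10% of the spectral axis, pooled over
voxels, as MAD×1.4826 of the magnitude converted to the Gaussian
per-component σ through the Rayleigh MAD constant (0.66488).

### Lac/Pyr and ADC

Metabolite volumes are collapsed to the CSI slab by unweighted averaging
of slices whose centers fall in the half-open slab interval, regridded
in-plane by Fourier zero-filling (scipy's resampler; exactly
signal-conserving because the DC coefficient is preserved) and cropped
to the common 32 mm FOV on voxel centers.  The ratio applies the
asymmetric rules: lactate SNR < 4 masks the voxel; pyruvate SNR < 4
replaces the denominator with the mean noise magnitude
(Rayleigh mean σ√(π/2)), estimated from the signal-free corners of the
volume — this bounds ratios without discarding high-lactate voxels.

ADC is fit per voxel by weighted log-linear least squares (weights ∝ S²,
emulating signal-domain least squares in closed form; a brute-force
grid-search oracle in the tests guards the approximation to 1%).  RMS
residuals are computed in the signal domain.  Exclusions are strict
inequalities — residual > 500 (scanner arbitrary units; the synthetic
scale S₀ = 1000 makes the limit directly applicable) or
ADC > 3.0×10⁻³ mm²/s, free water at 37 °C — so boundary voxels survive.

### Grading and statistics

Histologic index = 0·f_normal + 1·f_well + 2·f_moderate + 3·f_poor,
dichotomized at 2 (low ≤ 2 < high).  Tumor voxels require ≥ 50% tumor
content (inclusive).  Group tests are two-sided throughout and
uncorrected for multiplicity (p < 0.05 convention): Mann–Whitney U with
full label-assignment enumeration for pooled n ≤ 12 (ties handled
exactly; average ranks), normal approximation with tie correction above;
Spearman with permutation p for n ≤ 10, t approximation above; Cohen's d
with the pooled-SD formula.  The voxelwise model is
pH ~ 1 + Lac/Pyr with a random intercept per mouse and a variance
component for lesion nested in mouse, fit by REML (statsmodels MixedLM).
The paper-gap choice of *nested* rather than crossed intercepts is a
config switch; degenerate fits (single lesion, zero variance, singular
designs) fall back to OLS and carry a flag rather than raising.  The
per-mouse sensitivity analysis keeps one lesion per mouse, by default
the one with the most pH voxels.

## The digital cohort

The generator is the package's verification instrument: it plants known
truth and the pipeline must return it.

* **Geometry**: each lesion is a disc (radius 7.5–9 mm, jittered center)
  near the isocenter of the 32 mm CSI FOV, extended 20 mm axially on the
  volume grids; tumor fraction per CSI voxel is computed by 8×8
  sub-voxel sampling.  The body is a 16 mm-radius disc; outside it the
  metabolite volumes are signal-free, which is what makes corner noise
  estimation possible.
* **pH**: lesion ROI values form a linear ramp ordered along a spatial
  gradient, constructed so the realized ROI mean and minimum equal the
  planted lesion-level values exactly; background tissue sits at 7.4.
  Group defaults are the reported cohort statistics: low grade
  7.53 ± 0.17 with regional minimum 0.10 below the mean, high grade
  7.22 ± 0.14 with minimum 0.16 below (the reported mean-to-minimum
  gaps).
* **Lac/Pyr and ADC**: no numeric group statistics are reported for
  these modalities, so defaults are chosen once as realistic for the
  model system — Lac/Pyr 0.8 ± 0.3 (low) vs 2.0 ± 0.6 (high), spanning
  the 0–3 range the voxelwise analysis uses; ADC 1.35 ± 0.15 vs
  0.80 ± 0.10 ×10⁻³ mm²/s (high-grade tumors are more cellular, hence
  lower ADC; both far below the 3.0×10⁻³ free-water cutoff).  The
  within-lesion Lac/Pyr gradient is anti-aligned with the pH gradient
  (the acidic pole is the high-lactate pole), so voxelwise tables carry
  the negative association the analysis is built to detect.
* **Histology**: low-grade compositions draw the poorly-differentiated
  fraction from [0, 0.20], high-grade from [0.70, 0.95], so indices
  straddle the cutoff at 2 with margin.
* **Expression**: Mct4 = 2.0·10^(−1.5·(pH−7.3)) times log-normal noise —
  strictly decreasing in lesion-mean pH — with Ldha/Mct1/Hif1α elevated
  in high grade; all relative to a housekeeping level of 1.
* **Sampling modes**: lesion-level values are drawn iid
  (`sampling="random"`) or at symmetric quantiles of the group
  distribution (`"stratified"`).  Stratified cohorts realize the group
  mean exactly and are used for parameter-recovery experiments, where
  the question is whether the *pipeline* returns the planted statistics,
  not whether a 5-lesion sample resembles its population.  Monte-Carlo
  experiments (effect sizes) use iid draws.
* **Noise calibration**: the k-space σ needed for a requested minimum
  CO₂ peak-integral SNR follows in closed form from the FFT
  normalizations and apodization weights (`csi_noise_sigma_for_snr`);
  recovery experiments run at minimum CO₂ SNR 20.
* **Seeding**: one root seed fans out to per-grade, per-lesion and
  per-acquisition seeds through `numpy.random.SeedSequence` spawn keys
  (`child_seed`), so outputs are bit-reproducible and regenerating one
  lesion never perturbs another.

## Problem sizes

The recovery experiments use the study's own dimensions: 5 + 7 lesions
on the 8×8×256 CSI grid, 153 voxels / 12 lesions / 10 mice for the mixed
model, 200 replicate cohorts for effect-size and coverage Monte Carlo.
The full test suite and the acceptance script each run in well under a
minute of compute on one core.

## What the synthetic tests do not show

The generator emulates grid geometry, pool physics, excitation
asymmetry, exchange-equilibrated ratios and standard MR noise.  It does
not emulate: B₀ inhomogeneity or phase errors; signal depletion across
the centric encoding train; perfusion, injection kinetics or T₁ decay of
the hyperpolarized magnetization; partial blood/intracellular
compartments (so the measured quantity is treated as extracellular pH
as-is); motion or eddy currents in DWI; or histology-to-imaging
registration error (region assignment is taken as given).  Passing
recovery tests therefore demonstrates correctness of the processing
rules and statistics under the stated physics, not robustness to these
real-world confounds.

Two numerical limits are worth knowing.  First, pointwise recovery of a
lesion only ~2.5 native voxels in radius on the 2 mm regridded Lac/Pyr
grid is resolution-limited: band-limited interpolation of such a
structure deviates from the continuous truth by ~10% near the lesion
profile's transition regardless of pipeline correctness, so the
noiseless-recovery guarantee is stated (and tested, at machine
precision) on the native acquisition grid, while the regridding step is
separately verified against an explicit zero-padded-DFT oracle.  Second,
magnitude-mode peak integration is biased at finite SNR; the corrections
above reduce the residual ROI-mean pH bias to ≈ 0.001–0.02 depending on
statistic (minima are noise-biased downward by ~0.02 at SNR 20), which
is why the regional-minimum recovery tolerance is wider than the mean's.
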