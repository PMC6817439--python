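# hyperph

Analysis pipeline for multiparametric hyperpolarized ¹³C MRI of prostate
cancer, verified end to end on a synthetic "digital mouse" cohort.

Aggressive prostate tumors acidify their extracellular space: glycolytic
cells export lactic acid through the MCT4 transporter, and the resulting
drop in extracellular pH (pH_e) is a candidate imaging biomarker for
separating indolent from aggressive disease.  Hyperpolarized
[¹³C] bicarbonate MRI measures pH_e voxel by voxel through the
bicarbonate/CO₂ buffer equilibrium, while hyperpolarized [1-¹³C] pyruvate
MRI measures the lactate-to-pyruvate conversion in the same session, and
¹H diffusion-weighted imaging adds cellularity (ADC).  This package
implements the full analysis chain for such an experiment — for imaging
scientists who want every processing rule tested against planted ground
truth before it ever touches animal data.

## What it computes

**Spectroscopic pH mapping.**  A 2D CSI acquisition (8×8 voxels, 256
spectral points over 8013 Hz) carries the bicarbonate and CO₂ resonances,
excited by a two-band pulse at nominal tips of 2.78° and 25° so the large
bicarbonate pool is spared.  After spatial/spectral reconstruction and
magnitude peak integration, pH follows the excitation-ratio-corrected
Henderson–Hasselbalch equation

    pH = pKa + log10( (S_bic / S_CO2) · κ ),    κ = sin(25°)/sin(2.78°) ≈ 8.71,

with κ measurable from a urea phantom in which both bands see a common
pool.  Voxels with either metabolite below SNR 3 are masked.

**Lac/Pyr mapping.**  Pyruvate/lactate 3D volumes (12×12×16 over
40×40×40 mm³) are slab-averaged to the CSI slice, Fourier-regridded to a
common 2×2 mm² grid, and divided under asymmetric SNR rules: lactate
voxels below SNR 4 are excluded, pyruvate voxels below SNR 4 are replaced
by the mean noise magnitude.

**ADC mapping.**  Voxelwise mono-exponential fits S(b) = S₀·exp(−b·ADC)
over four b-values in [0, 515] s/mm², with exclusion of voxels whose RMS
residual exceeds 500 (scanner units) or whose ADC exceeds the free-water
value 3.0×10⁻³ mm²/s.

**Grading and statistics.**  Histology compositions over
{normal, well, moderately, poorly differentiated} are collapsed to the
0–3 histologic index (weighted sum), dichotomized at 2 into low/high
grade.  Group comparisons use exact Mann–Whitney U tests (full
enumeration for pooled n ≤ 12), Spearman correlations (permutation p for
n ≤ 10), Cohen's d with pooled SD, and a linear mixed-effects model
pH ~ Lac/Pyr with random intercepts for mouse and lesion-within-mouse
(REML).

**Synthetic cohort.**  `hyperph.cohort` generates seeded digital lesions
with known pH / Lac/Pyr / ADC / histology / expression ground truth and
simulates all three acquisitions (complex Gaussian k-space noise for CSI,
Rician noise for magnitude volumes), so every stage above is testable
as a recovery problem.

## Worked example

```python
from hyperph.pipeline import run_cohort
from hyperph.stats import write_report

table = run_cohort(n_low=5, n_high=7, seed=11)   # full 12-lesion study
report = write_report(table, "report/")
```

With seed 11 this prints (via `report["group_comparisons"]` and
`report["mixed_model"]`):

```
mean pH   : low 7.442, high 7.256,  Mann–Whitney p = 0.0303, d = 1.42
min pH    : p = 0.0101, d = 1.94
mean Lac/Pyr: p = 0.0051, d = −2.14
mean ADC  : p = 0.0025, d = 4.69
voxelwise slope: −0.159 pH per unit Lac/Pyr (n = 150 voxels, p ≈ 3e−38)
Spearman(mean pH, Mct4) = −0.937
```

Read: the high-grade group is more acidic, more glycolytic and more
cellular than the low-grade group; voxelwise, pH falls by ≈ 0.16 per unit
Lac/Pyr; and lesion-mean pH is strongly anticorrelated with expression of
the lactic-acid exporter Mct4.  The same pipeline accepts real data
through the NIfTI loaders in `hyperph.io` and the `hyperph` CLI
(`simulate`, `phmap`, `analyze`).

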