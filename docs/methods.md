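# Methods

This note documents the models, numerical choices and limitations behind
`neomrs`. The study design it targets is a neonatal (postnatal day 0)
rabbit cohort at 7 T: six controls and five growth-restricted newborns
from three litters, each scanned with a short-TE PRESS voxel (TR 2500 ms,
TE 12 ms, 256 averages + 4 dummy scans, 650 s per scan) in cortex
(1.3×2.0×4.0 mm), hippocampus (1.6×4.3×1.5 mm) and striatum
(2.1×1.4×3.6 mm), with an 8-average unsuppressed water reference per
voxel.

## Spectrum model and synthetic data

Spectra live on a fixed acquisition grid (transmitter 300.3 MHz, spectral
width 4200 Hz, 2048 points, carrier at 4.7 ppm; ascending ppm axis). Every
resonance is synthesized in closed form in the frequency domain: metabolite
lines are complex Lorentzians (absorption + dispersion of a causal decaying
FID), macromolecule components are complex Gaussians evaluated through the
Faddeeva function, and extra Lorentzian damping is applied analytically
(Lorentzian convolution adds widths; Gaussians become Voigt profiles).
Because synthesis is closed-form, the fitter can evaluate the identical
model under trial shift/damping values with no interpolation error.

**Metabolite inventory.** 25 brain metabolites ship as a TSV of simplified
line lists (singlet/multiplet centroid positions with relative proton
amplitudes, compiled from standard brain-metabolite literature). J-coupling
evolution at TE 12 ms is approximated by static line lists; no
density-matrix simulation is attempted, because the package's test surface
is fit-recovery, not spectral realism at the J-evolution level. Line areas
are proportional to proton counts, so a unit basis amplitude corresponds to
one concentration unit.

**Baseline concentrations** (µmol/g) are plausible neonatal-brain defaults;
the only externally anchored values are the total creatine pools — cortex
3.0 and striatum 3.9 µmol/g, the ex-vivo reference concentrations the
water-scaled quantification is checked against (hippocampus, not reported,
is set to 3.4).

**Group effects.** The effect table stores the published relative changes
per (metabolite, region) — e.g. cortical aspartate −41.6 %, striatal
glycine +34.2 %. The published table also contains two pooled rows
(NAA+NAAG, myo-inositol+glycine); since the generator needs per-metabolite
multipliers, the NAAG and myo-inositol defaults are solved algebraically so
that the pooled group changes match the printed values under the default
baselines.

**Between-subject variability** is multiplicative log-normal noise on each
concentration with a 10 % coefficient of variation (a free parameter of
the design: only group-level means/SDs of derived quantities are published,
never the underlying concentration variance). Temperatures, birth weights,
placental weights and brain volumes are drawn from the published group
means ± SD. Litters follow the study's 2+2+2 / 2+2+1 pattern; the
neighbor-stillbirth covariate is Poisson(0.8), independent of group.

**Noise and lineshape calibration.** Per spectrum, the target linewidth is
drawn around 10.1 Hz (SD 0.8 Hz) and the target total-choline SNR around
47.7 (SD 5); complex white Gaussian noise is scaled so the noiseless
choline peak height over the injected noise SD equals the target. The
choline height definition (magnitude peak above a locally interpolated
flank-median baseline) is shared between the generator and the QC metric,
making the calibration self-consistent and phase-invariant. The
between-subject SDs are deliberately smaller than the published
cross-animal SDs (12.6 for SNR, 2.7 Hz for FWHM) so that the generator's
mean stays within the package's own calibration bands; the published SDs
mix hardware and physiological variation the simulator does not model.

**Residual water.** Water suppression is partial (the in-vivo sequence
leaves a usable residual line): the water line is placed at
`Dist(T)` ppm above the *measured* total-choline magnitude peak of the
simulated spectrum, with height 5× the tallest metabolite peak. Anchoring
to the measured peak rather than the nominal 3.21 ppm matters: the choline
maximum is pulled ~0.0015 ppm by neighboring resonances, and the
temperature calibration is defined on the measured peak distance — anchoring
nominally would bias every round trip by ~0.12 °C. Two fixed-point
iterations re-anchor the water position because the water dispersion tail
itself shifts the measured choline maximum slightly. The water reference
encodes the tissue water pool (0.80 g water/g tissue × 55 510 µmol/g)
attenuated by `exp(−TE/T2)` with T2 = 158 ms, which is exactly what the
absolute-quantification correction later undoes.

## Thermometry

`T(°C) = −82.33·(Dist + 1.21) + 255.94`, with `Dist = ppm(water) −
ppm(choline)` (positive, ≈1.5 ppm physiologically). Peaks are picked on
the magnitude spectrum — the paper trail gives no algorithm, and magnitude
picking is robust to phase — and refined by a 3-point parabola fitted to
the *reciprocal squared* magnitude: for a Lorentzian, 1/|S|² is exactly
quadratic in frequency, so the refinement is exact for an isolated line at
any sub-grid offset (a plain parabola on the magnitude leaves a
grid-offset-dependent bias of up to ~grid/10). Ties break toward the
lower-ppm maximum. Both peaks must rise at least 3 noise SDs above the
window's median magnitude (the median subtraction stops the extreme-value
statistics of pure noise from faking a peak); otherwise a low-confidence
error reports both peak SNRs. The estimate is invariant to global
intensity scaling and zero-order phase.

## Linear-combination quantification

Over the 0.5–4.25 ppm window the complex data are modeled as
`exp(iφ)·Σ c_m B_m(δ, γ) + baseline`, with non-negative amplitudes for the
25 metabolites and 11 macromolecule Gaussians (positions fixed at 3.0,
2.8, 2.25, 2.05, 1.95, 1.67, 1.4, 1.3, 1.2, 0.9, 0.85 ppm; width 0.15 ppm
by default), a Chebyshev baseline of order 4 per channel (an order-4
polynomial rather than a regularized spline: simpler, testable, adequate
for the synthetic baselines; configurable), and three global nuisances —
frequency shift δ (±0.1 ppm), zero-order phase φ (±30°) and extra
Lorentzian damping γ (0–15 Hz), bounded to prevent basis-swapping
degeneracies. A residual-water Lorentzian at the water line's measured
position is included as an extra non-negative component by default; without
it the one-signed water dispersion tail leaking into the window biases the
nuisance estimates and, through them, overlapped metabolites by a few
percent.

The inner amplitude/baseline problem is solved exactly as a non-negative
least squares (free baseline coefficients are split into ± parts); the
outer nuisance search uses bounded Powell iterations on the profiled
residual. On noiseless representable data the fit recovers amplitudes to
&lt;10⁻⁵ relative error.

**CRLBs** come from `100·σ·sqrt([(JᵀJ)⁻¹]_mm)/c_m`, with J the Jacobian of
the full model (amplitudes, baseline coefficients, three nuisances;
real/imag channels stacked) and σ the noise SD estimated from the
signal-free −2.0 to −0.5 ppm region unless supplied. A singular
information matrix or zero amplitude yields +∞, never a crash. Metabolites
with CRLB &lt; 50 % are retained for analysis. Monte-Carlo calibration at
the default SNR shows empirical amplitude CVs tracking the reported CRLBs
closely for well-determined metabolites; strongly overlapped pairs
(GPC/phosphocholine) scatter more than their bound, as expected for a
lower bound under a non-negativity constraint.

**Absolute scaling.** The water reference is fitted as a single complex
Lorentzian (area, position, width, phase). Then
`conc(m) = (A_m / A_w_corr)·(2/protons_m)·molality` with
`A_m = amplitude × proton count` (the basis is proton-normalized),
`A_w_corr = A_w / exp(−TE/T2_water)`, T2 = 158 ms, and molality
0.80×55 510 µmol water per g tissue. The 0.80 g/g water content is a
plausible neonatal-brain assumption exposed as configuration — the
analysis chain it reproduces does not state its value. T1 saturation is
deliberately *not* corrected (the short TR induces some saturation; the
group contrast is unaffected). QC metrics: water FWHM at half maximum with
linear interpolation on the autophased absorption channel (a pure
Lorentzian with FID damping R s⁻¹ measures R/π Hz), and total-choline SNR
as described above.

## Volumetry

Region volumes are voxel counts × voxel volume; "brain" aggregates all
non-background, non-CSF labels, and label groupings (cortex = its four
sub-regions, basal ganglia = striatum + thalamus) are configurable. The
MRS voxel's tissue composition is computed analytically: voxel and atlas
cells are axis-aligned boxes, so each overlap factors into three 1-D
interval overlaps — exact, with fractions summing to 100 % by
construction (nearest-neighbour assignment was rejected because it cannot
be oracle-checked to sub-percent accuracy).

The brain phantom realizes per-label volume targets as successive shells
of a normalized ellipsoidal radius field (semi-axis ratios 1.25 : 1 : 0.8),
with shell boundaries placed by voxel *rank* so each label's rasterized
volume matches its target to within one voxel at any feasible resolution;
a positive target below 8 voxels raises a resolution error. Default
targets follow the published control volumes (brain 1335.5 mm³, cortex
476.2, hippocampus 173.3, striatum 179.6), with the cortex split and the
non-tabulated tissues (thalamus, white matter, CSF, remainder) as package
defaults; per-subject phantoms scale all targets by the subject's drawn
brain volume. MRS voxels are placed on the +x ray through the phantom
centre at each region's radial midpoint, which produces realistic 50–85 %
tissue fractions.

## Spectral-pattern classification

Preprocessing: zero-order autophase (closed form: the real-channel
integral over the window is maximal at the phase of the complex sum), 4 Hz
Lorentzian apodization applied through an FFT round trip, linear baseline
through the medians of the 4.20–4.25 and 0.50–0.55 ppm flanks, grid shift
placing the choline maximum at 3.21 ppm, resampling of 4.25–0.5 ppm to 512
points (the original point count is unstated; 512 preserves the ~2 Hz
native resolution), and unit-norm (UL2) scaling. Subjects' region vectors
are concatenated cortex-first (cortex+hippocampus or cortex+striatum,
1024 features).

Feature selection is sequential forward floating selection: the criterion
is leave-one-out LDA accuracy on the candidate set, ties broken by the
larger Fisher criterion `dᵀS_w⁻¹d`, then by lower feature indices — fully
deterministic. The floating search explores two sizes past the target and
keeps the best subset recorded per size. When the whole subset space is
small (≤600 candidate sets) the criterion optimum is found exactly by
enumeration instead; the greedy path exists only because enumeration is
infeasible at 1024 features. The LOO evaluations are batched with
closed-form leave-one-out updates of class sums and scatter matrices, so a
bootstrap repetition costs milliseconds.

The Fisher discriminant is `w ∝ S_w⁻¹(μ₁−μ₀)` with the boundary at the
midpoint of the projected class means; a ridge `ε·I` (ε = 10⁻⁶·trace/d) is
added with a warning when the pooled scatter is singular. The 2-D latent
space pairs the discriminant score with the leading principal direction of
the within-class residual orthogonal to `w`; sign conventions (control
mean non-negative on axis 1, largest PC component positive) make the
projection order-invariant.

Bootstrap evaluation resamples subjects with replacement, stratified by
class, re-runs feature selection on each resample (the honest variant;
`freeze_features=True` reproduces the optimistic variant with the
full-data selection), trains the LDA, and scores the out-of-bag subjects;
repetitions with an empty out-of-bag set are skipped and counted. 1000
repetitions by default, fully seed-deterministic.

On cohorts generated at the default 10 % concentration CV the first
selected feature falls in the cortex segment in only a minority-to-half of
seeds (when it does, it tends to land in the 3.5 ppm
glycine/myo-inositol region): with 11 subjects and 1024 candidate
features, chance features compete strongly against the small injected
group effects, and out-of-bag accuracies sit near chance. This is a
property of the synthetic effect sizes, not of the selector — with
strongly separated synthetic classes the same code reaches ≥95 % accuracy.

## Group statistics

Per cell: Shapiro-Wilk on each group at α = 0.05; both normal → two-tailed
unpaired equal-variance t-test (Welch available by flag), else
Mann-Whitney U (exact for n ≤ 8 without ties, midrank ties otherwise).
Percent change is `100·(mean_IUGR − mean_control)/mean_control`. Pooled
rows (NAA+NAAG, myo-inositol+glycine) sum member concentrations per
subject before comparison, and a subject enters a pooled cell only when
every member passed the CRLB filter there; a cell needs ≥3 subjects per
group, else it is marked not-evaluable. The GLM is OLS on [intercept,
group, covariates], with brain temperature and voxel tissue fraction as
primary confounders and litter (as fixed indicator columns) plus
neighbor-stillbirth count in the secondary model; the group coefficient's
t-statistic supplies the adjusted p. No multiple-testing correction by
default (18 cells at raw α = 0.05); Benjamini-Hochberg is available as a
flag.

A note on power under the default design: several injected effects are
tiny (glutamate striatum +0.6 %, glycine hippocampus −2.7 %,
myo-inositol+glycine hippocampus +1.5 %) while the sampling SD of a
percent change at n = 6/5 and 10 % CV is ≈6 percentage points, so the
*sign* of such cells is close to a coin flip in any single cohort; across
many cohorts the expected sign-recovery rate over all 18 cells is ≈87 %,
with the shortfall concentrated entirely in those near-zero cells. The
large published effects (|change| ≥ 14 %) recover their sign essentially
always, and the cortical aspartate drop reaches significance in well over
80 % of seeds.

## Pipeline

One validated config (unknown keys rejected) drives simulate → quantify →
thermometry → volumetry → classify → statistics. A single global seed fans
out to per-stage child seeds by stable SHA-256 hashing of the stage name,
so stages are independently reproducible; re-running a config reproduces
every numeric output byte-for-byte. Outputs: per-subject quantification
CSVs, temperature, volumetry and QC tables, classification report with
latent coordinates, cohort-level and effect-table summaries with
significance stars, and a manifest (seed, config hash, versions). Stage
failures abort with the stage name and offending subject/region.

## Problem sizes used in the automated checks

Thermometry uses 4 noiseless temperatures plus 20 noisy repeats; the
quantification Monte-Carlo uses 200 spectra; feature-selection/exhaustive
agreement uses 50 random datasets; bootstrap sanity uses 1000 repetitions;
voxel composition is checked against a 10× supersampled rasterization on
100 random geometries; effect-table recovery uses four effect cohorts and
two null cohorts through the full quantification chain. These sizes give
stable estimates of each property while keeping a full run in the
minutes range on a single CPU.

## Known limitations

* Static line lists: no J-evolution, no TE/TR relaxation weighting of
  metabolites; absolute concentrations are exact only because generator
  and fitter share conventions — on real data, metabolite T2/T1 correction
  (deliberately omitted) would matter.
* The phantom geometry is concentric shells, not anatomy; voxel tissue
  fractions are realistic in magnitude but not in spatial detail.
* No eddy-current, lineshape-distortion or frequency-drift artifacts; the
  autophase stand-in replaces the original interactive phase correction.
* The bootstrap re-selects features per resample; published accuracies of
  the original pipeline may correspond to the optimistic frozen-feature
  variant, which is provided behind a flag.
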