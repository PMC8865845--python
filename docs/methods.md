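# Methods

## The measurement problem

A genotyping array reports, per probe and sample, the log2 ratio
`L2R = log2(observed / expected)` of hybridization intensity, where the
expected intensity is the genotype-cluster median for that probe. Deviations
of L2R from zero track DNA quantity, so the ~hundreds of mitochondrial
probes on a modern array carry a relative mtDNA copy-number signal. Three
artifact classes dominate the raw values:

* **Technical background.** Batch, plate and latent sample factors shift
  intensities coherently across the whole genome. On real biobank arrays
  most of the variance of rare-variant autosomal L2R values is technical,
  and the same factors load the MT probes, inducing strong autosomal–MT
  correlation unrelated to copy number.
* **GC waves.** Long-range intensity oscillations that track regional GC
  content, with per-sample amplitude.
* **Cross-hybridization.** Autosomal probes in NUMT regions partially
  hybridize to mitochondrial template (their intensity rises with true
  mtDNA-CN), and others pick up sex-chromosome dosage. Left in place, such
  probes contaminate the autosomal background model: at worst a background
  component tags the trait (or sex) itself, and residualizing MT probes
  against it subtracts real signal.

## Pipeline

### Probe selection

Autosomal probes with annotated MAF strictly below `maf_max` (default 0.01),
call rate at least `1 - missingness_max` (default 0.95) and position outside
optional exclusion regions (BED input; NUMTs, immunoglobulin/TCR genes,
centromere margins) form the background set. Rare variants are used because
their genotype clusters are nearly all homozygous, matching the effectively
homoplasmic MT probes, and because a single universal rare set needs no
per-ancestry LD pruning. Boundary conventions are strict on both sides
(MAF exactly at the limit is excluded; waviness exactly at the limit is
retained), and the filter errors if fewer than `min_autosomal_probes`
(default 1000) survive — roughly the smallest set shown to work in
practice. MAF and call rate come from the annotation; recomputing them from
genotypes is out of scope (the pipeline's input contract is L2R + metadata).

### GC-wave correction

For each sample independently, OLS of that sample's non-missing **autosomal**
L2R values on `(1, gc, gc^2)`; the fitted wave is subtracted from every
probe, MT included. Fitting on autosomal probes only is deliberate: they are
copy-neutral by assumption, so the per-sample intercept cannot absorb real
MT dosage signal (with all probes in the fit, the intercept soaks up the
sample mean, which contains the MT signal in proportion to the MT probe
fraction). The quadratic term is configurable off (`gc_quadratic=False`).
GC fraction is taken as a per-probe precomputed annotation column; the
window it was computed over is the annotation producer's concern. If GC is
constant across the fitting probes the correction degenerates to centering,
with a warning. The correction is idempotent and leaves per-sample residuals
exactly orthogonal to the GC regressors over the fitting probes.

### Waviness filter

Per-sample population SD (divide by n) of post-correction L2R values;
samples with SD strictly above `waviness_max` (default 0.35, the value used
on real arrays) are removed. `waviness_max=None` disables the filter — used
for synthetic data, see below.

### Background PCA and residualization

Probe-centered PCA of the rare-autosomal matrix, samples as observations:
economy SVD of the centered matrix transposed, scores = left singular
vectors × singular values. Missing cells are mean-imputed for the
decomposition only. Component signs are canonicalized (largest-magnitude
probe loading positive) so repeated fits are bit-identical. No unit-variance
scaling: L2R values share a scale by construction.

`k` is chosen by the smallest cumulative variance fraction ≥ 0.70
(default), by the maximum-distance-to-chord scree elbow, or fixed. The 70%
rule is the default because on real cohorts the scree elbow has coincided
with roughly 70% of variance; the rule, not any particular k, is the
contract.

Residualization regresses each probe's **observed** entries on the k scores
plus intercept and keeps the residuals — no imputed value ever reaches the
output. Probes with complete data share one normal-equations solve; probes
with missing cells reuse the shared Gram matrix via a downdate by the
missing design rows (falling back to `lstsq` if the downdated system is not
positive definite). With k = 0 this reduces to per-probe centering.

### Cross-hybridization screen

Pairwise-complete Pearson correlation of every corrected autosomal probe
with (a) the per-sample median of corrected MT values and (b) the female
indicator (female = 1, male = 0, unknown excluded pairwise); flag
|r| > 0.05. The threshold is the empirical point at which off-target dosage
is distinguishable from the null spread of r at biobank n. Probes with
fewer than 3 paired observations keep an undefined r and are retained with
a warning. Flagged probes are removed and the background PCA re-fit on the
survivors — exactly one filter-and-refit pass; the screen is not iterated.
The first pass deliberately uses the pre-filter probe set (adjust, then test
residual association).

### Estimation

MT probes are residualized against the refitted background, then the
per-sample score on the top principal component of the probe-centered MT
matrix is the raw estimate; the per-sample median of corrected MT values is
retained as the legacy estimator (`estimator="median"`). A PC has arbitrary
orientation, so the score is aligned against known predictors — sex first
(females expected higher), age as fallback (each decade expected lower),
requiring ≥ 30 non-missing samples and |r| ≥ 0.01; a contradiction of the
expected direction negates all scores, and with no usable covariate the sign
is left unchanged with a warning. Sex is preferred because its expected
effect per SD is the stronger of the two. Finally the scores are
standardized (mean 0, population SD 1) — estimates are relative, in SD
units; calibration to absolute copy counts is out of scope.

Region mode re-derives the complete estimate (PCA, alignment,
standardization) per MT window, default the thirds MT:1–6425, 6526–11947
and 11948–16569. The printed gap 6426–6525 between the first two windows is
honored literally: probes there go unused, with a warning. Windows with
fewer than 2 probes are skipped. Concordant per-third estimates argue
against NUMT interference, which loads unevenly along the MT genome.

## Synthetic data generator

`simulate_dataset` draws, from a single seed, per sample *i* and probe *j*:

* autosomal: `L2R = sum_f B[i,f] * Lambda[f,j] + gamma_i * (gc_j - mean gc)
  + delta_numt * C_i * [j NUMT-planted] + delta_sex * F_i * [j sex-planted]
  + eps`,
* mitochondrial: `L2R = alpha_j * C_i + sum_f B[i,f] * LambdaMT[f,j] + eps`,

with the latent copy trait `C_i = beta_sex * F_i + beta_age * (age_i / 10)
+ eta_i`, `eta ~ N(0,1)`, `F` the female indicator, `alpha_j = |N(1, 0.2)|`
(strictly positive so the top MT component has a true orientation, making
sign-alignment tests well-posed), `B, Lambda, eps` Gaussian, and missing
cells uniform at rate 0.01. Defaults: 2000 samples, 5000 autosomal probes
(all with MAF drawn < 0.01), 250 MT probes, 10 batch factors, noise SD 0.5.

Parameter choices and what they emulate:

* `batch_loading_sd = 0.226`: batch factors carry ≈ 2/3 of autosomal
  variance, so the 70% cumulative rule retains the 10-factor batch subspace
  plus ~90 leading residual components — mirroring the real-data regime
  where the retained k (≈ 120) exceeds the plausible number of distinct
  technical factors. Per-MT-probe copy signal-to-noise is
  `alpha^2 var(C) / eps^2 ≈ 4`.
* `beta_sex = 0.12` and `beta_age = -0.08` per decade: the reported
  directions and magnitudes of the sex and age associations of blood
  mtDNA-CN; ages uniform over 40–70, female fraction 0.5.
* `numt_loading = 0.07` on 100 probes and `sex_loading = 0.2` on 20 probes:
  *weak partial* cross-hybridization, which is both the realistic regime
  (real screens remove only ~0.2–1.1% of probes) and the regime in which
  the single-pass screen is effective. Contamination planted much more
  strongly forms a separable PCA direction that the *first-pass* background
  correction absorbs; the screen — which tests residual correlation after
  that correction — is then structurally blind to it, and recovery degrades
  whether or not the filter runs. Below the PCA detectability edge the
  planted probes keep per-probe screen correlations of ≈ 0.14 (NUMT) and
  ≈ 0.20 (sex), far above the 0.05 threshold, while an unfiltered run still
  loses recovery because near-edge background components tilt toward the
  contaminated directions. Similarly, many strongly sex-loaded probes make
  the background PCs absorb a large share of the sex indicator, which
  visibly deflates the sex screen's null flag rate; 20 probes leave the
  null near its analytic value `2*Phi(-0.05*sqrt(n-2)) ≈ 2.5%` per screen.

The generator operates at unit variance, not at real-array L2R amplitude:
per-sample SDs are ≈ 0.9, far above the 0.35 waviness cutoff calibrated for
real arrays, so pipeline runs on synthetic data disable the waviness filter
(`waviness_max=None`); the filter's behavior and its boundary conventions
are tested on constructed data. Features of real arrays the generator does
not emulate: genotype-cluster intensity geometry, B-allele frequencies,
heavy-tailed and spatially structured noise, probe-specific variances,
sequence-homology structure of real NUMTs, and informative missingness.
Passing recovery tests therefore demonstrates the pipeline's algebra and its
behavior under a known low-rank-plus-signal model, not its accuracy on any
real cohort.

## Numerical conventions

* Population SD (divide by n) for standardization and waviness; sample SD
  (n−1) inside Bland–Altman limits (`bias ± 1.96 · SD`), the standard
  agreement convention.
* Median of an even count is the midpoint of the two central values.
* Pearson p-values via the t transform; correlations are pairwise-complete.
* TSV floats are written at `repr` precision, so write/read round trips are
  bit-exact; missing values are the literal `NA`.
* PCA determinism: single-threaded LAPACK SVD with canonicalized signs;
  fixed seed implies byte-identical output files.
* Estimates are invariant to probe/sample input order up to floating-point
  summation effects (~1e-10 relative).

## Problem sizes

The default synthetic study (2000 × 5250) runs the full pipeline in ~30 s
on one CPU; the test suite uses a 20× smaller configuration for most
checks and the default configuration for the end-to-end properties.

## Known limitations

* The GC model is a per-sample quadratic in a single precomputed GC
  fraction; tools fitted on multi-scale GC windows may remove more wave
  structure.
* The cross-hybridization screen is single-pass by design; contamination
  strong enough to dominate a background component evades it (see above) in
  any single-pass design that adjusts before testing.
* Sign alignment is statistical: below a few hundred samples the sex/age
  associations (population r ≈ 0.06) cannot reliably orient the score.
* `covariate_r2` fits plain OLS; it does not model relatedness or
  ancestry structure.
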