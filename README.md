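# automitoc

Estimation of relative mitochondrial DNA copy number (mtDNA-CN) from
SNP-array probe intensities.

Blood mtDNA-CN is an accessible proxy for mitochondrial function, and
genotyping arrays — designed for genotype calling — can be repurposed to
measure it: the log2 ratio `L2R = log2(observed / expected)` of a probe's
hybridization intensity tracks the amount of template DNA, so mitochondrial
probes carry a (noisy) copy-number signal. The catch is that batch, plate
and latent sample factors inflate intensities genome-wide, some autosomal
probes cross-hybridize to the MT genome (NUMT regions) or to sex
chromosomes, and per-sample "genomic waves" track regional GC content. This
package implements an automated four-step pipeline that removes each of
those artifacts and extracts a standardized per-sample mtDNA-CN score,
together with a synthetic array-data generator that makes every stage
testable at desk scale.

## Method

Given an L2R matrix **X** (probes × samples), probe annotation (chromosome,
position, MAF, call rate, GC fraction) and sample annotation (sex, age):

1. **Preprocessing.** Keep rare autosomal probes (MAF < 0.01, genotype
   missingness < 0.05, outside optional exclusion regions such as NUMTs and
   immunoglobulin/TCR/centromere windows); rare variants are mostly
   homozygous, so their intensity behavior matches the predominantly
   homoplasmic MT probes and no LD pruning is needed. Regress each sample's
   autosomal L2R values on (gc, gc²) and subtract the fitted wave from every
   probe; drop samples whose post-correction L2R SD exceeds 0.35.
2. **Background correction.** Probe-centered PCA of the rare autosomal
   matrix; retain the top *k* components (smallest *k* reaching 70%
   cumulative variance by default; scree-elbow and fixed-*k* modes
   available) and residualize every probe — autosomal and MT — on the *k*
   per-sample scores.
3. **Cross-hybridization screen.** Correlate each corrected autosomal probe
   with (a) the per-sample median of corrected MT L2R values and (b)
   reported sex (female = 1); remove probes with |r| > 0.05 and re-derive
   the background PCA on the survivors.
4. **Estimation.** Residualize the MT probes against the refitted
   background, take each sample's score on the top MT principal component,
   orient the sign using known predictors (females higher, older age lower),
   and standardize to mean 0, SD 1. The legacy per-sample MT median is
   available for comparison, and estimates can be re-derived per MT-genome
   third (MT:1–6425, 6526–11947, 11948–16569) as a NUMT sensitivity check.

## Worked example

```python
import numpy as np
import automitoc as am

# synthetic dataset with known truth: 2000 samples, 5000 rare autosomal
# probes, 250 MT probes, 10 latent batch factors
matrix, probes, samples, truth = am.simulate_dataset(am.SimulationConfig(seed=1))

config = am.PipelineConfig(waviness_max=None)  # simulator works at unit scale
results = am.AutoMitoC(matrix, probes, samples, config=config).fit()
print(results.summary())
print("recovery r =", np.corrcoef(results.estimates.mtdna_cn,
                                  truth.true_copy)[0, 1].round(4))
```

prints

```
AutoMitoC mtDNA-CN estimation
==============================================
samples in / retained         2000 / 2000
rare autosomal probes         5000
cross-hybridizing removed      369  (MT 264, sex 110)
background PCs (k)             101  (70.0% variance)
MT probes used                 250
estimator                      pca
sign alignment                 sex  (flipped: False)
==============================================
mtdna_cn is standardized: mean 0, SD 1 over retained samples
recovery r = 0.9663
```

The screen removed the planted cross-hybridizing probes (plus a ~2.5%
false-positive tail expected from the |r| > 0.05 threshold at n = 2000),
101 background components captured 70% of the autosomal variance, and the
final standardized estimates correlate at r ≈ 0.97 with the simulated true
copy-number trait. `results.estimates`, `results.qc_report`,
`results.crosshyb_report` and `results.manifest` carry the full audit trail;
`results.write(out_dir)` serializes everything as TSV/JSON.

The same pipeline is available from the shell:

```sh
automitoc simulate --out-dir data --seed 1
automitoc run --l2r data/l2r.tsv --probes data/probes.tsv \
    --samples data/samples.tsv --out-dir out --waviness-max 1e9
automitoc evaluate --truth data/truth.tsv --estimates out/estimates.tsv
```

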