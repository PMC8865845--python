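"""Synthetic SNP-array L2R generator with known truth.

The generator emulates the statistical structure the pipeline must undo,
at desk scale and unit variance (not at real-array L2R amplitude):

* a shared low-rank technical background (``k_batch`` latent factors with
  Gaussian loadings on every probe, autosomal and MT alike) standing in for
  batch/plate effects;
* a per-sample GC wave: sample slope times centered probe GC fraction,
  applied to autosomal probes;
* a latent true copy-number trait ``C_i = beta_sex*F_i + beta_age*(age_i/10)
  + eta_i`` (eta standard normal, F the female indicator) loading on every
  MT probe with strictly positive loadings ``alpha_j = |N(mean, sd)|`` so the
  top MT component has an unambiguous true orientation;
* planted cross-hybridizing autosomal probes: NUMT-like probes that load the
  copy trait, and sex probes that load the female indicator;
* i.i.d. Gaussian measurement noise and uniform missingness.

Every random draw flows from the single config seed, so a fixed config is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (IntensityMatrix, MtEstimates, ProbeAnnotation, SampleAnnotation,
                 ValidationError)

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_dataset",
           "truth_recovery_report"]

MT_GENOME_LENGTH = 16569


@dataclass
class SimulationConfig:
    n_samples: int = 2000
    n_auto_probes: int = 5000
    n_mt_probes: int = 250
    k_batch: int = 10
    batch_loading_sd: float = 0.226  # batch factors ~2/3 of autosomal variance
    mt_copy_loading_mean: float = 1.0  # alpha scale
    mt_copy_loading_sd: float = 0.2
    noise_sd: float = 0.5
    gc_slope_sd: float = 1.0  # per-sample GC wave strength
    n_numt_probes: int = 100
    numt_loading: float = 0.07  # delta_numt: weak partial cross-hybridization
    n_sex_probes: int = 20
    sex_loading: float = 0.2  # delta_sex
    sex_effect_on_copy: float = 0.12  # beta_sex, SD units
    age_effect_on_copy: float = -0.08  # beta_age, per decade
    missing_rate: float = 0.01
    seed: int = 1

    def validate(self) -> None:
        counts = dict(n_samples=self.n_samples, n_auto_probes=self.n_auto_probes,
                      n_mt_probes=self.n_mt_probes, k_batch=self.k_batch,
                      n_numt_probes=self.n_numt_probes, n_sex_probes=self.n_sex_probes)
        for name, v in counts.items():
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        for name in ("batch_loading_sd", "mt_copy_loading_sd", "noise_sd",
                     "gc_slope_sd", "missing_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_mt_probes < 2:
            raise ValidationError("n_mt_probes must be >= 2 (MT PCA undefined below)")
        if self.n_numt_probes + self.n_sex_probes > self.n_auto_probes:
            raise ValidationError("planted probes exceed autosomal probe count")


@dataclass
class SimulationTruth:
    """Oracle for parameter-recovery tests."""

    true_copy: np.ndarray  # C_i per sample
    batch_scores: np.ndarray  # n_samples x k_batch
    planted_numt_probe_ids: list
    planted_sex_probe_ids: list
    gc_slope: np.ndarray  # gamma_i per sample
    config: SimulationConfig = field(repr=False, default=None)


def simulate_dataset(config: SimulationConfig):
    """Generate (IntensityMatrix, ProbeAnnotation, SampleAnnotation,
    SimulationTruth) under the generative model in the module docstring."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p_auto, p_mt = config.n_samples, config.n_auto_probes, config.n_mt_probes
    k = config.k_batch

    sample_ids = np.array([f"S{i:05d}" for i in range(n)], dtype=object)
    auto_ids = np.array([f"A{j:06d}" for j in range(p_auto)], dtype=object)
    mt_ids = np.array([f"M{j:04d}" for j in range(p_mt)], dtype=object)

    # covariates and latent copy trait
    female = (rng.random(n) < 0.5).astype(float)
    age = rng.integers(40, 71, size=n).astype(float)
    eta = rng.standard_normal(n)
    true_copy = (config.sex_effect_on_copy * female
                 + config.age_effect_on_copy * (age / 10.0) + eta)

    # shared technical background
    batch_scores = rng.standard_normal((n, k)) if k else np.zeros((n, 0))
    lam_auto = rng.normal(0.0, config.batch_loading_sd, size=(k, p_auto))
    lam_mt = rng.normal(0.0, config.batch_loading_sd, size=(k, p_mt))

    # probe annotation: rare autosomal probes spread over chromosomes 1..22
    auto_chrom = rng.integers(1, 23, size=p_auto).astype(str)
    auto_pos = rng.integers(1, 250_000_001, size=p_auto)
    auto_gc = rng.uniform(0.3, 0.7, size=p_auto)
    auto_maf = rng.uniform(1e-4, 0.0099, size=p_auto)  # all rare by default
    auto_callrate = rng.uniform(0.96, 1.0, size=p_auto)
    mt_pos = np.sort(rng.choice(MT_GENOME_LENGTH, size=p_mt, replace=False) + 1)
    mt_gc = rng.uniform(0.3, 0.7, size=p_mt)

    # per-sample GC wave on autosomal probes
    gc_slope = rng.normal(0.0, config.gc_slope_sd, size=n)
    gc_centered = auto_gc - auto_gc.mean()

    # planted cross-hybridizing probes (disjoint autosomal subsets)
    planted = rng.choice(p_auto, size=config.n_numt_probes + config.n_sex_probes,
                         replace=False)
    numt_idx = planted[:config.n_numt_probes]
    sex_idx = planted[config.n_numt_probes:]

    # MT copy-number loadings, strictly positive
    alpha = np.abs(rng.normal(config.mt_copy_loading_mean,
                              config.mt_copy_loading_sd, size=p_mt))

    auto_vals = lam_auto.T @ batch_scores.T  # p_auto x n
    auto_vals += gc_centered[:, None] * gc_slope[None, :]
    auto_vals[numt_idx] += config.numt_loading * true_copy[None, :]
    auto_vals[sex_idx] += config.sex_loading * female[None, :]
    auto_vals += rng.normal(0.0, config.noise_sd, size=(p_auto, n))

    mt_vals = alpha[:, None] * true_copy[None, :]
    mt_vals += lam_mt.T @ batch_scores.T
    mt_vals += rng.normal(0.0, config.noise_sd, size=(p_mt, n))

    values = np.vstack([auto_vals, mt_vals])
    if config.missing_rate > 0:
        values[rng.random(values.shape) < config.missing_rate] = np.nan

    matrix = IntensityMatrix(np.concatenate([auto_ids, mt_ids]), sample_ids, values)
    probes = ProbeAnnotation(pd.DataFrame({
        "chromosome": np.concatenate([auto_chrom, np.full(p_mt, "MT", dtype=object)]),
        "position": np.concatenate([auto_pos, mt_pos]),
        "maf": np.concatenate([auto_maf, np.zeros(p_mt)]),
        "call_rate": np.concatenate([auto_callrate, np.ones(p_mt)]),
        "gc_fraction": np.concatenate([auto_gc, mt_gc]),
    }, index=pd.Index(np.concatenate([auto_ids, mt_ids]), name="probe_id")))
    samples = SampleAnnotation(pd.DataFrame({
        "sex": np.where(female == 1.0, "female", "male"),
        "age": age,
    }, index=pd.Index(sample_ids, name="sample_id")))
    truth = SimulationTruth(
        true_copy=true_copy,
        batch_scores=batch_scores,
        planted_numt_probe_ids=[str(p) for p in auto_ids[np.sort(numt_idx)]],
        planted_sex_probe_ids=[str(p) for p in auto_ids[np.sort(sex_idx)]],
        gc_slope=gc_slope,
        config=config,
    )
    return matrix, probes, samples, truth


def truth_recovery_report(estimates: MtEstimates, truth: SimulationTruth,
                          removed_probe_ids=None) -> dict:
    """Summary of how well estimates recover the simulated copy trait.

    Returns Pearson r with the true trait, its sign, and — when the removed
    probe list from the cross-hybridization filter is supplied — the
    detection rate of each planted probe class.
    """
    n = len(truth.true_copy)
    if len(estimates.sample_ids) != n:
        raise ValidationError(
            f"estimates cover {len(estimates.sample_ids)} samples, "
            f"truth covers {n}: sample sets must match")
    expected_ids = [f"S{i:05d}" for i in range(n)]
    if list(estimates.sample_ids) != expected_ids:
        raise ValidationError("estimate sample ids do not match simulation ids")
    r = float(np.corrcoef(estimates.mtdna_cn, truth.true_copy)[0, 1])
    report = {"r_truth": r, "sign": int(np.sign(r)),
              "estimator": estimates.estimator,
              "region_label": estimates.region_label}
    if removed_probe_ids is not None:
        removed = set(removed_probe_ids)
        for label, planted in (("numt", truth.planted_numt_probe_ids),
                               ("sex", truth.planted_sex_probe_ids)):
            if planted:
                hits = sum(p in removed for p in planted)
                report[f"{label}_probe_detection_rate"] = hits / len(planted)
                report[f"{label}_probes_planted"] = len(planted)
    return report
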