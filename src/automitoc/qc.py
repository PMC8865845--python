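"""Sample and probe quality-control filters with an auditable report.

Probe selection keeps rare autosomal probes (MAF < 0.01 by default — rare
variants are mostly homozygous, so their intensity profiles resemble the
predominantly homoplasmic mitochondrial probes), with call rate at least
1 - missingness_max and position outside any supplied exclusion regions
(NUMTs, immunoglobulin/TCR genes, centromeres). Sample filtering removes
high-waviness samples (post-GC-correction L2R SD strictly above 0.35 by
default). Boundary conventions are strict on both sides: SD exactly at the
threshold is retained, MAF exactly at the maximum is excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io import IntensityMatrix, ProbeAnnotation, RegionSet, ValidationError

__all__ = ["QCReport", "filter_samples", "select_rare_autosomal_probes",
           "subsample_probes"]

DEFAULT_WAVINESS_MAX = 0.35
DEFAULT_MAF_MAX = 0.01
DEFAULT_MISSINGNESS_MAX = 0.05
DEFAULT_MIN_PROBES = 1000


@dataclass
class QCReport:
    removed_samples: list = field(default_factory=list)  # (sample_id, reason)
    removed_probes: list = field(default_factory=list)  # (probe_id, reason)
    thresholds: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def merge(self, other: "QCReport") -> "QCReport":
        return QCReport(self.removed_samples + other.removed_samples,
                        self.removed_probes + other.removed_probes,
                        {**self.thresholds, **other.thresholds},
                        {**self.counts, **other.counts})

    def to_json(self, path=None) -> str:
        doc = {
            "removed_samples": [{"sample_id": s, "reason": r}
                                for s, r in self.removed_samples],
            "removed_probes": [{"probe_id": p, "reason": r}
                               for p, r in self.removed_probes],
            "thresholds": self.thresholds,
            "counts": self.counts,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "wt") as fh:
                fh.write(text + "\n")
        return text


def filter_samples(matrix: IntensityMatrix, waviness: np.ndarray,
                   threshold: float = DEFAULT_WAVINESS_MAX):
    """Drop samples whose post-GC-correction L2R SD is strictly above the
    threshold. Returns (filtered matrix, QCReport)."""
    waviness = np.asarray(waviness, dtype=float)
    if waviness.shape != (matrix.n_samples,):
        raise ValidationError("waviness vector does not match sample count")
    drop = waviness > threshold  # strict: SD exactly at threshold is retained
    drop &= ~np.isnan(waviness)  # undefined waviness never removes a sample
    if drop.all():
        raise ValidationError(f"waviness filter (SD > {threshold}) removed every sample")
    report = QCReport(
        removed_samples=[(str(s), "waviness") for s in matrix.sample_ids[drop]],
        thresholds={"waviness_max": threshold},
        counts={"samples_in": matrix.n_samples,
                "samples_out": int((~drop).sum())},
    )
    return matrix.select_samples_mask(~drop), report


def select_rare_autosomal_probes(matrix: IntensityMatrix, probes: ProbeAnnotation,
                                 maf_max: float = DEFAULT_MAF_MAX,
                                 callrate_min: float = 1.0 - DEFAULT_MISSINGNESS_MAX,
                                 exclusions: RegionSet | None = None,
                                 min_probes: int = DEFAULT_MIN_PROBES) -> list:
    """Rare autosomal probe set for background PCA, input order preserved.

    Predicates are conjunctive (order-independent): autosomal chromosome,
    maf strictly < maf_max, call_rate >= callrate_min, position outside all
    exclusion intervals. Errors if fewer than ``min_probes`` survive.
    """
    ann = probes.loc(matrix.probe_ids)
    keep = (
        probes.is_autosomal(matrix.probe_ids)
        & (ann["maf"].to_numpy(dtype=float) < maf_max)
        & (ann["call_rate"].to_numpy(dtype=float) >= callrate_min)
    )
    if exclusions is not None and len(exclusions):
        keep &= ~exclusions.contains(ann["chromosome"].to_numpy(dtype=object),
                                     ann["position"].to_numpy())
    selected = [str(p) for p in matrix.probe_ids[keep]]
    if len(selected) < min_probes:
        raise ValidationError(
            f"only {len(selected)} rare autosomal probes survive QC; "
            f"at least {min_probes} are required for stable background PCA")
    return selected


def subsample_probes(probe_ids, n: int, seed: int) -> list:
    """Uniform random subset of n probes without replacement (the pipeline
    works with as few as ~1000 very rare probes); seed-deterministic,
    original order preserved."""
    probe_ids = list(probe_ids)
    if n > len(probe_ids):
        raise ValidationError(f"cannot subsample {n} from {len(probe_ids)} probes")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(probe_ids), size=n, replace=False))
    return [probe_ids[i] for i in idx]
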