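"""The AutoMitoC model: the four-step pipeline as a fit/results pair.

``AutoMitoC`` holds the input data (L2R matrix, probe and sample annotation,
optional exclusion regions) and the configuration; ``fit()`` executes the
pipeline —

  (i)   preprocessing: rare-autosomal probe selection, GC-wave correction,
        waviness-based sample exclusion;
  (ii)  background correction: PCA of rare autosomal probe intensities,
        residualization of every probe against the top k component scores;
  (iii) cross-hybridization screening: removal of autosomal probes whose
        corrected intensity tracks the median MT signal or reported sex,
        then re-derivation of the background PCA on the survivors;
  (iv)  estimation: top MT principal component, sign alignment against sex
        or age, standardization —

and returns an ``AutoMitoCResults`` carrying the estimates, the QC and
cross-hybridization reports, the final background PC model, and a run
manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import background, crosshyb, estimate, gc_wave, io, qc

__all__ = ["PipelineConfig", "AutoMitoC", "AutoMitoCResults"]


@dataclass
class PipelineConfig:
    """All pipeline thresholds; defaults are the published values."""

    maf_max: float = qc.DEFAULT_MAF_MAX  # rare autosomal: maf < 0.01
    missingness_max: float = qc.DEFAULT_MISSINGNESS_MAX  # call_rate >= 0.95
    waviness_max: float | None = qc.DEFAULT_WAVINESS_MAX  # None disables
    crosshyb_threshold: float = crosshyb.DEFAULT_THRESHOLD  # |r| > 0.05
    crosshyb_enabled: bool = True
    pca_mode: str = "variance"  # {"variance", "elbow", "fixed"}
    pca_target_fraction: float = 0.70
    pca_k: int | None = None  # for mode "fixed"
    gc_quadratic: bool = True
    estimator: str = "pca"  # {"pca", "median"}
    regions: str = "full"  # {"full", "thirds"}
    min_autosomal_probes: int = qc.DEFAULT_MIN_PROBES
    subsample_n: int | None = None  # optional random probe thinning
    seed: int = 0  # used only for probe subsampling

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AutoMitoCResults:
    """Fitted pipeline outputs."""

    estimates: io.MtEstimates
    region_estimates: list  # per-window MtEstimates when regions="thirds"
    qc_report: qc.QCReport
    crosshyb_report: crosshyb.CrossHybReport | None
    pc_model: background.PCModel
    first_pass_pc_model: background.PCModel
    manifest: dict
    corrected_mt: io.IntensityMatrix = field(repr=False, default=None)

    def summary(self) -> str:
        m = self.manifest
        e = self.estimates
        lines = [
            "AutoMitoC mtDNA-CN estimation",
            "=" * 46,
            f"samples in / retained      {m['counts']['samples_in']:>7} / "
            f"{m['counts']['samples_retained']}",
            f"rare autosomal probes      {m['counts']['rare_autosomal_probes']:>7}",
            f"cross-hybridizing removed  {m['counts']['crosshyb_removed']:>7}"
            f"  (MT {m['counts']['crosshyb_removed_mt']},"
            f" sex {m['counts']['crosshyb_removed_sex']})",
            f"background PCs (k)         {self.pc_model.k:>7}"
            f"  ({self.pc_model.total_fraction:.1%} variance)",
            f"MT probes used             {e.n_mt_probes_used:>7}",
            f"estimator                  {e.estimator:>7}",
            f"sign alignment             {e.alignment_covariate:>7}"
            f"  (flipped: {e.sign_flipped})",
            "=" * 46,
            "mtdna_cn is standardized: mean 0, SD 1 over retained samples",
        ]
        return "\n".join(lines)

    def write(self, out_dir) -> None:
        """Write estimates TSV, QC report JSON, cross-hyb report TSV,
        PC metadata JSON and the run manifest to a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_estimates(out / "estimates.tsv", self.estimates)
        for est in self.region_estimates:
            safe = est.region_label.replace(":", "_").replace("-", "_")
            io.write_estimates(out / f"estimates.{safe}.tsv", est)
        self.qc_report.to_json(out / "qc_report.json")
        if self.crosshyb_report is not None:
            self.crosshyb_report.to_tsv(out / "crosshyb_report.tsv")
        with open(out / "pc_model.json", "wt") as fh:
            json.dump({
                "k": self.pc_model.k,
                "total_fraction": self.pc_model.total_fraction,
                "variance_explained": list(map(float,
                                               self.pc_model.variance_explained[:50])),
                "n_probes": len(self.pc_model.probe_ids),
            }, fh, indent=2)
        with open(out / "manifest.json", "wt") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class AutoMitoC:
    """mtDNA-CN estimation model over an L2R matrix plus annotations.

    Parameters
    ----------
    matrix : IntensityMatrix
        Probes x samples L2R values (NaN = missing).
    probes : ProbeAnnotation
        Chromosome, position, MAF, call rate and GC fraction per probe.
    samples : SampleAnnotation
        Sex/age (and extra covariates) per sample.
    exclusions : RegionSet, optional
        Regions (NUMTs, immunoglobulin/TCR, centromeres) whose probes are
        excluded from the autosomal background set.
    config : PipelineConfig, optional
    """

    def __init__(self, matrix: io.IntensityMatrix, probes: io.ProbeAnnotation,
                 samples: io.SampleAnnotation,
                 exclusions: io.RegionSet | None = None,
                 config: PipelineConfig | None = None):
        missing = set(matrix.probe_ids) - set(probes.df.index)
        if missing:
            raise io.ValidationError(
                f"{len(missing)} matrix probes lack annotation, e.g. "
                f"{sorted(missing)[:3]}")
        missing_s = set(matrix.sample_ids) - set(samples.df.index)
        if missing_s:
            raise io.ValidationError(
                f"{len(missing_s)} matrix samples lack annotation, e.g. "
                f"{sorted(missing_s)[:3]}")
        self.matrix = matrix
        self.probes = probes
        self.samples = samples
        self.exclusions = exclusions
        self.config = config or PipelineConfig()
        self._input_files: dict = {}

    @classmethod
    def from_files(cls, l2r_path, probes_path, samples_path, bed_path=None,
                   config: PipelineConfig | None = None) -> "AutoMitoC":
        model = cls(
            io.read_l2r_matrix(l2r_path),
            io.read_probe_annotation(probes_path),
            io.read_sample_annotation(samples_path),
            io.read_bed(bed_path) if bed_path else None,
            config=config,
        )
        model._input_files = {str(p): _sha256(p)
                              for p in (l2r_path, probes_path, samples_path, bed_path)
                              if p}
        return model

    def fit(self) -> AutoMitoCResults:
        cfg = self.config
        counts = {"samples_in": self.matrix.n_samples,
                  "probes_in": self.matrix.n_probes}

        # --- (i) preprocessing -------------------------------------------
        rare_auto = qc.select_rare_autosomal_probes(
            self.matrix, self.probes, maf_max=cfg.maf_max,
            callrate_min=1.0 - cfg.missingness_max, exclusions=self.exclusions,
            min_probes=cfg.min_autosomal_probes)
        if cfg.subsample_n is not None:
            rare_auto = qc.subsample_probes(rare_auto, cfg.subsample_n, cfg.seed)
        counts["rare_autosomal_probes"] = len(rare_auto)

        mt_ids = [str(p) for p in
                  self.matrix.probe_ids[self.probes.is_mitochondrial(self.matrix.probe_ids)]]
        if len(mt_ids) < 2:
            raise io.ValidationError("pipeline requires >= 2 mitochondrial probes")
        counts["mt_probes"] = len(mt_ids)

        working = self.matrix.select_probes(rare_auto + mt_ids)
        working = gc_wave.gc_correct(working, self.probes, quadratic=cfg.gc_quadratic)

        if cfg.waviness_max is not None:
            waviness = gc_wave.sample_waviness(working)
            working, qc_report = qc.filter_samples(working, waviness,
                                                   threshold=cfg.waviness_max)
        else:
            qc_report = qc.QCReport(thresholds={"waviness_max": None},
                                    counts={"samples_in": working.n_samples,
                                            "samples_out": working.n_samples})
        counts["samples_retained"] = working.n_samples
        retained_samples = working.sample_ids

        # --- (ii) first-pass background correction -----------------------
        auto_matrix = working.select_probes(rare_auto)
        pc1 = background.fit_background_pca(
            auto_matrix, mode=cfg.pca_mode,
            target_fraction=cfg.pca_target_fraction, k_fixed=cfg.pca_k)
        corrected = background.residualize(working, pc1)

        # --- (iii) cross-hybridization screen + re-fit -------------------
        ch_report = None
        removed: list = []
        surviving_auto = rare_auto
        if cfg.crosshyb_enabled:
            mt_signal = crosshyb.median_mt_signal(corrected, self.probes)
            female = self.samples.female_indicator(retained_samples)
            ch_report = crosshyb.detect_cross_hybridization(
                corrected, self.probes, mt_signal, female,
                threshold=cfg.crosshyb_threshold)
            working, removed = crosshyb.apply_crosshyb_filter(working, ch_report)
            surviving_auto = [p for p in rare_auto if p not in set(removed)]
            flags = ch_report.table.loc[removed] if removed else None
            counts["crosshyb_removed_mt"] = (
                int(flags["flag_mt"].sum()) if flags is not None else 0)
            counts["crosshyb_removed_sex"] = (
                int(flags["flag_sex"].sum()) if flags is not None else 0)
        else:
            counts["crosshyb_removed_mt"] = counts["crosshyb_removed_sex"] = 0
        counts["crosshyb_removed"] = len(removed)
        qc_report = qc_report.merge(qc.QCReport(
            removed_probes=[(p, "cross_hybridization") for p in removed],
            thresholds={"crosshyb_threshold":
                        cfg.crosshyb_threshold if cfg.crosshyb_enabled else None},
            counts={"probes_removed_crosshyb": len(removed)}))

        pc2 = background.fit_background_pca(
            working.select_probes(surviving_auto), mode=cfg.pca_mode,
            target_fraction=cfg.pca_target_fraction, k_fixed=cfg.pca_k)

        # --- (iv) final MT correction and estimation ---------------------
        corrected_mt = background.residualize(working.select_probes(mt_ids), pc2)
        estimates = estimate.derive_estimates(corrected_mt, self.samples,
                                              estimator=cfg.estimator)
        region_estimates = []
        if cfg.regions == "thirds":
            region_estimates = estimate.estimate_by_region(
                corrected_mt, self.probes, self.samples, estimator=cfg.estimator)
        elif cfg.regions != "full":
            raise io.ValidationError(f"unknown regions mode {cfg.regions!r}")

        manifest = {
            "config": cfg.to_dict(),
            "inputs": self._input_files,
            "counts": counts,
            "k_background_pcs": pc2.k,
            "background_variance_fraction": pc2.total_fraction,
            "first_pass_k": pc1.k,
            "sign_flipped": estimates.sign_flipped,
            "alignment_covariate": estimates.alignment_covariate,
        }
        return AutoMitoCResults(
            estimates=estimates,
            region_estimates=region_estimates,
            qc_report=qc_report,
            crosshyb_report=ch_report,
            pc_model=pc2,
            first_pass_pc_model=pc1,
            manifest=manifest,
            corrected_mt=corrected_mt,
        )
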