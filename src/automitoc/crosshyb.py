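"""Empirical detection of cross-hybridizing autosomal probes.

Some autosomal probes partially hybridize to off-target genomes: NUMT-region
probes pick up mitochondrial signal, others pick up sex-chromosome signal.
Instead of sequence-homology screening (probe sequences are often not
published), the background-corrected intensity of every autosomal probe is
correlated with (a) the per-sample median of corrected MT L2R values and
(b) reported sex (female = 1, male = 0, unknown excluded pairwise); probes
with even modest correlation (|r| > 0.05 by default) are removed and the
background PCA is re-derived on the survivors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IntensityMatrix, ProbeAnnotation, ValidationError

__all__ = ["CrossHybReport", "median_mt_signal", "detect_cross_hybridization",
           "apply_crosshyb_filter"]

DEFAULT_THRESHOLD = 0.05


@dataclass
class CrossHybReport:
    """Per-autosomal-probe association with off-target signals.

    ``table`` columns: r_mt, r_sex (pairwise-complete Pearson r; NaN when
    fewer than 3 paired observations), flag_mt, flag_sex (|r| strictly above
    the threshold). Probes with undefined r are retained.
    """

    table: pd.DataFrame  # index probe_id
    threshold: float

    @property
    def flagged_probe_ids(self) -> list:
        flagged = self.table["flag_mt"] | self.table["flag_sex"]
        return [str(p) for p in self.table.index[flagged]]

    def to_tsv(self, path) -> None:
        self.table.rename_axis("probe_id").to_csv(path, sep="\t")


def median_mt_signal(matrix: IntensityMatrix, probes: ProbeAnnotation) -> np.ndarray:
    """Per-sample median of non-missing MT-probe L2R values; the off-target
    reference signal for the MT cross-hybridization screen."""
    mt_rows = probes.is_mitochondrial(matrix.probe_ids)
    if not mt_rows.any():
        raise ValidationError("no mitochondrial probes in matrix")
    sub = matrix.values[mt_rows]
    n_obs = (~np.isnan(sub)).sum(axis=0)
    if np.any(n_obs == 0):
        warnings.warn(f"samples with no MT data (median undefined): "
                      f"{list(matrix.sample_ids[n_obs == 0])}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(sub, axis=0)


def _rowwise_pearson(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pairwise-complete Pearson r of each row of ``values`` with ``y``.

    Rows with fewer than 3 paired observations, or zero variance on either
    side, give NaN.
    """
    valid = ~np.isnan(values) & ~np.isnan(y)[None, :]
    y0 = np.nan_to_num(y)
    vm = np.where(valid, values, 0.0)
    n = valid.sum(axis=1).astype(float)
    sx = vm.sum(axis=1)
    sxx = (vm * vm).sum(axis=1)
    sy = valid @ y0
    syy = valid @ (y0 * y0)
    sxy = vm @ y0
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        varx = sxx - sx * sx / n
        vary = syy - sy * sy / n
        r = cov / np.sqrt(varx * vary)
    r[(n < 3) | ~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0)


def detect_cross_hybridization(matrix: IntensityMatrix, probes: ProbeAnnotation,
                               mt_signal: np.ndarray, female: np.ndarray,
                               threshold: float = DEFAULT_THRESHOLD) -> CrossHybReport:
    """Correlate every GC- and background-corrected autosomal probe with the
    median MT signal and the female indicator; flag |r| > threshold.

    ``female`` is 1.0/0.0/NaN (unknown sex excluded pairwise from r_sex
    only). Probes with undefined r are retained with a warning.
    """
    auto_rows = probes.is_autosomal(matrix.probe_ids)
    sub = matrix.values[auto_rows]
    probe_ids = matrix.probe_ids[auto_rows]
    r_mt = _rowwise_pearson(sub, np.asarray(mt_signal, dtype=float))
    r_sex = _rowwise_pearson(sub, np.asarray(female, dtype=float))
    undefined = np.isnan(r_mt) | np.isnan(r_sex)
    if undefined.any():
        warnings.warn(f"{int(undefined.sum())} autosomal probes with undefined "
                      "correlation (<3 paired observations or zero variance); retained")
    table = pd.DataFrame({
        "r_mt": r_mt,
        "r_sex": r_sex,
        "flag_mt": np.abs(r_mt) > threshold,
        "flag_sex": np.abs(r_sex) > threshold,
    }, index=pd.Index(probe_ids, name="probe_id"))
    return CrossHybReport(table=table, threshold=threshold)


def apply_crosshyb_filter(matrix: IntensityMatrix, report: CrossHybReport):
    """Remove flagged probes; returns (surviving matrix, removed probe ids).

    Downstream contract: the background PCA must be re-fit on the surviving
    probe set before the final MT correction.
    """
    flagged = set(report.flagged_probe_ids)
    keep = [p for p in matrix.probe_ids if p not in flagged]
    if not keep:
        raise ValidationError("cross-hybridization filter removed every probe")
    removed = [str(p) for p in matrix.probe_ids if p in flagged]
    return matrix.select_probes(keep), removed
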