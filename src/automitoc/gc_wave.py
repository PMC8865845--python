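"""Per-sample GC-wave correction and post-correction waviness.

Array intensities show long-range "genomic waves" whose amplitude varies by
sample and tracks regional GC content. The first correction of the pipeline
regresses, independently for every sample, that sample's non-missing L2R
values on the probes' GC fraction (linear + optional quadratic term, with
intercept) and keeps the residuals. The residual SD per sample ("waviness")
is the QC statistic used to drop wavy samples.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io import IntensityMatrix, ProbeAnnotation, ValidationError

__all__ = ["gc_correct", "sample_waviness"]


def gc_correct(matrix: IntensityMatrix, probes: ProbeAnnotation,
               quadratic: bool = True) -> IntensityMatrix:
    """Remove each sample's GC wave by OLS on (gc, gc^2) with intercept.

    The wave coefficients are fitted per sample on the autosomal probes —
    copy-neutral by assumption, so the fit cannot soak up real MT dosage
    signal through the intercept — and the fitted wave is then subtracted
    from every probe, mitochondrial included. If the matrix contains no
    autosomal probes the fit uses all probes.

    Residuals are returned in a new matrix; missing cells stay missing. If
    the GC fraction is constant across the fitting probes the regression is
    degenerate: values are only centered (by the fitting-probe mean), with
    a warning.
    """
    gc_all = probes.loc(matrix.probe_ids)["gc_fraction"].to_numpy(dtype=float)
    fit_rows = probes.is_autosomal(matrix.probe_ids)
    if not fit_rows.any():
        fit_rows = np.ones(matrix.n_probes, dtype=bool)
    values = matrix.values
    mask = ~matrix.missing_mask
    fit_mask = mask[fit_rows]
    fit_values = values[fit_rows]
    gc = gc_all[fit_rows]

    n_obs = fit_mask.sum(axis=0)
    if np.any(n_obs == 0):
        bad = list(matrix.sample_ids[n_obs == 0])
        raise ValidationError(f"samples with all fitting L2R values missing: {bad}")
    if np.any(n_obs < 3):
        bad = list(matrix.sample_ids[n_obs < 3])
        raise ValidationError(f"samples with <3 non-missing L2R values: {bad}")

    if np.ptp(gc) == 0.0:
        warnings.warn("gc_fraction is constant across fitting probes; "
                      "GC correction skipped, values centered only")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_means = np.nanmean(fit_values, axis=0)
        out = values - col_means[None, :]
        out[~mask] = np.nan
        return IntensityMatrix(matrix.probe_ids.copy(), matrix.sample_ids.copy(), out)

    def _design(g):
        cols = [np.ones_like(g), g]
        if quadratic:
            cols.append(g * g)
        return np.column_stack(cols)

    design_fit = _design(gc)  # fitting probes x q
    design_all = _design(gc_all)  # all probes x q

    coef = np.empty((design_fit.shape[1], matrix.n_samples))
    complete = n_obs == len(gc)
    if complete.any():
        # shared design for fully observed samples: one batched solve
        coef[:, complete], *_ = np.linalg.lstsq(design_fit, fit_values[:, complete],
                                                rcond=None)
    for j in np.nonzero(~complete)[0]:
        obs = fit_mask[:, j]
        coef[:, j], *_ = np.linalg.lstsq(design_fit[obs], fit_values[obs, j],
                                         rcond=None)
    out = values - design_all @ coef
    out[~mask] = np.nan
    return IntensityMatrix(matrix.probe_ids.copy(), matrix.sample_ids.copy(), out)


def sample_waviness(matrix: IntensityMatrix) -> np.ndarray:
    """Per-sample population SD of non-missing L2R values (divide by n).

    Samples with fewer than two non-missing values get NaN with a warning.
    """
    mask = ~matrix.missing_mask
    n = mask.sum(axis=0)
    out = np.full(matrix.n_samples, np.nan)
    ok = n >= 2
    if not ok.all():
        warnings.warn(f"waviness undefined (<2 values) for samples: "
                      f"{list(matrix.sample_ids[~ok])}")
    if ok.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[ok] = np.nanstd(matrix.values[:, ok], axis=0, ddof=0)
    return out
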