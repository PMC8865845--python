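"""Low-rank technical background estimation and removal.

Plate, batch and latent sample factors inflate probe intensities genome-wide
and induce strong correlation between autosomal and mitochondrial L2R values.
The background is estimated by probe-centered PCA of the rare autosomal
probes (samples are the observations), the number of retained components k
is chosen by a cumulative-variance rule (default), a scree elbow, or fixed,
and every probe — autosomal and mitochondrial alike — is then residualized
against the k per-sample component scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .io import IntensityMatrix, ValidationError

__all__ = ["PCModel", "fit_background_pca", "choose_k", "residualize"]


@dataclass
class PCModel:
    """Probe-centered PCA of an intensity matrix.

    ``scores`` (samples x k) are the per-sample principal component scores
    (left singular vectors scaled by singular values; columns mutually
    orthogonal). ``variance_explained`` holds the per-component variance
    fractions for *all* components so k can be re-chosen without refitting.
    Component signs are canonicalized so the largest-magnitude probe loading
    of each component is positive, making repeated fits bit-identical.
    """

    k: int
    scores: np.ndarray  # samples x k
    variance_explained: np.ndarray  # all components, non-increasing
    total_fraction: float  # cumulative fraction at k
    probe_ids: np.ndarray
    centering: np.ndarray  # per-probe means used to center


def _centered_imputed(matrix: IntensityMatrix):
    """Per-probe means over observed cells; missing cells imputed to the mean
    (i.e. zero after centering) for the decomposition only."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        center = np.nanmean(matrix.values, axis=1)
    center = np.where(np.isnan(center), 0.0, center)
    xc = matrix.values - center[:, None]
    xc[matrix.missing_mask] = 0.0
    return xc, center


def fit_background_pca(matrix: IntensityMatrix, mode: str = "variance",
                       target_fraction: float = 0.70,
                       k_fixed: int | None = None) -> PCModel:
    """Probe-centered PCA over samples of (typically) the rare autosomal
    probe submatrix, retaining k components chosen by ``choose_k``."""
    if matrix.n_probes < 2 or matrix.n_samples < 2:
        raise ValidationError("PCA requires >= 2 probes and >= 2 samples")
    xc, center = _centered_imputed(matrix)
    if not np.any(xc):
        raise ValidationError("zero-variance matrix: PCA undefined")
    # samples x probes orientation: left singular vectors are sample scores
    u, s, vt = scipy.linalg.svd(xc.T, full_matrices=False)
    # canonical sign: largest-|loading| entry of each component positive
    flip = vt[np.arange(len(s)), np.argmax(np.abs(vt), axis=1)] < 0
    u[:, flip] *= -1.0
    var = s ** 2
    frac = var / var.sum()
    k = choose_k(frac, mode=mode, target_fraction=target_fraction, k_fixed=k_fixed)
    return PCModel(
        k=k,
        scores=u[:, :k] * s[:k],
        variance_explained=frac,
        total_fraction=float(frac[:k].sum()),
        probe_ids=matrix.probe_ids.copy(),
        centering=center,
    )


def choose_k(variance_explained, mode: str = "variance",
             target_fraction: float = 0.70, k_fixed: int | None = None) -> int:
    """Select the number of background components.

    ``variance`` (default): smallest k whose cumulative variance fraction
    reaches ``target_fraction`` (~70% matched the scree elbow on real
    biobank arrays). ``elbow``: maximum perpendicular distance of the scree
    curve to the chord from its first to last point. ``fixed``: ``k_fixed``.
    """
    frac = np.asarray(variance_explained, dtype=float)
    if frac.size == 0:
        raise ValidationError("empty variance_explained")
    if mode == "fixed":
        if k_fixed is None or not (1 <= k_fixed <= frac.size):
            raise ValidationError(f"fixed mode needs 1 <= k_fixed <= {frac.size}")
        return int(k_fixed)
    if mode == "variance":
        cum = np.cumsum(frac)
        hit = np.nonzero(cum >= target_fraction - 1e-12)[0]
        if hit.size == 0:
            warnings.warn(f"cumulative variance never reaches {target_fraction}; "
                          "retaining all components")
            return int(frac.size)
        return int(hit[0]) + 1
    if mode == "elbow":
        if frac.size == 1:
            return 1
        x = np.arange(frac.size, dtype=float)
        y = frac
        dx, dy = x[-1] - x[0], y[-1] - y[0]
        norm = np.hypot(dx, dy)
        dist = np.abs(dy * x - dx * y + x[-1] * y[0] - y[-1] * x[0]) / norm
        return int(np.argmax(dist)) + 1
    raise ValidationError(f"unknown k-selection mode: {mode!r}")


def residualize(matrix: IntensityMatrix, model: PCModel) -> IntensityMatrix:
    """Residualize every probe against the k background scores.

    Per probe, OLS of its observed L2R values on the score columns with an
    intercept; residuals replace the values, missing cells stay missing.
    Unlike the PCA fit, no imputation enters the output: each regression
    uses observed entries only. With k = 0 this reduces to per-probe
    centering.
    """
    scores = model.scores[:, :model.k]
    n = matrix.n_samples
    if scores.shape[0] != n:
        raise ValidationError("PC scores do not align with matrix samples")
    if model.k >= n:
        raise ValidationError(f"k={model.k} >= n_samples={n}: residualization undefined")

    design = np.column_stack([np.ones(n), scores])  # n x (k+1)
    values = matrix.values
    mask = ~matrix.missing_mask
    out = np.full_like(values, np.nan)

    complete = mask.all(axis=1)
    dtd = design.T @ design
    chol = scipy.linalg.cho_factor(dtd)
    if complete.any():
        coef = scipy.linalg.cho_solve(chol, design.T @ values[complete].T)
        out[complete] = values[complete] - (design @ coef).T

    # probes with missing cells: downdate the shared normal equations by the
    # missing rows instead of refactoring the full design per probe
    for i in np.nonzero(~complete)[0]:
        obs = mask[i]
        n_obs = int(obs.sum())
        if n_obs == 0:
            continue  # all-missing probe stays all-missing
        if n_obs <= design.shape[1]:
            # too few observations to fit: fall back to centering
            out[i, obs] = values[i, obs] - values[i, obs].mean()
            continue
        d_miss = design[~obs]
        dtd_i = dtd - d_miss.T @ d_miss
        dty = design[obs].T @ values[i, obs]
        try:
            coef = scipy.linalg.cho_solve(scipy.linalg.cho_factor(dtd_i), dty)
        except scipy.linalg.LinAlgError:
            coef, *_ = np.linalg.lstsq(design[obs], values[i, obs], rcond=None)
        out[i, obs] = values[i, obs] - design[obs] @ coef
    return IntensityMatrix(matrix.probe_ids.copy(), matrix.sample_ids.copy(), out)
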