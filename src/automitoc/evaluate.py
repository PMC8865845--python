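"""Agreement and association metrics for benchmarking estimates.

Pearson correlation (with the usual t-transform p-value) and Bland-Altman
limits of agreement are the two ways array-based estimates are compared to
reference modalities (exome read-depth ratios, qPCR); covariate R-squared
quantifies how much variance known predictors (sex, age, blood counts)
explain in the standardized estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .io import SampleAnnotation, ValidationError

__all__ = ["pearson", "bland_altman", "covariate_r2", "BlandAltman"]


def _paired(x, y, min_n: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired vectors must have equal length")
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < min_n:
        raise ValidationError(f"need >= {min_n} paired non-missing values, "
                              f"got {int(ok.sum())}")
    return x[ok], y[ok]


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r and two-sided p-value (t transform), pairwise
    complete. Errors on zero variance."""
    x, y = _paired(x, y, 3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance: correlation undefined")
    res = scipy.stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class BlandAltman:
    bias: float
    lower: float
    upper: float
    sd_diff: float
    n: int


def bland_altman(x, y) -> BlandAltman:
    """Bland-Altman agreement of paired measurements: differences d = x - y,
    bias = mean(d), 95% limits = bias +/- 1.96 * sample SD(d)."""
    x, y = _paired(x, y, 3)
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, lower=bias - 1.96 * sd, upper=bias + 1.96 * sd,
                       sd_diff=sd, n=len(d))


def covariate_r2(estimates, samples: SampleAnnotation, covariates,
                 sample_ids=None) -> dict:
    """OLS R-squared of the estimates on named sample covariates.

    Returns per-covariate R-squared (single-predictor models) plus the joint
    model under key "joint". "sex" is coded female=1/male=0; unknown-sex and
    missing-covariate samples are dropped listwise per model. Errors on a
    collinear joint design, naming the offending covariates.
    """
    estimates = np.asarray(estimates, dtype=float)
    if sample_ids is None:
        sample_ids = samples.df.index
    cols = {}
    for name in covariates:
        if name == "sex":
            cols[name] = samples.female_indicator(sample_ids)
        elif name == "age":
            cols[name] = samples.age(sample_ids)
        else:
            if name not in samples.df.columns:
                raise ValidationError(f"unknown covariate {name!r}")
            cols[name] = samples.df.loc[list(sample_ids), name].to_numpy(dtype=float)
    design = pd.DataFrame(cols)

    def _fit(names):
        sub = design[list(names)]
        ok = ~(np.isnan(estimates) | sub.isna().any(axis=1).to_numpy())
        X = sm.add_constant(sub.to_numpy()[ok])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValidationError(f"collinear covariate set: {list(names)}")
        return float(sm.OLS(estimates[ok], X).fit().rsquared)

    out = {name: _fit([name]) for name in design.columns}
    out["joint"] = _fit(design.columns)
    return out
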