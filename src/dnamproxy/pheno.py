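"""Trait preparation ahead of training and association testing.

Three operations: rank-based inverse-normal transformation (Blom offset
c = 3/8, average ranks for ties), offset natural-log transformation, and
residualization on a covariate design followed by standardization of the
residuals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = ["rank_inverse_normal", "log_transform", "residualize", "PhenoError"]


class PhenoError(ValueError):
    pass


def _as_float_array(x) -> np.ndarray:
    if isinstance(x, pd.Series):
        return x.to_numpy(dtype=float)
    return np.asarray(x, dtype=float)


def _wrap_like(values: np.ndarray, template):
    if isinstance(template, pd.Series):
        return pd.Series(values, index=template.index, name=template.name)
    return values


def rank_inverse_normal(x, offset_c: float = 3.0 / 8.0):
    """Map values to normal quantiles of their offset ranks.

    Returns Φ⁻¹((rᵢ − c) / (n − 2c + 1)) where rᵢ is the average-tied rank
    among non-missing entries and c the Blom offset (default 3/8).  Missing
    values stay missing; the transform is strictly monotone on distinct
    values and invariant to any strictly monotone transform of its input.
    """
    arr = _as_float_array(x)
    out = np.full(arr.shape, np.nan)
    obs = ~np.isnan(arr)
    vals = arr[obs]
    if vals.size < 2:
        raise PhenoError("rank_inverse_normal needs ≥2 non-missing values")
    if np.all(vals == vals[0]):
        raise PhenoError("all values identical; ranks are degenerate")
    n = vals.size
    r = rankdata(vals, method="average")
    out[obs] = norm.ppf((r - offset_c) / (n - 2.0 * offset_c + 1.0))
    return _wrap_like(out, x)


def log_transform(x, offset: float = 0.0):
    """Natural log of (x + offset); e.g. log(units + 1) for alcohol intake."""
    if offset < 0:
        raise PhenoError("offset must be nonnegative")
    arr = _as_float_array(x)
    shifted = arr + offset
    bad = np.nonzero(~np.isnan(shifted) & (shifted <= 0))[0]
    if bad.size:
        if isinstance(x, pd.Series):
            names = x.index[bad].tolist()
        else:
            names = bad.tolist()
        raise PhenoError(f"nonpositive values after offset at: {names[:10]}")
    return _wrap_like(np.log(shifted), x)


def residualize(y, covariates):
    """Standardized OLS residuals of y on [intercept, covariates].

    Residuals are divided by their sample standard deviation (n−1
    denominator), so the output has mean 0 and SD 1.  The design must be
    full rank after adding the intercept and leave nonzero residual variance.
    """
    yv = _as_float_array(y)
    if isinstance(covariates, pd.DataFrame):
        names = covariates.columns.tolist()
        C = covariates.to_numpy(dtype=float)
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        names = [f"covariate_{j}" for j in range(C.shape[1])]
    n = yv.size
    if C.shape[0] != n:
        raise PhenoError("covariate rows do not match y length")
    if np.isnan(yv).any() or np.isnan(C).any():
        raise PhenoError("residualize requires complete cases")
    X = np.column_stack([np.ones(n), C])
    k = X.shape[1]
    if n <= k:
        raise PhenoError("need more observations than covariates + intercept")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name columns involved in the collinearity by checking incremental rank
        collinear = []
        r_prev = 1
        for j in range(C.shape[1]):
            r_now = np.linalg.matrix_rank(X[:, : j + 2])
            if r_now == r_prev:
                collinear.append(names[j])
            r_prev = r_now
        raise PhenoError(f"rank-deficient design; collinear columns: {collinear}")
    coef, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ coef
    sd = resid.std(ddof=1)
    if sd < 1e-12 * max(1.0, float(np.abs(yv).max())):
        raise PhenoError("zero residual variance: y lies in the covariate span")
    return _wrap_like(resid / sd, y)
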