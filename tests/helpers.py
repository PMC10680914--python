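"""Independent closed-form oracles used to cross-check the OLS machinery.

Deliberately implemented from the normal equations and the t distribution
only — no statsmodels, no shared code with the package's fitting paths.
"""

from __future__ import annotations

import numpy as np
import scipy.stats


def ols_normal_equations(x: np.ndarray, y: np.ndarray, degree: int):
    """Solve the polynomial least-squares problem via the normal equations.

    Returns (coefficients ascending, r_squared, slope_p, cov_params) with
    residual variance on n - degree - 1 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    X = np.vander(x, degree + 1, increasing=True)
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    df = n - (degree + 1)
    s2 = sse / df if df > 0 else np.nan
    cov = s2 * np.linalg.inv(xtx)
    if degree >= 1 and df > 0 and cov[1, 1] > 0:
        t = beta[1] / np.sqrt(cov[1, 1])
        p = 2.0 * scipy.stats.t.sf(abs(t), df)
    else:
        p = np.nan
    return beta, r2, p, cov


def sample_sd(values, ddof: int = 1) -> float:
    """Plain unbiased sample standard deviation."""
    v = np.asarray(values, float)
    return float(np.sqrt(((v - v.mean()) ** 2).sum() / (len(v) - ddof)))
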