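"""Per-disease polynomial trajectories of z-scores versus clinical covariates.

Each fit regresses a region's z-scores on ataxia duration (years) or SARA
sum score within one disease group, by ordinary least squares.  The linear
(degree-1) fit is the primary model: its R^2 and the two-sided t-test
p-value of the slope are reported, equivalent to the Pearson-correlation
test.  Quadratic and cubic fits are produced only as diagnostics
(residual-vs-fitted and Q-Q evidence plus AIC); no automatic model choice
is made.  p-values are unadjusted; a Benjamini-Hochberg column can be added
across a fit table as a clearly labelled extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .exceptions import FitError, InsufficientDataError
from .normative import ZScoreTable

COVARIATES = ("duration", "sara")


@dataclass
class TrajectoryFit:
    """One disease x region x covariate polynomial OLS fit."""

    disease: str
    region: str
    covariate: str
    degree: int
    coefficients: np.ndarray  # ascending powers of the covariate
    r_squared: float
    slope_p: float  # two-sided t-test of the linear coefficient (degree 1)
    n: int
    residuals: np.ndarray
    fitted: np.ndarray
    x: np.ndarray
    cov_params: np.ndarray  # coefficient covariance (includes residual scale)
    resid_var: float  # SSE / (n - degree - 1), NaN when df = 0

    @property
    def x_range(self) -> tuple[float, float]:
        return float(self.x.min()), float(self.x.max())

    @property
    def df_resid(self) -> int:
        return self.n - (self.degree + 1)

    def predict(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return np.vander(x, self.degree + 1, increasing=True) @ self.coefficients

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Confidence interval for the linear coefficient (degree-1 fits)."""
        if self.degree != 1:
            raise FitError("slope CI defined for degree-1 fits only")
        se = float(np.sqrt(self.cov_params[1, 1]))
        t = scipy.stats.t.ppf(0.5 + level / 2, self.df_resid)
        b = float(self.coefficients[1])
        return b - t * se, b + t * se


@dataclass
class DiagnosticsBundle:
    """Residual-vs-fitted and Q-Q evidence for degrees 1-3 on one data set."""

    disease: str
    region: str
    covariate: str
    fits: dict[int, TrajectoryFit]
    residual_vs_fitted: dict[int, pd.DataFrame]
    qq: dict[int, pd.DataFrame]  # theoretical vs ordered sample quantiles
    aic: dict[int, float]
    infeasible_degrees: list[int] = field(default_factory=list)


def _select(z: ZScoreTable, disease: str, region: str, covariate: str) -> pd.DataFrame:
    if covariate not in COVARIATES:
        raise ValueError(f"covariate must be one of {COVARIATES}")
    if disease == z.reference_group:
        raise FitError("trajectories are defined for disease groups, not the reference")
    df = z.data[z.data["group"] == disease]
    return df.dropna(subset=[region, covariate])


def fit_trajectory(
    z: ZScoreTable, disease: str, region: str, covariate: str, degree: int = 1
) -> TrajectoryFit:
    """OLS polynomial fit of z on the covariate within one disease group.

    Complete-case on (z, covariate); reference rows are never eligible.
    Needs n >= degree + 1 records (exact interpolation is legal but leaves
    the residual variance, R^2 denominator and slope test undefined or
    degenerate) and a covariate with positive variance.
    """
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    df = _select(z, disease, region, covariate)
    n = len(df)
    if n < degree + 1:
        raise InsufficientDataError(
            f"{disease}/{region}/{covariate}: n={n} < {degree + 1} for degree {degree}"
        )
    x = df[covariate].to_numpy(dtype=float)
    y = df[region].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise FitError(f"{disease}/{region}/{covariate}: zero covariate variance")
    X = np.vander(x, degree + 1, increasing=True)
    res = sm.OLS(y, X).fit()
    coef = np.asarray(res.params, dtype=float)
    fitted = X @ coef
    resid = y - fitted
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst > 0:
        r2 = 1.0 - sse / sst
    else:
        r2 = 0.0  # constant response: the model explains nothing
    df_resid = n - (degree + 1)
    resid_var = sse / df_resid if df_resid > 0 else float("nan")
    if degree == 1 and sst == 0:
        slope_p = 1.0  # flat data, slope is 0 by construction
    elif degree == 1 and df_resid > 0 and res.bse[1] > 0:
        slope_p = float(res.pvalues[1])
    else:
        slope_p = float("nan")
    return TrajectoryFit(
        disease=disease,
        region=region,
        covariate=covariate,
        degree=degree,
        coefficients=coef,
        r_squared=max(0.0, min(1.0, r2)),
        slope_p=slope_p,
        n=n,
        residuals=resid,
        fitted=fitted,
        x=x,
        cov_params=np.asarray(res.cov_params(), dtype=float),
        resid_var=resid_var,
    )


def confidence_band(
    fit: TrajectoryFit, x_grid, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise CI for the mean response (not a prediction interval).

    Uses the coefficient covariance and a t quantile with n - degree - 1
    degrees of freedom; the band is symmetric about the fitted line and
    narrowest at the covariate mean.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if fit.df_resid <= 0:
        raise FitError("confidence band undefined without residual degrees of freedom")
    x_grid = np.atleast_1d(np.asarray(x_grid, dtype=float))
    D = np.vander(x_grid, fit.degree + 1, increasing=True)
    mu = D @ fit.coefficients
    se = np.sqrt(np.einsum("ij,jk,ik->i", D, fit.cov_params, D))
    t = scipy.stats.t.ppf(0.5 + level / 2, fit.df_resid)
    return mu - t * se, mu + t * se


def compare_degrees(
    z: ZScoreTable, disease: str, region: str, covariate: str, max_degree: int = 3
) -> DiagnosticsBundle:
    """Fit degrees 1..max_degree and export diagnostics for each.

    Degrees needing more records than available are listed in
    ``infeasible_degrees`` (a degree is feasible at n >= degree + 2, so the
    diagnostics have at least one residual degree of freedom).
    """
    n_avail = len(_select(z, disease, region, covariate))
    fits: dict[int, TrajectoryFit] = {}
    rvf: dict[int, pd.DataFrame] = {}
    qq: dict[int, pd.DataFrame] = {}
    aic: dict[int, float] = {}
    infeasible: list[int] = []
    for degree in range(1, max_degree + 1):
        if n_avail < degree + 2:
            infeasible.append(degree)
            continue
        fit = fit_trajectory(z, disease, region, covariate, degree)
        fits[degree] = fit
        rvf[degree] = pd.DataFrame({"fitted": fit.fitted, "residual": fit.residuals})
        (theo, ordered), _ = scipy.stats.probplot(fit.residuals, dist="norm")
        qq[degree] = pd.DataFrame({"theoretical": theo, "ordered": ordered})
        # Gaussian log-likelihood AIC with k = degree + 2 (coefficients + variance)
        sse = float(fit.residuals @ fit.residuals)
        k = degree + 2
        aic[degree] = fit.n * np.log(sse / fit.n) + 2 * k
    return DiagnosticsBundle(
        disease=disease,
        region=region,
        covariate=covariate,
        fits=fits,
        residual_vs_fitted=rvf,
        qq=qq,
        aic=aic,
        infeasible_degrees=infeasible,
    )


def fits_to_frame(fits: list[TrajectoryFit], bh_adjust: bool = True) -> pd.DataFrame:
    """Long-format fit table (one row per fit), mirroring the per-panel
    annotations of the scatter figures.  ``slope_p_bh`` is a
    Benjamini-Hochberg adjusted column added as an extension; the primary
    p-values stay unadjusted."""
    rows = []
    for f in fits:
        rows.append(
            {
                "disease": f.disease,
                "region": f.region,
                "covariate": f.covariate,
                "degree": f.degree,
                "intercept": float(f.coefficients[0]),
                "slope": float(f.coefficients[1]) if f.degree >= 1 else np.nan,
                "coefficients": ";".join(f"{c:.17g}" for c in f.coefficients),
                "r_squared": f.r_squared,
                "slope_p": f.slope_p,
                "n": f.n,
            }
        )
    out = pd.DataFrame(rows)
    if bh_adjust and len(out):
        mask = out["slope_p"].notna() & (out["degree"] == 1)
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(
                out.loc[mask, "slope_p"].to_numpy(), method="fdr_bh"
            )[1]
        out["slope_p_bh"] = adj
    return out
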