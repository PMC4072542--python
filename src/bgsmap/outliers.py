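"""Diversity baselines from B and studentized-residual outlier scans.

Observed silent diversity is regressed on the predicted background-selection
baseline B (ordinary least squares, with intercept; the slope absorbs the
scale theta0 = 4*Ne*u so no assumption about absolute diversity is needed).
Autosomes and the X chromosome are fitted separately to avoid building the
true X/A ratio into the baseline.  Departures are parameterized by
externally studentized residuals (pi_sil-R): the observation under test is
left out of the residual-variance estimate, giving an exact t distribution
with n - 3 degrees of freedom and two-sided P values.  Windows passing a
Benjamini-Hochberg FDR threshold are flagged as diversity deficits
(candidate sweeps) or excesses (candidate balancing selection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BaselineFit",
    "fit_baseline",
    "studentized_residuals",
    "normality_check",
    "fdr_bh",
    "concordance",
    "outlier_table",
]


class FitError(ValueError):
    """Degenerate or underdetermined baseline regression."""


@dataclass
class BaselineFit:
    """OLS fit of pi_sil on B for one chromosome group."""

    group: str
    intercept: float
    slope: float
    slope_se: float
    residual_variance: float
    n: int
    result: object  # statsmodels RegressionResults


def fit_baseline(pi_sil: np.ndarray, b: np.ndarray, group: str = "autosome") -> BaselineFit:
    """Least-squares linear fit of observed diversity on the B baseline."""
    pi_sil = np.asarray(pi_sil, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = ~(np.isnan(pi_sil) | np.isnan(b))
    pi_sil, b = pi_sil[ok], b[ok]
    if len(pi_sil) < 10:
        raise FitError(f"need >= 10 windows per group, got {len(pi_sil)}")
    if np.ptp(b) == 0:
        raise FitError("B is constant; baseline fit is degenerate")
    res = sm.OLS(pi_sil, sm.add_constant(b)).fit()
    return BaselineFit(
        group=group,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        residual_variance=float(res.mse_resid),
        n=len(pi_sil),
        result=res,
    )


def studentized_residuals(fit: BaselineFit) -> pd.DataFrame:
    """Externally studentized residuals with two-sided t-based P values.

    Degrees of freedom are n - 3: n minus the two regression parameters
    minus the left-out observation.
    """
    n = fit.n
    if n < 5:
        raise FitError("too few windows for studentized residuals")
    df = n - 3
    endog_var = float(np.var(np.asarray(fit.result.model.endog)))
    if fit.residual_variance <= 1e-16 * max(endog_var, 1e-300):  # exact fit
        r_student = np.zeros(n)
        p = np.ones(n)
    else:
        infl = fit.result.get_influence()
        r_student = infl.resid_studentized_external
        p = 2.0 * stats.t.sf(np.abs(r_student), df)
    return pd.DataFrame(
        {
            "residual": fit.result.resid,
            "studentized": r_student,
            "P": p,
        }
    )


def normality_check(residuals: np.ndarray, n_bins: int = 24) -> tuple[float, int, float]:
    """Chi-square goodness of fit of studentized residuals to the standard
    normal over ``n_bins`` equal-probability bins; df = n_bins - 1."""
    residuals = np.asarray(residuals, dtype=float)
    residuals = residuals[~np.isnan(residuals)]
    n = len(residuals)
    if n < 5 * n_bins:
        raise FitError(f"need >= {5 * n_bins} residuals for {n_bins} bins")
    edges = stats.norm.ppf(np.linspace(0, 1, n_bins + 1))
    observed, _ = np.histogram(residuals, bins=edges)
    expected = np.full(n_bins, n / n_bins)
    chi2, p = stats.chisquare(observed, expected)
    return float(chi2), n_bins - 1, float(p)


def fdr_bh(p_values: np.ndarray, q_level: float = 0.10):
    """Benjamini-Hochberg step-up q-values and pass flags at ``q_level``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q, reject


def outlier_table(
    windows: pd.DataFrame,
    fit: BaselineFit,
    q_level: float = 0.10,
    nominal_p: float = 0.05,
) -> pd.DataFrame:
    """Assemble the per-window outlier table for one fitted group.

    ``windows`` must carry ``pi_sil`` and ``B`` columns (rows with NaN in
    either are dropped, matching the fit).  Flags mark windows with nominal
    P below ``nominal_p``: ``deficit`` for negative residuals (sweep-like),
    ``excess`` for positive (balancing-like); ``q_pass`` additionally marks
    BH q < ``q_level``.
    """
    out = windows.copy()
    ok = ~(out["pi_sil"].isna() | out["B"].isna())
    out = out[ok].reset_index(drop=True)
    if len(out) != fit.n:
        raise FitError("window table does not match the fitted sample")
    resid = studentized_residuals(fit)
    out["fitted"] = fit.result.fittedvalues
    out["residual"] = resid["residual"].to_numpy()
    out["pi_sil_R"] = resid["studentized"].to_numpy()
    out["P"] = resid["P"].to_numpy()
    q, reject = fdr_bh(out["P"].to_numpy(), q_level)
    out["q"] = q
    out["q_pass"] = reject
    sign = np.sign(out["pi_sil_R"].to_numpy())
    flag = np.where(
        out["P"].to_numpy() < nominal_p,
        np.where(sign < 0, "deficit", "excess"),
        "none",
    )
    out["flag"] = flag
    return out


def concordance(
    pi_sil_r: np.ndarray,
    tajima_norm: np.ndarray,
    flags: np.ndarray | None = None,
) -> dict:
    """Association between baseline residuals and the site-frequency
    spectrum: Spearman rho between pi_sil-R and D/Dmin (tie-aware,
    two-sided), plus Mann-Whitney U tests comparing flagged deficit/excess
    windows against unflagged ones when flags are supplied."""
    x = np.asarray(pi_sil_r, dtype=float)
    y = np.asarray(tajima_norm, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 5:
        raise ValueError("need >= 5 matched windows")
    rho, p = stats.spearmanr(x[ok], y[ok])
    out = {"spearman_rho": float(rho), "spearman_p": float(p), "n": int(ok.sum())}
    if flags is not None:
        flags = np.asarray(flags)[ok]
        xo, yo = x[ok], y[ok]
        none = flags == "none"
        for kind in ("deficit", "excess"):
            mask = flags == kind
            if mask.sum() >= 1 and none.sum() >= 1:
                u, pu = stats.mannwhitneyu(
                    yo[mask], yo[none], alternative="two-sided"
                )
                out[f"mwu_{kind}_p"] = float(pu)
                out[f"n_{kind}"] = int(mask.sum())
    return out
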