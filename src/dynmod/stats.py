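"""Brain-behavior inference.

OLS regression of the behavioral PC1 on network measures, internally
validated by leave-one-out cross-validation whose mean squared error is
compared against a permutation null (predictor-outcome mapping permuted;
the model is significant when the observed MSE lies in the low tail).
Also: Benjamini–Hochberg FDR adjustment, the Steiger/Williams test for
two dependent correlations sharing one variable, and the subgroup
t-tests (pooled-variance two-sample; paired).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import statsmodels.api as sm
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from ._seeds import derive_rng

__all__ = [
    "RegressionResult",
    "ols_fit",
    "loocv_permutation",
    "fdr_adjust",
    "steiger_dependent_corr",
    "subgroup_tests",
    "paired_test",
]

_COND_TOL = 1e10


@dataclass
class RegressionResult:
    """OLS fit summary, optionally with LOOCV-permutation validation fields."""

    beta0: float
    betas: np.ndarray
    r_squared: float
    f_statistic: float
    df: tuple[int, int]
    p: float
    n: int
    loocv_mse: float | None = None
    loocv_mse_sd: float | None = None
    permutation_p: float | None = None


def _design(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def ols_fit(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares of y on x (with intercept)."""
    X = _design(x)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > k+1 observations (n={n}, k={k})")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("missing or non-finite values")
    Xc = sm.add_constant(X)
    if np.linalg.cond(Xc) > _COND_TOL:
        raise ValueError("collinear predictors: design condition number above tolerance")
    fit = sm.OLS(y, Xc).fit()
    return RegressionResult(
        beta0=float(fit.params[0]),
        betas=np.asarray(fit.params[1:]),
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        df=(int(fit.df_model), int(fit.df_resid)),
        p=float(fit.f_pvalue),
        n=n,
    )


def _loocv_sq_errors(Xc: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out squared prediction errors via the hat-matrix identity.

    For OLS, the held-out residual is e_i / (1 − h_ii); supports y as a
    vector or a matrix of columns (vectorizing permutations).  Points with
    leverage ≈ 1 (possible at very small n) fall back to an explicit refit.
    """
    H = Xc @ np.linalg.solve(Xc.T @ Xc, Xc.T)
    h = np.diag(H)
    resid = y - H @ y
    denom = 1.0 - h
    high = denom < 1e-8
    denom = np.where(high, 1.0, denom)
    out = (resid / (denom if y.ndim == 1 else denom[:, None])) ** 2
    for i in np.flatnonzero(high):
        mask = np.arange(Xc.shape[0]) != i
        beta, *_ = np.linalg.lstsq(Xc[mask], y[mask], rcond=None)
        pred = Xc[i] @ beta
        out[i] = (y[i] - pred) ** 2
    return out


def loocv_permutation(
    x: np.ndarray, y: np.ndarray, n_perm: int = 10_000, seed: int = 0
) -> dict:
    """LOOCV mean squared error with a permutation-null significance test.

    Permuting the predictor-outcome mapping ``n_perm`` times yields a
    null distribution of LOOCV MSEs; p is the add-one-corrected
    proportion of null MSEs less than or equal to the observed MSE, so
    small p means the model predicts better than chance.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X = _design(x)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need n >= 4 for LOOCV")
    Xc = sm.add_constant(X)
    sq = _loocv_sq_errors(Xc, y)
    mse, sd = float(sq.mean()), float(sq.std(ddof=1))
    rng = derive_rng(seed, "loocv-perm")
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)], axis=1)  # n×n_perm
    null_mse = _loocv_sq_errors(Xc, perms).mean(axis=0)
    p = (1.0 + np.count_nonzero(null_mse <= mse)) / (n_perm + 1.0)
    return {"loocv_mse": mse, "loocv_mse_sd": sd, "permutation_p": float(p),
            "null_mse": null_mse}


def validated_regression(
    x: np.ndarray, y: np.ndarray, n_perm: int = 10_000, seed: int = 0
) -> RegressionResult:
    """OLS fit plus LOOCV-permutation internal validation."""
    res = ols_fit(x, y)
    v = loocv_permutation(x, y, n_perm=n_perm, seed=seed)
    res.loocv_mse = v["loocv_mse"]
    res.loocv_mse_sd = v["loocv_mse_sd"]
    res.permutation_p = v["permutation_p"]
    return res


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D array")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def steiger_dependent_corr(r12: float, r13: float, r23: float, n: int) -> dict:
    """Williams-form t for H0: ρ12 = ρ13 with shared variable 1.

    t = (r12 − r13) sqrt( (n−1)(1+r23) /
        ( 2 ((n−1)/(n−3)) |R| + r̄² (1−r23)³ ) ),  df = n−3,

    with |R| = 1 − r12² − r13² − r23² + 2 r12 r13 r23 and
    r̄ = (r12+r13)/2; two-sided p from Student's t.
    """
    for r in (r12, r13, r23):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n <= 3:
        raise ValueError("need n > 3")
    detR = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    if detR < 0:
        raise ValueError("infeasible correlation triple (determinant < 0)")
    rbar = 0.5 * (r12 + r13)
    denom = 2.0 * ((n - 1) / (n - 3)) * detR + rbar**2 * (1.0 - r23) ** 3
    t = (r12 - r13) * np.sqrt((n - 1) * (1.0 + r23) / denom)
    df = n - 3
    p = 2.0 * sp_stats.t.sf(abs(t), df)
    return {"t": float(t), "df": df, "p": float(p)}


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> dict:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sp_stats.ttest_ind(a, b, equal_var=True)
    return {"t": float(res.statistic), "df": len(a) + len(b) - 2, "p": float(res.pvalue)}


def subgroup_tests(values_by_group: dict) -> dict:
    """Pairwise pooled-variance two-sample t-tests (df = n1+n2−2)."""
    out = {}
    for g1, g2 in combinations(sorted(values_by_group), 2):
        out[(g1, g2)] = _two_sample_t(values_by_group[g1], values_by_group[g2])
    return out


def paired_test(values1: np.ndarray, values2: np.ndarray) -> dict:
    """Paired t-test (df = n−1)."""
    a, b = np.asarray(values1, float), np.asarray(values2, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.all(d == 0):
        return {"t": 0.0, "df": len(a) - 1, "p": 1.0}
    res = sp_stats.ttest_rel(a, b)
    return {"t": float(res.statistic), "df": len(a) - 1, "p": float(res.pvalue)}
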