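"""Statistical inference chain: correlations, PCA diagnostics, regression.

The cohort analysis mirrors the classical morphology-to-strength
workflow: Pearson correlations of every morphological parameter with
the fracture strength of each load case (two-tailed t test, α = 0.05,
no multiplicity correction by default), a principal component analysis
of the significantly correlated parameters (correlation-matrix PCA,
Kaiser criterion eigenvalue > 1, Kaiser–Meyer–Olkin sampling adequacy
and Bartlett sphericity as preconditions), and an ordinary
least-squares regression of strength on the standardized component
scores.  With standardized orthogonal scores the regression intercept
equals the cohort-mean strength and each coefficient is independent of
which other components are included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, UndefinedStatisticError

__all__ = [
    "pearson_with_p", "correlation_table", "pca_with_diagnostics",
    "regress_on_pcs", "PCABlock", "RegressionBlock", "StatsReport",
    "run_stats_chain",
]


def pearson_with_p(x: Sequence[float], y: Sequence[float]
                   ) -> Tuple[float, float]:
    """Product-moment correlation with the two-tailed t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ConfigurationError("correlation requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError(
            "correlation undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return r, float(p)


def correlation_table(table: pd.DataFrame, response: str,
                      predictors: Sequence[str]) -> pd.DataFrame:
    """Pearson r and p of each predictor against one response column."""
    rows = []
    for name in predictors:
        r, p = pearson_with_p(table[name].to_numpy(),
                              table[response].to_numpy())
        rows.append({"parameter": name, "r": r, "p": p})
    return pd.DataFrame(rows).set_index("parameter")


@dataclass
class PCABlock:
    """Correlation-matrix PCA with retention and adequacy diagnostics."""

    variables: List[str]
    eigenvalues: np.ndarray           # all p eigenvalues, descending
    pct_variance: np.ndarray
    cum_pct_variance: np.ndarray
    n_retained: int
    loadings: pd.DataFrame            # variables x retained PCs
    scores: np.ndarray                # n x retained, standardized (SD 1)
    kmo: Optional[float]
    bartlett_chi2: Optional[float]
    bartlett_df: int
    bartlett_p: Optional[float]


def _kmo(R: np.ndarray) -> float:
    """Kaiser–Meyer–Olkin measure from anti-image partial correlations."""
    Rinv = np.linalg.inv(R)
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    partial = -Rinv / d
    off = ~np.eye(len(R), dtype=bool)
    r2 = (R[off] ** 2).sum()
    p2 = (partial[off] ** 2).sum()
    return float(r2 / (r2 + p2))


def pca_with_diagnostics(table: pd.DataFrame, variables: Sequence[str],
                         eigen_threshold: float = 1.0) -> PCABlock:
    """PCA of the correlation matrix of the selected columns.

    Columns are standardized; components with eigenvalue above the
    Kaiser threshold are retained; loadings are eigenvectors scaled by
    the square root of their eigenvalue; scores are standardized to
    unit variance.  KMO and Bartlett are computed when the correlation
    matrix is invertible (otherwise left as None, PCA still returned).
    """
    variables = list(variables)
    if len(variables) < 2:
        raise ConfigurationError("PCA requires at least two variables")
    X = table[variables].to_numpy(dtype=float)
    n, p = X.shape
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise UndefinedStatisticError("zero-variance variable in PCA input")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    # deterministic sign: dominant loading positive
    for k in range(p):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    pct = evals / p * 100.0
    cum = np.cumsum(pct)
    n_ret = int(np.sum(evals > eigen_threshold))
    load = evecs[:, :n_ret] * np.sqrt(evals[:n_ret])[None, :]
    if n_ret:
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = Z @ evecs[:, :n_ret] / np.sqrt(evals[:n_ret])[None, :]
        # normalise to sample SD exactly 1
        scores = scores / scores.std(axis=0, ddof=1)[None, :]
    else:
        scores = np.empty((n, 0))
    kmo = chi2 = bart_p = None
    df = p * (p - 1) // 2
    det = np.linalg.det(R)
    if det > 1e-12:
        kmo = _kmo(R)
        chi2 = -(n - 1 - (2 * p + 5) / 6.0) * math.log(det)
        bart_p = float(sps.chi2.sf(chi2, df))
    loadings = pd.DataFrame(
        load, index=variables,
        columns=[f"PC-{k + 1}" for k in range(n_ret)])
    return PCABlock(
        variables=variables, eigenvalues=evals, pct_variance=pct,
        cum_pct_variance=cum, n_retained=n_ret, loadings=loadings,
        scores=scores, kmo=kmo, bartlett_chi2=chi2, bartlett_df=df,
        bartlett_p=bart_p,
    )


@dataclass
class RegressionBlock:
    """OLS of strength on standardized component scores."""

    intercept: float
    intercept_se: float
    intercept_p: float
    coef: pd.DataFrame            # per PC: B, SE, beta, p
    model_r: float
    model_p: float
    see: float                    # standard error of the estimate
    n: int


def regress_on_pcs(scores: np.ndarray, y: Sequence[float],
                   names: Optional[Sequence[str]] = None) -> RegressionBlock:
    """Ordinary least squares of ``y`` on PC scores (with intercept).

    ``beta`` is the standardized coefficient B·SD(score)/SD(y); the
    model p-value comes from the overall F statistic; SEE is the
    residual standard deviation at n − k − 1 degrees of freedom.
    """
    S = np.atleast_2d(np.asarray(scores, dtype=float))
    if S.shape[0] == 1 and S.size > S.shape[1]:
        S = S.T
    y = np.asarray(y, dtype=float)
    n, k = S.shape
    if len(y) != n:
        raise ConfigurationError("scores and response lengths differ")
    if n <= k + 1:
        raise ConfigurationError("regression requires n > k + 1")
    X = np.column_stack([np.ones(n), S])
    rank = np.linalg.matrix_rank(X)
    if rank < k + 1:
        raise ConfigurationError("collinear scores: design is rank deficient")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ssr = float(resid @ resid)
    dof = n - k - 1
    see = math.sqrt(ssr / dof)
    XtX_inv = np.linalg.inv(X.T @ X)
    se = see * np.sqrt(np.diag(XtX_inv))
    sdy = y.std(ddof=1)
    sy = S.std(axis=0, ddof=1)
    beta = coef[1:] * sy / sdy if sdy > 0 else np.zeros(k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, coef / se, 0.0)
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df=dof)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    r2 = max(0.0, min(1.0, r2))
    if sst > 0 and ssr < sst and k > 0 and ssr > 0:
        F = (sst - ssr) / k / (ssr / dof)
        model_p = float(sps.f.sf(F, k, dof))
    elif sst == 0 or ssr == 0:
        model_p = 0.0 if sst > 0 else 1.0
    else:
        model_p = 1.0
    names = list(names) if names is not None else [
        f"PC-{i + 1}" for i in range(k)]
    coef_df = pd.DataFrame({
        "B": coef[1:], "SE": se[1:], "beta": beta, "p": pvals[1:],
    }, index=names)
    return RegressionBlock(
        intercept=float(coef[0]), intercept_se=float(se[0]),
        intercept_p=float(pvals[0]), coef=coef_df,
        model_r=math.sqrt(r2), model_p=model_p, see=see, n=n,
    )


@dataclass
class StatsReport:
    """Full inference chain output for one cohort."""

    correlations: Dict[str, pd.DataFrame]      # per load case
    significant: Dict[str, List[str]]
    pca: Dict[str, Optional[PCABlock]]
    pca_skip_reason: Dict[str, Optional[str]]
    regression: Dict[str, Optional[RegressionBlock]]
    alpha: float


def run_stats_chain(table: pd.DataFrame, morphology_columns: Sequence[str],
                    strength_columns: Sequence[str], alpha: float = 0.05,
                    holm: bool = False) -> StatsReport:
    """Correlations → PCA of significant parameters → regression on PCs.

    PCA (and the subsequent regression) is run per load case only when
    at least two parameters correlate significantly with that case's
    strength, mirroring how sparse stumbling correlations make a PCA
    inappropriate.  ``holm`` applies a Holm step-down correction to the
    per-case correlation p-values before the significance cut (off by
    default).
    """
    if table.isna().any().any():
        raise ConfigurationError("cohort table contains missing values")
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    correlations: Dict[str, pd.DataFrame] = {}
    significant: Dict[str, List[str]] = {}
    pca: Dict[str, Optional[PCABlock]] = {}
    skip: Dict[str, Optional[str]] = {}
    regression: Dict[str, Optional[RegressionBlock]] = {}
    for case in strength_columns:
        corr = correlation_table(table, case, morphology_columns)
        if holm:
            order = np.argsort(corr["p"].to_numpy())
            m = len(corr)
            adj = corr["p"].to_numpy().copy()
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (m - rank) * adj[idx])
                adj[idx] = min(1.0, running)
            corr["p_adjusted"] = adj
            pcol = "p_adjusted"
        else:
            pcol = "p"
        correlations[case] = corr
        sig = corr.index[corr[pcol] <= alpha].tolist()
        significant[case] = sig
        if len(sig) < 2:
            pca[case] = None
            regression[case] = None
            skip[case] = (
                f"only {len(sig)} parameter(s) correlated significantly "
                f"with {case} strength (alpha={alpha:g}); PCA not appropriate")
            continue
        block = pca_with_diagnostics(table, sig)
        pca[case] = block
        skip[case] = None
        if block.n_retained == 0:
            regression[case] = None
            skip[case] = ("no component exceeded the Kaiser eigenvalue "
                          "threshold; regression skipped")
            continue
        regression[case] = regress_on_pcs(
            block.scores, table[case].to_numpy(),
            names=list(block.loadings.columns))
    return StatsReport(
        correlations=correlations, significant=significant, pca=pca,
        pca_skip_reason=skip, regression=regression, alpha=alpha,
    )
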