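"""Model fitting: adjusted odds ratios, multiplicative interaction LRTs,
ANCOVA group comparisons, and the nonparametric tests used on severity data.

Logistic models are maximum-likelihood fits by iteratively reweighted least
squares (statsmodels GLM with a binomial family); frequency weights let the
grouped contingency-cell representation reproduce the closed-form odds
ratios exactly. The multiplicative gene-environment interaction test is a
likelihood-ratio test between nested logistic models with and without the
G x E product term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelSpec",
    "LogisticFit",
    "SeparationError",
    "fit_logistic",
    "likelihood_ratio_test",
    "interaction_test",
    "ancova_compare",
    "mann_whitney",
    "spearman",
]

_SEPARATION_BETA = 15.0  # |log-odds| beyond this flags (quasi-)separation


class SeparationError(RuntimeError):
    """Raised when a logistic fit diverges (perfect or quasi separation)."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model: response column, main-effect terms, optional
    interaction pairs (added as product columns), optional frequency weights."""

    response: str
    terms: tuple[str, ...] | list[str]
    interactions: tuple[tuple[str, str], ...] | list[tuple[str, str]] = ()
    weights: str | None = None

    def __post_init__(self) -> None:
        terms = tuple(self.terms)
        inter = tuple(tuple(p) for p in self.interactions)
        if len(set(terms)) != len(terms):
            raise ValueError("duplicate main-effect terms")
        for a, b in inter:
            if a not in terms or b not in terms:
                raise ValueError(f"interaction ({a}, {b}) members must appear as main effects")
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "interactions", inter)

    @property
    def columns(self) -> list[str]:
        return list(self.terms) + [f"{a}:{b}" for a, b in self.interactions]


@dataclass(frozen=True)
class LogisticFit:
    """Converged logistic-regression fit: log-odds coefficients, their
    covariance, the (frequency-weighted) log-likelihood, and bookkeeping."""

    coefficients: pd.Series
    covariance: pd.DataFrame
    loglik: float
    n_iter: int
    converged: bool
    n_obs: float
    spec: ModelSpec = field(compare=False, default=None)

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        se = np.sqrt(np.diag(self.covariance))
        beta = self.coefficients.to_numpy()
        return pd.DataFrame(
            {
                "or": np.exp(beta),
                "ci_low": np.exp(beta - z * se),
                "ci_high": np.exp(beta + z * se),
                "p": 2 * stats.norm.sf(np.abs(beta / se)),
            },
            index=self.coefficients.index,
        )


def _design(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.Series, pd.DataFrame, np.ndarray]:
    missing = [c for c in (spec.response, *spec.terms) if c not in data.columns]
    if spec.weights and spec.weights not in data.columns:
        missing.append(spec.weights)
    if missing:
        raise KeyError(f"columns missing from data: {missing}")
    y = data[spec.response].astype(float)
    X = pd.DataFrame({"const": np.ones(len(data))}, index=data.index)
    for t in spec.terms:
        X[t] = pd.to_numeric(data[t])
    for a, b in spec.interactions:
        X[f"{a}:{b}"] = X[a] * X[b]
    w = data[spec.weights].to_numpy(dtype=float) if spec.weights else np.ones(len(data))
    if (w <= 0).any():
        raise ValueError("frequency weights must be positive")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns by finding which drop restores full rank
        collinear = []
        for col in X.columns[1:]:
            sub = X.drop(columns=[col]).to_numpy()
            if np.linalg.matrix_rank(sub) == rank:
                collinear.append(col)
        raise ValueError(f"design matrix is rank deficient; collinear terms: {collinear or list(X.columns)}")
    return y, X, w


def fit_logistic(data: pd.DataFrame, spec: ModelSpec, tol: float = 1e-8, maxiter: int = 100) -> LogisticFit:
    """ML logistic fit by IRLS on individual-level or grouped (weighted) data.

    The response must be binary 0/1.  With a frequency-weight column, each
    row stands for `w` identical subjects, so grouped contingency-cell data
    give the same estimates (and log-likelihood up to the weighting) as the
    expanded individual-level table.
    """
    y, X, w = _design(data, spec)
    vals = set(np.unique(y))
    if not vals <= {0.0, 1.0}:
        raise ValueError(f"response must be binary 0/1, saw values {sorted(vals)}")
    model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
    res = model.fit(maxiter=maxiter, tol=tol)
    beta = res.params
    if not np.isfinite(beta).all() or np.abs(beta).max() > _SEPARATION_BETA:
        raise SeparationError(
            "logistic fit diverged (|beta| > "
            f"{_SEPARATION_BETA}); data are likely perfectly separated: {beta.to_dict()}"
        )
    n_iter = getattr(res, "fit_history", {}).get("iteration", maxiter)
    return LogisticFit(
        coefficients=beta,
        covariance=pd.DataFrame(res.cov_params(), index=beta.index, columns=beta.index),
        loglik=float(res.llf),
        n_iter=int(n_iter),
        converged=bool(res.converged),
        n_obs=float(w.sum()),
        spec=spec,
    )


def likelihood_ratio_test(full: LogisticFit, reduced: LogisticFit) -> tuple[float, int, float]:
    """LRT between nested logistic fits: chi2 = 2*(ll_full - ll_reduced)."""
    full_cols = set(full.coefficients.index)
    red_cols = set(reduced.coefficients.index)
    if not red_cols < full_cols:
        raise ValueError("models are not nested (reduced terms must be a strict subset)")
    if not (full.converged and reduced.converged):
        raise ValueError("both fits must have converged")
    df = len(full_cols) - len(red_cols)
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return chi2, df, float(stats.chi2.sf(chi2, df))


@dataclass(frozen=True)
class InteractionResult:
    p_value: float
    chi2: float
    df: int
    or_interaction: float
    ci95: tuple[float, float]
    full: LogisticFit
    reduced: LogisticFit


def interaction_test(
    data: pd.DataFrame,
    response: str,
    g: str,
    e: str,
    covariates: list[str] | tuple[str, ...] = (),
    weights: str | None = None,
    alpha: float = 0.05,
) -> InteractionResult:
    """Multiplicative G x E interaction: LRT of the product term in a
    logistic model of `response` on `g`, `e` (and covariates).

    Returns the LRT p-value together with the interaction odds ratio
    exp(beta_GxE) and its Wald CI from the full model.
    """
    w = data[weights] if weights else pd.Series(1.0, index=data.index)
    for col in (g, e):
        cells = data.assign(_w=w.to_numpy()).groupby([response, col], observed=True)["_w"].sum()
        if len(cells) < 4 or (cells <= 0).any():
            raise ValueError(f"degenerate outcome-by-{col!r} cell: {cells.to_dict()}")
    terms = [g, e, *covariates]
    reduced = fit_logistic(data, ModelSpec(response, terms, weights=weights))
    full = fit_logistic(data, ModelSpec(response, terms, interactions=[(g, e)], weights=weights))
    chi2, df, p = likelihood_ratio_test(full, reduced)
    key = f"{g}:{e}"
    beta = full.coefficients[key]
    se = math.sqrt(full.covariance.loc[key, key])
    z = stats.norm.ppf(1 - alpha / 2)
    return InteractionResult(
        p_value=p, chi2=chi2, df=df,
        or_interaction=math.exp(beta),
        ci95=(math.exp(beta - z * se), math.exp(beta + z * se)),
        full=full, reduced=reduced,
    )


def ancova_compare(
    data: pd.DataFrame,
    outcome: str,
    group: str,
    covariates: list[str] | tuple[str, ...] = (),
) -> dict:
    """ANCOVA comparison of group means adjusted for covariates.

    Ordinary least squares of `outcome` on group dummies plus covariates;
    the group effect is a partial F-test against the covariate-only model,
    and adjusted means are model predictions at the grand covariate means.
    """
    y = pd.to_numeric(data[outcome])
    if y.nunique() < 2:
        raise ValueError("outcome is constant")
    groups = pd.Categorical(data[group])
    if len(groups.categories) < 2:
        raise ValueError("need at least two groups")
    dummies = pd.get_dummies(pd.Series(groups, index=data.index), drop_first=True, prefix=group, dtype=float)
    X_cov = pd.DataFrame({"const": np.ones(len(data))}, index=data.index)
    for c in covariates:
        X_cov[c] = pd.to_numeric(data[c])
    X_full = pd.concat([X_cov, dummies], axis=1)
    full = sm.OLS(y, X_full).fit()
    reduced = sm.OLS(y, X_cov).fit()
    f_stat, p, df_diff = full.compare_f_test(reduced)
    cov_means = {c: float(pd.to_numeric(data[c]).mean()) for c in covariates}
    adjusted = {}
    for level in groups.categories:
        row = {"const": 1.0, **cov_means}
        for dcol in dummies.columns:
            row[dcol] = 1.0 if dcol == f"{group}_{level}" else 0.0
        adjusted[level] = float(full.predict(pd.DataFrame([row])[X_full.columns]).iloc[0])
    return {
        "adjusted_means": adjusted,
        "f_stat": float(f_stat),
        "df": (int(df_diff), int(full.df_resid)),
        "p_value": float(p),
        "fit": full,
    }


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when n_x * n_y <= 400 and there are no cross-sample
    ties; otherwise the tie-corrected normal approximation with continuity
    correction.  Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
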