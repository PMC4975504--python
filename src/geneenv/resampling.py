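"""Monte-Carlo permutation empirical p-values for genotype tables, and
Bonferroni multiple-testing control.

The permutation null fixes both margins of the 2x3 case/control genotype
table — the genotype column totals and the case/control row totals — and
redistributes genotype counts between the rows.  Drawing the case row from
a multivariate hypergeometric distribution is distributionally identical to
shuffling case/control labels over subjects but costs O(1) per permutation
instead of O(n).  The empirical p uses the (b + 1) / (m + 1) estimator, so
it is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assoc import GENETIC_MODELS, GenotypeTable

__all__ = [
    "PermutationPlan",
    "EmpiricalPResult",
    "empirical_p",
    "exact_permutation_p",
    "bonferroni",
]


@dataclass(frozen=True)
class PermutationPlan:
    """How to permute: number of resamples, RNG seed, and which
    genetic-model statistic to track."""

    n_permutations: int = 100_000
    seed: int = 0
    statistic: str = "allelic"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")
        if self.statistic not in GENETIC_MODELS:
            raise ValueError(f"statistic must be one of {GENETIC_MODELS}, got {self.statistic!r}")


@dataclass(frozen=True)
class EmpiricalPResult:
    p_value: float
    observed: float
    exceedances: int
    n_permutations: int
    seed: int
    statistic: str


def _chi2_2x2(a, b, c, d):
    """Vectorized Pearson chi-square for 2x2 tables (no continuity correction)."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(den > 0, num / den, 0.0)
    return chi2


def _model_statistic(case_rows: np.ndarray, ctrl_rows: np.ndarray, statistic: str) -> np.ndarray:
    """Chi-square statistic for each permuted table (rows GG/AG/AA).

    allelic/dominant/recessive: Pearson chi-square on the recoded 2x2;
    additive: Cochran-Armitage trend chi-square on dosage 0/1/2 (the score
    statistic of the dosage logistic model).
    """
    cg, ca, caa = case_rows[..., 0], case_rows[..., 1], case_rows[..., 2]
    kg, ka, kaa = ctrl_rows[..., 0], ctrl_rows[..., 1], ctrl_rows[..., 2]
    if statistic == "allelic":
        return _chi2_2x2(2 * caa + ca, 2 * cg + ca, 2 * kaa + ka, 2 * kg + ka)
    if statistic == "dominant":
        return _chi2_2x2(ca + caa, cg, ka + kaa, kg)
    if statistic == "recessive":
        return _chi2_2x2(caa, cg + ca, kaa, kg + ka)
    if statistic == "additive":
        dose = np.array([0.0, 1.0, 2.0])
        r = case_rows.sum(axis=-1, dtype=float)
        tot = case_rows + ctrl_rows
        n = tot.sum(axis=-1, dtype=float)
        t_obs = (case_rows * dose).sum(axis=-1)
        col_dose = (tot * dose).sum(axis=-1)
        col_dose2 = (tot * dose**2).sum(axis=-1)
        mean_t = r * col_dose / n
        var_t = r * (n - r) / (n - 1) * (col_dose2 / n - (col_dose / n) ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(var_t > 0, (t_obs - mean_t) ** 2 / var_t, 0.0)
        return chi2
    raise ValueError(f"unknown statistic {statistic!r}")


def empirical_p(g: GenotypeTable, plan: PermutationPlan) -> EmpiricalPResult:
    """Monte-Carlo empirical p-value with both table margins held fixed.

    p = (1 + #{permuted statistic >= observed}) / (1 + n_permutations).
    """
    col_totals = g.counts.sum(axis=0)
    n_cases = g.n_cases
    if (col_totals > 0).sum() < 2 or n_cases == 0 or g.n_controls == 0:
        raise ValueError("degenerate margins: need two genotype columns and both rows populated")
    observed = float(_model_statistic(g.counts[0][None, :], g.counts[1][None, :], plan.statistic)[0])
    rng = np.random.default_rng(plan.seed)
    case_rows = rng.multivariate_hypergeometric(col_totals, n_cases, size=plan.n_permutations)
    ctrl_rows = col_totals[None, :] - case_rows
    perm_stats = _model_statistic(case_rows, ctrl_rows, plan.statistic)
    b = int((perm_stats >= observed - 1e-12).sum())
    p = (1 + b) / (1 + plan.n_permutations)
    return EmpiricalPResult(p_value=p, observed=observed, exceedances=b,
                            n_permutations=plan.n_permutations, seed=plan.seed,
                            statistic=plan.statistic)


def exact_permutation_p(g: GenotypeTable, statistic: str) -> float:
    """Exhaustive fixed-margin permutation p-value (small tables only).

    Enumerates every case row compatible with the margins, weights each by
    its multivariate hypergeometric probability, and sums the probability
    of statistics >= the observed one.  Intended as an oracle for
    :func:`empirical_p` on desk-size tables.
    """
    col = g.counts.sum(axis=0)
    n_cases = g.n_cases
    rows = []
    for gg in range(min(col[0], n_cases) + 1):
        for ag in range(min(col[1], n_cases - gg) + 1):
            aa = n_cases - gg - ag
            if 0 <= aa <= col[2]:
                rows.append((gg, ag, aa))
    case_rows = np.array(rows)
    ctrl_rows = col[None, :] - case_rows
    # multivariate hypergeometric pmf: product of per-column binomials over
    # the total binomial
    from scipy.special import gammaln

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    logw = (
        log_comb(col[0], case_rows[:, 0])
        + log_comb(col[1], case_rows[:, 1])
        + log_comb(col[2], case_rows[:, 2])
        - log_comb(col.sum(), n_cases)
    )
    w = np.exp(logw - logw.max())
    w /= w.sum()
    stats_all = _model_statistic(case_rows, ctrl_rows, statistic)
    observed = float(_model_statistic(g.counts[0][None, :], g.counts[1][None, :], statistic)[0])
    return float(w[stats_all >= observed - 1e-12].sum())


def bonferroni(p_values, m: int | None = None, alpha: float = 0.05):
    """Bonferroni adjustment: adjusted p = min(1, m*p); flags at alpha/m.

    ``m`` defaults to the number of p-values; an ``m`` smaller than the
    number of tests is rejected (it would under-correct).
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} is smaller than the number of tests ({p.size})")
    adjusted = np.minimum(1.0, m * p)
    return adjusted, p < alpha / m, alpha / m
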