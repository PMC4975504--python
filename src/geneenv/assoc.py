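"""Contingency-table association statistics for a single biallelic SNP.

Case-control genotype counts (GG / AG / AA, with G the major and A the
minor allele) are the unit of analysis.  This module covers allelic and
genotypic recoding under the classical genetic models, odds ratios with
Woolf confidence intervals and Wald p-values, Hardy-Weinberg equilibrium
testing, minor-allele frequencies, Breslow-Day homogeneity of stratified
odds ratios, pooling of study stages, and the two-proportion power
calculation used to size a case-control comparison of allele frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GENOTYPES",
    "GENETIC_MODELS",
    "GenotypeTable",
    "TwoByTwo",
    "AssocResult",
    "allele_table",
    "recode_model",
    "odds_ratio",
    "pearson_chi2",
    "additive_trend",
    "hwe_test",
    "minor_allele_frequency",
    "breslow_day",
    "pool_strata",
    "inverse_variance_pool",
    "power_two_proportions",
]

#: Genotype column order used everywhere: major homozygote, heterozygote,
#: minor homozygote.
GENOTYPES = ("GG", "AG", "AA")

GENETIC_MODELS = ("allelic", "additive", "dominant", "recessive")


@dataclass(frozen=True)
class GenotypeTable:
    """2x3 case/control genotype counts, rows (case, control) x (GG, AG, AA)."""

    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (2, 3):
            raise ValueError(f"counts must be 2x3 (case/control x GG/AG/AA), got {c.shape}")
        if (c < 0).any():
            raise ValueError("genotype counts must be nonnegative")
        if (c.sum(axis=1) < 1).any():
            raise ValueError("each of the case and control rows must contain at least one subject")
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_rows(cls, cases: Sequence[int], controls: Sequence[int], label: str = "") -> "GenotypeTable":
        return cls(np.array([cases, controls]), label=label)

    @property
    def cases(self) -> np.ndarray:
        return self.counts[0]

    @property
    def controls(self) -> np.ndarray:
        return self.counts[1]

    @property
    def n_cases(self) -> int:
        return int(self.counts[0].sum())

    @property
    def n_controls(self) -> int:
        return int(self.counts[1].sum())


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 table: a/b = case exposed/unexposed, c/d = control exposed/unexposed."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def swapped_rows(self) -> "TwoByTwo":
        return TwoByTwo(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class AssocResult:
    """Odds-ratio estimate with 95% CI and p-value under a genetic model."""

    or_estimate: float
    ci95: tuple[float, float]
    p_value: float
    method: str
    model: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.or_estimate <= hi):
            raise ValueError("point estimate must lie inside its CI")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def allele_table(g: GenotypeTable) -> TwoByTwo:
    """Collapse genotype counts to per-allele counts (exposure = minor allele A).

    Each subject contributes two alleles: AA contributes two A, AG one of
    each, GG two G.
    """
    case_a = 2 * g.cases[2] + g.cases[1]
    case_g = 2 * g.cases[0] + g.cases[1]
    ctrl_a = 2 * g.controls[2] + g.controls[1]
    ctrl_g = 2 * g.controls[0] + g.controls[1]
    return TwoByTwo(int(case_a), int(case_g), int(ctrl_a), int(ctrl_g))


def recode_model(g: GenotypeTable, model: str) -> TwoByTwo:
    """Recode genotypes under a dominant (AG+AA vs GG) or recessive (AA vs AG+GG) model."""
    if model == "dominant":
        return TwoByTwo(
            int(g.cases[1] + g.cases[2]), int(g.cases[0]),
            int(g.controls[1] + g.controls[2]), int(g.controls[0]),
        )
    if model == "recessive":
        return TwoByTwo(
            int(g.cases[2]), int(g.cases[0] + g.cases[1]),
            int(g.controls[2]), int(g.controls[0] + g.controls[1]),
        )
    raise ValueError(f"unknown genetic model {model!r}; expected 'dominant' or 'recessive'")


def odds_ratio(t: TwoByTwo, alpha: float = 0.05, model: str = "") -> AssocResult:
    """Cross-product odds ratio with Woolf CI and two-sided Wald p-value.

    If any cell is zero the Haldane-Anscombe continuity correction (+0.5 to
    every cell) is applied before taking logs.
    """
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise ValueError("odds ratio undefined: a table row is empty")
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    log_or = math.log(or_est)
    ci = (math.exp(log_or - z * se), math.exp(log_or + z * se))
    wald_z = log_or / se
    p = 2 * stats.norm.sf(abs(wald_z))
    return AssocResult(or_est, ci, float(p), method="wald", model=model,
                       extras={"log_or": log_or, "se": se, "z": wald_z})


def pearson_chi2(t: TwoByTwo) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table."""
    arr = t.as_array()
    if arr.sum() == 0:
        raise ValueError("empty table")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), float(p)


def additive_trend(g: GenotypeTable, alpha: float = 0.05) -> AssocResult:
    """Per-allele odds ratio from a logistic fit on dosage-coded (0/1/2) genotypes.

    Fits case status ~ dosage on the grouped six-cell data with frequency
    weights; the exponentiated slope is the additive-model OR.
    """
    present = g.counts.sum(axis=0) > 0
    if np.unique(np.nonzero(present)[0]).size < 2:
        raise ValueError("additive trend undefined: only one genotype present")
    import pandas as pd

    from .regression import ModelSpec, fit_logistic

    rows = []
    for status, row in zip((1, 0), g.counts):
        for dose, n in zip((0, 1, 2), row):
            if n > 0:
                rows.append({"case": status, "dosage": dose, "w": int(n)})
    data = pd.DataFrame(rows)
    fit = fit_logistic(data, ModelSpec(response="case", terms=["dosage"], weights="w"))
    beta = fit.coefficients["dosage"]
    se = math.sqrt(fit.covariance.loc["dosage", "dosage"])
    z = stats.norm.ppf(1 - alpha / 2)
    ci = (math.exp(beta - z * se), math.exp(beta + z * se))
    p = 2 * stats.norm.sf(abs(beta / se))
    return AssocResult(math.exp(beta), ci, float(p), method="trend", model="additive",
                       extras={"log_or": beta, "se": se})


def hwe_test(genotype_counts: Sequence[int]) -> tuple[float, float]:
    """Pearson chi-square test of Hardy-Weinberg proportions (1 df).

    ``genotype_counts`` is (n_GG, n_AG, n_AA).  Expected counts come from
    the sample allele frequency: n*(p^2, 2pq, q^2).
    """
    n_gg, n_ag, n_aa = (int(x) for x in genotype_counts)
    n = n_gg + n_ag + n_aa
    if n < 1:
        raise ValueError("HWE test needs at least one subject")
    q = (2 * n_aa + n_ag) / (2 * n)
    p = 1 - q
    expected = np.array([n * p * p, n * 2 * p * q, n * q * q])
    observed = np.array([n_gg, n_ag, n_aa], dtype=float)
    if q in (0.0, 1.0):
        return 0.0, 1.0  # monomorphic sample is vacuously in HWE
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def minor_allele_frequency(g: GenotypeTable, group: str) -> float:
    """Minor (A) allele frequency in the case or control row."""
    if group == "case":
        row = g.cases
    elif group == "control":
        row = g.controls
    else:
        raise ValueError(f"group must be 'case' or 'control', got {group!r}")
    total = 2 * row.sum()
    if total == 0:
        raise ValueError(f"{group} group is empty")
    return float((2 * row[2] + row[1]) / total)


def breslow_day(strata: Sequence[TwoByTwo], tarone: bool = True) -> tuple[float, int, float]:
    """Breslow-Day homogeneity test of odds ratios across 2x2 strata.

    Tests every stratum's OR against the Mantel-Haenszel common OR; with
    ``tarone=True`` (default) the Tarone correction is applied.  Returns
    (chi2, df, p) with df = #strata - 1.
    """
    if len(strata) < 2:
        raise ValueError("Breslow-Day needs at least two strata")
    for i, t in enumerate(strata):
        if t.a + t.b == 0 or t.c + t.d == 0:
            raise ValueError(f"stratum {i} has an empty row")
    import statsmodels.stats.contingency_tables as ct

    tables = np.stack([t.as_array() for t in strata], axis=-1)
    res = ct.StratifiedTable(tables).test_equal_odds(adjust=tarone)
    df = len(strata) - 1
    return float(res.statistic), df, float(res.pvalue)


def pool_strata(strata: Sequence[GenotypeTable], label: str = "merged") -> GenotypeTable:
    """Element-wise sum of genotype tables (two-stage 'merged set' counts)."""
    if not strata:
        raise ValueError("nothing to pool")
    total = np.sum([g.counts for g in strata], axis=0)
    return GenotypeTable(total, label=label)


def inverse_variance_pool(results: Sequence[AssocResult], alpha: float = 0.05) -> AssocResult:
    """Fixed-effect inverse-variance combination of log odds ratios.

    Provided as an explicitly labeled alternative to count pooling; the
    primary "merged set" analysis sums the stratum counts.
    """
    logs = np.array([r.extras["log_or"] for r in results])
    ses = np.array([r.extras["se"] for r in results])
    w = 1.0 / ses**2
    pooled = float((w * logs).sum() / w.sum())
    se = float(1.0 / math.sqrt(w.sum()))
    z = stats.norm.ppf(1 - alpha / 2)
    p = 2 * stats.norm.sf(abs(pooled / se))
    return AssocResult(math.exp(pooled), (math.exp(pooled - z * se), math.exp(pooled + z * se)),
                       float(p), method="inverse_variance", model=results[0].model,
                       extras={"log_or": pooled, "se": se})


def power_two_proportions(p1: float, p2: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample proportion z-test (no continuity correction).

    power = Phi((|p1 - p2| - z_{alpha/2} * SE0) / SE1) with SE0 the pooled
    null standard error and SE1 the unpooled alternative standard error;
    n1, n2 are per-group subject counts.
    """
    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise ValueError("proportions must lie in (0, 1)")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be at least 2")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    se0 = math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    se1 = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    z = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf((abs(p1 - p2) - z * se0) / se1))
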