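"""Synthetic case-control cohorts with gene-environment structure.

The generator emulates a retrospective two-stage case-control study of a
single biallelic SNP (major allele G, minor allele A): a large source
population is simulated with Hardy-Weinberg genotypes and Bernoulli risk
factors, disease status is drawn from a logistic model whose linear
predictor carries a genotype effect (under a configurable genetic model),
covariate effects, and multiplicative G x E product terms, and the
requested numbers of cases and controls are then sampled without
replacement — preserving the odds-ratio (rather than risk-ratio)
interpretation of the embedded effects.  Cases additionally receive a
right-skewed (log-normal) angiographic severity score with a
multiplicative shift for risk-genotype carriers, and per-case coronary
lesion sets can be emitted whose computed modified Gensini scores follow
that severity distribution.

Defaults reproduce the study conditions of a central-Chinese CAD cohort:
2317 cases / 2404 controls, control minor-allele frequency 0.306, dominant
genotype OR 1.28, G x E interaction ORs of roughly 1.4-1.6 for T2DM,
hyperlipidemia and high BMI, and case severity scores with median 30.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .gensini import SEGMENT_MULTIPLIERS, stenosis_points

__all__ = ["CohortConfig", "simulate_genotypes", "simulate_cohort", "simulate_lesions"]

GENOTYPE_LEVELS = ("GG", "AG", "AA")

#: Default covariate prevalences (control margins of the study population).
_DEFAULT_PREVALENCES = {
    "smoking": 0.278,
    "drinking": 0.243,
    "t2dm": 0.255,
    "hyperlipidemia": 0.228,
    "hypertension": 0.373,
    "bmi_gt25": 0.379,
}

#: Default covariate main-effect ORs: standard epidemiological effect sizes
#: for conventional CAD risk factors (the source tables print only
#: stratified genotype ORs, not covariate main effects).
_DEFAULT_COVARIATE_ORS = {
    "smoking": 1.5,
    "drinking": 1.2,
    "t2dm": 2.0,
    "hyperlipidemia": 2.0,
    "hypertension": 1.8,
    "bmi_gt25": 1.4,
}

#: Default G x E interaction ORs, the ratios of the stratified dominant
#: genotype ORs (exposed / unexposed strata) in the study.
_DEFAULT_INTERACTION_ORS = {
    "t2dm": 1.46,
    "hyperlipidemia": 1.55,
    "bmi_gt25": 1.37,
}


@dataclass
class CohortConfig:
    """Parameters of the simulated study population.

    All odds ratios are multiplicative effects on disease odds; genotype
    coding follows ``model`` (dominant: carriers of A vs GG; additive: A
    dosage 0/1/2; recessive: AA vs carriers of G).
    """

    n_cases: int = 2317
    n_controls: int = 2404
    maf: float = 0.306
    model: str = "dominant"
    genotype_or: float = 1.28
    covariate_prevalences: dict = field(default_factory=lambda: dict(_DEFAULT_PREVALENCES))
    covariate_ors: dict = field(default_factory=lambda: dict(_DEFAULT_COVARIATE_ORS))
    interaction_ors: dict = field(default_factory=lambda: dict(_DEFAULT_INTERACTION_ORS))
    baseline_prevalence: float = 0.08
    gensini_log_mean: float = float(np.log(30.0))
    gensini_log_sd: float = 0.95
    gensini_genotype_shift: float = 1.19
    age_mean: float = 60.0
    age_sd: float = 10.0
    bmi_mean: float = 24.0
    bmi_sd: float = 3.3
    male_fraction: float = 0.55
    occlusion_fraction: float = 0.1
    population_factor: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if not (0.0 < self.maf < 1.0):
            raise ValueError("maf must lie in (0, 1)")
        if self.model not in ("dominant", "additive", "recessive"):
            raise ValueError(f"unknown genetic model {self.model!r}")
        probs = [self.baseline_prevalence, self.male_fraction, self.occlusion_fraction,
                 *self.covariate_prevalences.values()]
        if any(not (0.0 < p < 1.0) for p in probs):
            raise ValueError("all probabilities must lie in (0, 1)")
        ors = [self.genotype_or, self.gensini_genotype_shift,
               *self.covariate_ors.values(), *self.interaction_ors.values()]
        if any(v <= 0 for v in ors):
            raise ValueError("all odds ratios / shifts must be positive")
        unknown = set(self.interaction_ors) - set(self.covariate_prevalences)
        if unknown:
            raise ValueError(f"interaction covariates without prevalences: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return asdict(self)


class GenerationError(RuntimeError):
    """Sampling the requested cases/controls from the simulated population failed."""


def simulate_genotypes(maf: float, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` genotypes i.i.d. in Hardy-Weinberg proportions.

    P(GG, AG, AA) = ((1-q)^2, 2q(1-q), q^2) with q the minor-allele
    frequency.  Returns an array of 'GG'/'AG'/'AA' strings.
    """
    if not (0.0 < maf < 1.0):
        raise ValueError("maf must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    q = maf
    probs = [(1 - q) ** 2, 2 * q * (1 - q), q * q]
    rng = np.random.default_rng(seed)
    idx = rng.choice(3, size=n, p=probs)
    return np.array(GENOTYPE_LEVELS)[idx]


def _code_genotype(genotypes: np.ndarray, model: str) -> np.ndarray:
    dosage = np.select([genotypes == "AG", genotypes == "AA"], [1, 2], default=0)
    if model == "additive":
        return dosage.astype(float)
    if model == "dominant":
        return (dosage >= 1).astype(float)
    if model == "recessive":
        return (dosage == 2).astype(float)
    raise ValueError(model)


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a source population and sample a retrospective case-control cohort.

    The source population is ``population_factor`` times the requested
    cohort size (doubled automatically, up to three times, if it yields too
    few cases or controls).  Disease probability follows
    ``logit(p) = b0 + bG*g + sum(bE*e) + sum(bGE*g*e)`` with every beta the
    log of the configured OR and b0 = logit(baseline_prevalence).

    Returns a subject table with columns subject_id, status (1=case),
    genotype, age, sex, bmi, the binary risk-factor flags, and a ``gensini``
    severity score for cases (NaN for controls).
    """
    rng = np.random.default_rng(config.seed)
    total = config.n_cases + config.n_controls
    factor = config.population_factor
    for _attempt in range(4):
        n_pop = factor * total
        pop = _simulate_population(config, n_pop, rng)
        case_idx = np.flatnonzero(pop["status"].to_numpy() == 1)
        ctrl_idx = np.flatnonzero(pop["status"].to_numpy() == 0)
        if case_idx.size >= config.n_cases and ctrl_idx.size >= config.n_controls:
            break
        factor *= 2
    else:
        raise GenerationError(
            f"simulated population ({n_pop}) produced {case_idx.size} cases / "
            f"{ctrl_idx.size} controls but {config.n_cases}/{config.n_controls} were "
            "requested; increase population_factor or baseline_prevalence"
        )
    chosen = np.concatenate([
        rng.choice(case_idx, size=config.n_cases, replace=False),
        rng.choice(ctrl_idx, size=config.n_controls, replace=False),
    ])
    cohort = pop.iloc[chosen].reset_index(drop=True)
    cohort["subject_id"] = [f"S{i:06d}" for i in range(len(cohort))]

    # right-skewed severity scores for cases, with a carrier/risk-genotype shift
    g = _code_genotype(cohort["genotype"].to_numpy(), config.model)
    mu = config.gensini_log_mean + np.log(config.gensini_genotype_shift) * g
    scores = rng.lognormal(mean=mu, sigma=config.gensini_log_sd)
    cohort["gensini"] = np.where(cohort["status"] == 1, scores, np.nan)
    cols = ["subject_id", "status", "genotype", "age", "sex", "bmi",
            *sorted(config.covariate_prevalences), "gensini"]
    return cohort[cols]


def _simulate_population(config: CohortConfig, n_pop: int, rng: np.random.Generator) -> pd.DataFrame:
    q = config.maf
    geno_idx = rng.choice(3, size=n_pop, p=[(1 - q) ** 2, 2 * q * (1 - q), q * q])
    genotypes = np.array(GENOTYPE_LEVELS)[geno_idx]
    g = _code_genotype(genotypes, config.model)

    pop = pd.DataFrame({"genotype": genotypes})
    pop["age"] = rng.normal(config.age_mean, config.age_sd, size=n_pop).round(1)
    pop["sex"] = np.where(rng.random(n_pop) < config.male_fraction, "male", "female")
    pop["bmi"] = rng.normal(config.bmi_mean, config.bmi_sd, size=n_pop).round(1)

    eta = np.full(n_pop, _logit(config.baseline_prevalence))
    eta += np.log(config.genotype_or) * g
    for name, prev in config.covariate_prevalences.items():
        if name == "bmi_gt25":
            flag = (pop["bmi"].to_numpy() > 25.0).astype(float)
        else:
            flag = (rng.random(n_pop) < prev).astype(float)
        pop[name] = flag.astype(int)
        eta += np.log(config.covariate_ors.get(name, 1.0)) * flag
        eta += np.log(config.interaction_ors.get(name, 1.0)) * g * flag
    p_disease = 1.0 / (1.0 + np.exp(-eta))
    pop["status"] = (rng.random(n_pop) < p_disease).astype(int)
    return pop


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def simulate_lesions(cases: pd.DataFrame, config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Emit per-case coronary lesion sets realizing the cases' severity scores.

    For each case a target score is taken from its ``gensini`` column (or
    drawn from the configured log-normal when absent) and greedily
    decomposed into segment lesions: random segments receive the largest
    stenosis band whose weighted contribution still fits the remaining
    target, so the computed modified Gensini score lands within about one
    point of the target.  A configurable fraction of subjects additionally
    carries one acute total occlusion (contribution = min(multiplier, 5)).

    Returns a table (subject_id, segment, stenosis_pct, acute_occlusion).
    """
    if "status" in cases.columns and (cases["status"] != 1).any():
        raise ValueError("simulate_lesions expects case records only")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    segments = list(SEGMENT_MULTIPLIERS)
    # representative stenosis percent per band, band points 1..32
    band_pcts = [12.0, 40.0, 65.0, 85.0, 95.0, 100.0]
    band_points = [stenosis_points(p) for p in band_pcts]  # 1, 2, 4, 8, 16, 32
    rows: list[dict] = []
    for rec in cases.itertuples(index=False):
        target = getattr(rec, "gensini", np.nan)
        g_code = _code_genotype(np.array([rec.genotype]), config.model)[0]
        if target is None or (isinstance(target, float) and np.isnan(target)):
            mu = config.gensini_log_mean + np.log(config.gensini_genotype_shift) * g_code
            target = float(rng.lognormal(mu, config.gensini_log_sd))
        remaining = float(target)
        subject_rows: list[dict] = []
        used: set[str] = set()
        if rng.random() < config.occlusion_fraction:
            seg = segments[rng.integers(len(segments))]
            contrib = min(SEGMENT_MULTIPLIERS[seg], 5.0)
            if contrib <= remaining:
                subject_rows.append({"subject_id": rec.subject_id, "segment": seg,
                                     "stenosis_pct": 100.0, "acute_occlusion": True})
                remaining -= contrib
                used.add(seg)
        for seg in rng.permutation(segments):
            if remaining < 0.5:
                break
            if seg in used:
                continue
            mult = SEGMENT_MULTIPLIERS[seg]
            fitting = [(pts, pct) for pts, pct in zip(band_points, band_pcts)
                       if pts * mult <= remaining]
            if not fitting:
                continue
            pts, pct = fitting[-1]
            subject_rows.append({"subject_id": rec.subject_id, "segment": seg,
                                 "stenosis_pct": pct, "acute_occlusion": False})
            remaining -= pts * mult
            used.add(seg)
        rows.extend(subject_rows)
    return pd.DataFrame(rows, columns=["subject_id", "segment", "stenosis_pct", "acute_occlusion"])
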