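"""Pipeline orchestration: simulate -> score -> associate -> interact ->
resample -> MDR -> report, with deterministic per-stage seeding.

One global seed fans out to stable per-stage child seeds (via
``numpy.random.SeedSequence`` spawn keys), so enabling or disabling one
stage never shifts another stage's randomness.  Every run writes a
manifest recording the package version, seed, stage list, and input file
hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import (
    GenotypeTable,
    additive_trend,
    allele_table,
    hwe_test,
    minor_allele_frequency,
    odds_ratio,
    recode_model,
)
from .gensini import dichotomize_severity, score_lesion_table
from .io import (
    cohort_to_genotype_table,
    read_cohort,
    read_counts,
    read_lesions,
    write_cohort,
    write_counts,
    write_json,
    write_lesions,
)
from .mdr import entropy_graph, permutation_significance, search_best_models
from .regression import interaction_test, mann_whitney
from .resampling import PermutationPlan, bonferroni, empirical_p
from .synthetic import CohortConfig, simulate_cohort, simulate_lesions

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger("geneenv")

_STAGES = ("simulate", "gensini", "associate", "interact", "resample", "mdr", "report")

_DEFAULT_MDR_FACTORS = ("genotype_dominant", "bmi_gt25", "t2dm", "hyperlipidemia")


@dataclass
class RunConfig:
    """Pipeline run settings; see README for the YAML schema."""

    output_dir: str = "geneenv_run"
    seed: int = 0
    stages: tuple[str, ...] = _STAGES
    cohort_path: str | None = None
    lesion_path: str | None = None
    counts_path: str | None = None
    simulate: dict = field(default_factory=dict)     # CohortConfig overrides
    alpha: float = 0.05
    permutations: int = 100_000
    permutation_statistics: tuple[str, ...] = ("allelic", "additive", "dominant", "recessive")
    interaction_covariates: tuple[str, ...] = ("t2dm", "hyperlipidemia", "bmi_gt25")
    mdr: dict = field(default_factory=dict)          # factors/max_size/folds/repeats/permutations
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; valid: {_STAGES}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        cfg = cls(**{k: v for k, v in (raw or {}).items()})
        for key in ("stages", "permutation_statistics", "interaction_covariates"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


def stage_seed(seed: int, stage: str) -> int:
    """Stable child seed for a stage (independent streams per stage)."""
    idx = _STAGES.index(stage)
    child = np.random.SeedSequence(entropy=seed, spawn_key=(idx,))
    return int(child.generate_state(1)[0] % (2**31))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _prepare_mdr_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    df = cohort.copy()
    df["genotype_dominant"] = (df["genotype"] != "GG").astype(int)
    if "bmi_gt25" not in df.columns and "bmi" in df.columns:
        df["bmi_gt25"] = (df["bmi"] > 25).astype(int)
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "inputs": {},
        "outputs": [],
    }

    def record(path: Path):
        manifest["outputs"].append(str(path))

    cohort: pd.DataFrame | None = None
    lesions: pd.DataFrame | None = None
    gtab: GenotypeTable | None = None

    for name, p in (("cohort", config.cohort_path), ("lesions", config.lesion_path),
                    ("counts", config.counts_path)):
        if p:
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} input not found: {p}")
            manifest["inputs"][name] = {"path": p, "sha256_16": _hash_file(Path(p))}

    if config.cohort_path:
        cohort = read_cohort(config.cohort_path)
    if config.lesion_path:
        lesions = read_lesions(config.lesion_path)
    if config.counts_path:
        gtab = read_counts(config.counts_path)

    if "simulate" in config.stages:
        sim_cfg = CohortConfig(**{**config.simulate, "seed": stage_seed(config.seed, "simulate")})
        cohort = simulate_cohort(sim_cfg)
        lesions = simulate_lesions(cohort[cohort["status"] == 1], sim_cfg,
                                   seed=stage_seed(config.seed, "gensini"))
        write_cohort(cohort, out / "cohort.csv")
        write_lesions(lesions, out / "lesions.csv")
        write_json(sim_cfg.to_dict(), out / "simulate_config.json")
        record(out / "cohort.csv")
        record(out / "lesions.csv")
        log.info("simulated cohort: %d cases / %d controls",
                 int((cohort["status"] == 1).sum()), int((cohort["status"] == 0).sum()))

    if cohort is not None and gtab is None:
        gtab = cohort_to_genotype_table(cohort, label="cohort")

    if "gensini" in config.stages:
        if lesions is None:
            log.info("gensini stage skipped: no lesion table available")
        else:
            scores = score_lesion_table(lesions)
            severity, cutoff = dichotomize_severity(scores["score"], cutoff="median")
            scores["high_severity"] = severity
            scores.to_csv(out / "gensini_scores.tsv", sep="\t", index=False)
            record(out / "gensini_scores.tsv")
            manifest["gensini_cutoff"] = cutoff
            if cohort is not None and "gensini" not in cohort.columns:
                cohort = cohort.merge(scores.rename(columns={"score": "gensini"}),
                                      on="subject_id", how="left")

    assoc_rows = []
    if "associate" in config.stages:
        if gtab is None:
            log.info("associate stage skipped: no genotype counts available")
        else:
            results = {
                "allelic": odds_ratio(allele_table(gtab), config.alpha, model="allelic"),
                "additive": additive_trend(gtab, config.alpha),
                "dominant": odds_ratio(recode_model(gtab, "dominant"), config.alpha, model="dominant"),
                "recessive": odds_ratio(recode_model(gtab, "recessive"), config.alpha, model="recessive"),
            }
            chi2, p_hwe = hwe_test(gtab.controls)
            summary = {
                "hwe_controls": {"chi2": chi2, "p": p_hwe},
                "maf_cases": minor_allele_frequency(gtab, "case"),
                "maf_controls": minor_allele_frequency(gtab, "control"),
            }
            for model, r in results.items():
                assoc_rows.append({
                    "model": model, "or": r.or_estimate, "ci_low": r.ci95[0],
                    "ci_high": r.ci95[1], "p": r.p_value,
                })
                summary[model] = {"or": r.or_estimate, "ci95": list(r.ci95), "p": r.p_value}
            adjusted, flags, threshold = bonferroni([r["p"] for r in assoc_rows])
            for row, adj, flag in zip(assoc_rows, adjusted, flags):
                row["p_bonferroni"] = float(adj)
                row["significant"] = bool(flag)
            summary["bonferroni_threshold"] = threshold
            pd.DataFrame(assoc_rows).to_csv(out / "association.tsv", sep="\t", index=False)
            write_json(summary, out / "association.json")
            write_counts(gtab, out / "genotype_counts.tsv")
            record(out / "association.tsv")

    if "interact" in config.stages:
        if cohort is None:
            log.info("interact stage skipped: individual-level cohort required")
        else:
            df = _prepare_mdr_columns(cohort)
            rows = []
            for cov in config.interaction_covariates:
                if cov not in df.columns:
                    log.warning("interaction covariate %s not in cohort; skipped", cov)
                    continue
                res = interaction_test(df, "status", "genotype_dominant", cov)
                rows.append({
                    "covariate": cov, "p_interaction": res.p_value,
                    "or_interaction": res.or_interaction,
                    "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                })
            if "gensini" in df.columns and df["gensini"].notna().sum() >= 4:
                cases = df[df["status"] == 1]
                carriers = cases.loc[cases["genotype_dominant"] == 1, "gensini"].dropna()
                refs = cases.loc[cases["genotype_dominant"] == 0, "gensini"].dropna()
                if len(carriers) and len(refs):
                    u, p = mann_whitney(carriers, refs)
                    manifest["gensini_mann_whitney"] = {"U": u, "p": p}
            pd.DataFrame(rows).to_csv(out / "interactions.tsv", sep="\t", index=False)
            record(out / "interactions.tsv")

    if "resample" in config.stages:
        if gtab is None:
            log.info("resample stage skipped: no genotype counts available")
        else:
            rows = []
            for stat in config.permutation_statistics:
                plan = PermutationPlan(n_permutations=config.permutations,
                                       seed=stage_seed(config.seed, "resample"),
                                       statistic=stat)
                res = empirical_p(gtab, plan)
                rows.append({
                    "statistic": stat, "empirical_p": res.p_value,
                    "observed_chi2": res.observed, "exceedances": res.exceedances,
                    "n_permutations": res.n_permutations, "seed": res.seed,
                })
            pd.DataFrame(rows).to_csv(out / "empirical_p.tsv", sep="\t", index=False)
            record(out / "empirical_p.tsv")

    if "mdr" in config.stages:
        if cohort is None:
            log.info("mdr stage skipped: individual-level cohort required")
        else:
            df = _prepare_mdr_columns(cohort)
            factors = tuple(config.mdr.get("factors", _DEFAULT_MDR_FACTORS))
            factors = tuple(f for f in factors if f in df.columns)
            settings = {
                "max_size": config.mdr.get("max_size", 4),
                "folds": config.mdr.get("folds", 10),
                "repeats": config.mdr.get("repeats", 10),
                "seed": stage_seed(config.seed, "mdr"),
            }
            result = search_best_models(df, factors, **settings)
            n_perm = config.mdr.get("permutations", 0)
            perm_p = None
            if n_perm:
                perm_p = permutation_significance(df, factors, observed=result,
                                                  n_perm=n_perm, **settings)
            rows = [
                {
                    "n_factors": k,
                    "best_model": ", ".join(d["factors"]),
                    "cvc": f"{d['cvc']}/{result.n_evaluations}",
                    "testing_accuracy": round(d["testing_accuracy"], 4),
                }
                for k, d in sorted(result.best_per_size.items())
            ]
            if perm_p is not None:
                rows[-1]["permutation_p"] = perm_p
            pd.DataFrame(rows).to_csv(out / "mdr_models.tsv", sep="\t", index=False)
            graph = entropy_graph(df, factors)
            write_json(graph.to_json_dict(), out / "entropy_graph.json")
            record(out / "mdr_models.tsv")
            record(out / "entropy_graph.json")

    if "report" in config.stages:
        write_json(manifest, out / "manifest.json")
        record(out / "manifest.json")

    return manifest
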