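"""Multifactor dimensionality reduction (MDR) with interaction-entropy graphs.

MDR searches exhaustively over combinations of categorical factors.  For a
candidate combination, the contingency cells of the multilocus genotype /
exposure grid are collapsed into "high risk" and "low risk" by comparing
each cell's case:control ratio with the overall training-set ratio, turning
the combination into a one-dimensional classifier.  Classifiers are scored
by balanced testing accuracy under repeated stratified cross-validation;
cross-validation consistency (CVC) counts how many CV evaluations pick a
combination as the within-size winner.  Significance of the best model is
assessed by permuting the outcome labels and re-running the whole search.

Interaction entropy graphs decompose the outcome entropy H(Y): each
factor's univariate effect is the mutual information I(X;Y) as a percent of
H(Y); each pair's interaction information I(A,B;Y) - I(A;Y) - I(B;Y)
quantifies synergy (positive) or redundancy (negative).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FactorSet",
    "MDRModel",
    "MDRResult",
    "EntropyGraph",
    "label_cells",
    "balanced_accuracy",
    "cross_validate",
    "search_best_models",
    "permutation_significance",
    "entropy_graph",
]


@dataclass(frozen=True)
class FactorSet:
    """An ordered combination of categorical factor columns with their levels."""

    factors: tuple[str, ...]
    levels: tuple[tuple, ...]

    def __post_init__(self) -> None:
        if not (1 <= len(self.factors)):
            raise ValueError("need at least one factor")
        if len(self.factors) != len(self.levels):
            raise ValueError("levels must be given per factor")

    @classmethod
    def from_data(cls, data: pd.DataFrame, factors) -> "FactorSet":
        factors = tuple(factors)
        levels = tuple(tuple(sorted(data[f].dropna().unique().tolist())) for f in factors)
        return cls(factors, levels)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(l) for l in self.levels)


@dataclass(frozen=True)
class MDRModel:
    """Trained cell labeling: True = high-risk cell (predicts case)."""

    factor_set: FactorSet
    high_risk: np.ndarray  # boolean, flattened over factor-level grid
    threshold: float       # training case:control ratio used

    def predict(self, cells: np.ndarray) -> np.ndarray:
        return self.high_risk[cells]


def _cell_index(data: pd.DataFrame, fs: FactorSet) -> np.ndarray:
    """Flattened multilocus cell index for every row of ``data``."""
    codes = []
    for f, levels in zip(fs.factors, fs.levels):
        cat = pd.Categorical(data[f], categories=list(levels))
        if (cat.codes < 0).any():
            bad = set(data[f]) - set(levels)
            raise ValueError(f"factor {f!r} has levels outside the factor set: {sorted(bad)}")
        codes.append(cat.codes.astype(np.int64))
    return np.ravel_multi_index(codes, fs.shape)


def label_cells(train: pd.DataFrame, fs: FactorSet, outcome: str = "status") -> MDRModel:
    """Collapse the multilocus grid into high/low-risk cells.

    A nonempty cell is high-risk iff cases/controls in the cell >= the
    training-set case:control ratio; cells with cases but no controls are
    high-risk; empty cells default to low-risk (they also absorb test cells
    unseen in training).
    """
    y = train[outcome].to_numpy()
    n_cases = int((y == 1).sum())
    n_controls = int((y == 0).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("training data must contain both cases and controls")
    threshold = n_cases / n_controls
    cells = _cell_index(train, fs)
    n_cells = int(np.prod(fs.shape))
    case_counts = np.bincount(cells[y == 1], minlength=n_cells)
    ctrl_counts = np.bincount(cells[y == 0], minlength=n_cells)
    nonempty = (case_counts + ctrl_counts) > 0
    # ratio rule with >= tie-break; zero-control nonempty cells are high-risk
    high = nonempty & (case_counts >= threshold * ctrl_counts) & (case_counts > 0)
    return MDRModel(factor_set=fs, high_risk=high, threshold=threshold)


def balanced_accuracy(model: MDRModel, test: pd.DataFrame, outcome: str = "status") -> float:
    """(sensitivity + specificity) / 2 of the high-risk-cell classifier."""
    y = test[outcome].to_numpy()
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("test data must contain both cases and controls")
    pred = model.predict(_cell_index(test, model.factor_set))
    sens = float(pred[y == 1].mean())
    spec = float((~pred[y == 0]).mean())
    return (sens + spec) / 2.0


def _cv_splits(data: pd.DataFrame, outcome: str, folds: int, repeats: int, seed: int):
    """(repeat, fold) -> (train_idx, test_idx); identical across factor sets."""
    y = data[outcome].to_numpy()
    splits = []
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(repeats)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(states[r]))
        splits.extend(skf.split(np.zeros(len(y)), y))
    return splits


def cross_validate(
    data: pd.DataFrame,
    fs: FactorSet,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    outcome: str = "status",
) -> dict:
    """Repeated stratified k-fold CV of one factor set.

    Returns the mean balanced testing accuracy over folds x repeats
    held-out evaluations plus the per-evaluation accuracies.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    y = data[outcome].to_numpy()
    if min((y == 1).sum(), (y == 0).sum()) < folds:
        raise ValueError("too few subjects per class for the requested folds")
    accs = []
    for train_idx, test_idx in _cv_splits(data, outcome, folds, repeats, seed):
        model = label_cells(data.iloc[train_idx], fs, outcome)
        accs.append(balanced_accuracy(model, data.iloc[test_idx], outcome))
    accs = np.array(accs)
    return {"mean_testing_accuracy": float(accs.mean()), "accuracies": accs,
            "n_evaluations": len(accs)}


@dataclass(frozen=True)
class MDRResult:
    """Search outcome: per-size winners with CVC and mean testing accuracy."""

    best_per_size: dict
    overall_best: FactorSet
    overall_best_accuracy: float
    permutation_p: float | None = None
    n_evaluations: int = 100
    all_models: dict = field(default_factory=dict, repr=False)


def search_best_models(
    data: pd.DataFrame,
    candidate_factors,
    max_size: int = 4,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    outcome: str = "status",
) -> MDRResult:
    """Exhaustive MDR search over factor combinations of size 1..max_size.

    Every combination is evaluated on the same CV splits.  Within each
    size, a combination's CVC is the number of evaluations in which it has
    the (strictly argmax, first-listed on ties) best testing accuracy; the
    per-size winner maximizes CVC, ties broken by mean testing accuracy.
    The overall best maximizes CVC across sizes, ties broken by mean
    testing accuracy, then by smaller size.
    """
    candidate_factors = list(candidate_factors)
    if not candidate_factors:
        raise ValueError("need at least one candidate factor")
    max_size = min(max_size, len(candidate_factors))
    splits = _cv_splits(data, outcome, folds, repeats, seed)
    n_eval = len(splits)

    combos: list[tuple[str, ...]] = []
    for k in range(1, max_size + 1):
        combos.extend(itertools.combinations(candidate_factors, k))
    factor_sets = {c: FactorSet.from_data(data, c) for c in combos}

    acc = np.zeros((len(combos), n_eval))
    for j, (train_idx, test_idx) in enumerate(splits):
        train = data.iloc[train_idx]
        test = data.iloc[test_idx]
        for i, c in enumerate(combos):
            model = label_cells(train, factor_sets[c], outcome)
            acc[i, j] = balanced_accuracy(model, test, outcome)

    best_per_size: dict[int, dict] = {}
    all_models: dict[tuple[str, ...], dict] = {}
    for k in range(1, max_size + 1):
        rows = [i for i, c in enumerate(combos) if len(c) == k]
        sub = acc[rows]
        winners = np.argmax(sub, axis=0)  # first index wins ties
        cvc = np.bincount(winners, minlength=len(rows))
        means = sub.mean(axis=1)
        order = sorted(range(len(rows)), key=lambda i: (-cvc[i], -means[i]))
        best_i = order[0]
        best_combo = combos[rows[best_i]]
        best_per_size[k] = {
            "factor_set": factor_sets[best_combo],
            "factors": best_combo,
            "cvc": int(cvc[best_i]),
            "testing_accuracy": float(means[best_i]),
        }
        for i, ri in enumerate(rows):
            all_models[combos[ri]] = {
                "cvc": int(cvc[i]),
                "testing_accuracy": float(means[i]),
            }
    overall = max(
        best_per_size.values(),
        key=lambda d: (d["cvc"], d["testing_accuracy"], -len(d["factors"])),
    )
    return MDRResult(
        best_per_size=best_per_size,
        overall_best=overall["factor_set"],
        overall_best_accuracy=overall["testing_accuracy"],
        n_evaluations=n_eval,
        all_models=all_models,
    )


def permutation_significance(
    data: pd.DataFrame,
    candidate_factors,
    observed: MDRResult | None = None,
    n_perm: int = 1000,
    max_size: int = 4,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    outcome: str = "status",
) -> float:
    """Permutation p-value of the MDR search's best testing accuracy.

    Outcome labels are permuted ``n_perm`` times and the full search is
    re-run on each; p = (1 + #{permuted best accuracy >= observed}) /
    (1 + n_perm), so p is never 0.
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    if observed is None:
        observed = search_best_models(data, candidate_factors, max_size, folds, repeats, seed, outcome)
    obs_acc = observed.overall_best_accuracy
    rng = np.random.default_rng(seed)
    exceed = 0
    perm_data = data.copy()
    y = data[outcome].to_numpy()
    for _ in range(n_perm):
        perm_data[outcome] = rng.permutation(y)
        res = search_best_models(perm_data, candidate_factors, max_size, folds, repeats, seed, outcome)
        if res.overall_best_accuracy >= obs_acc - 1e-12:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


@dataclass(frozen=True)
class EntropyGraph:
    """Univariate and pairwise interaction information as % of H(Y)."""

    univariate: dict
    pairwise: dict
    strength_class: dict
    outcome_entropy: float

    def to_json_dict(self) -> dict:
        return {
            "outcome_entropy_bits": self.outcome_entropy,
            "nodes": [{"factor": f, "percent_entropy": v} for f, v in self.univariate.items()],
            "edges": [
                {"factors": list(pair), "percent_entropy": v,
                 "strength": self.strength_class[pair]}
                for pair, v in self.pairwise.items()
            ],
        }


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _mutual_information(data: pd.DataFrame, cols: list[str], outcome: str) -> float:
    joint = data.groupby([*cols, outcome], observed=True).size().to_numpy()
    marg_x = data.groupby(cols, observed=True).size().to_numpy()
    marg_y = data.groupby(outcome, observed=True).size().to_numpy()
    return _entropy(marg_x) + _entropy(marg_y) - _entropy(joint)


def entropy_graph(
    data: pd.DataFrame,
    factors,
    outcome: str = "status",
    strong_threshold: float = 2.0,
    moderate_threshold: float = 1.0,
) -> EntropyGraph:
    """Interaction entropy decomposition for a set of categorical factors.

    Univariate percent = 100 * I(X;Y) / H(Y).  Pairwise percent =
    100 * [I(A,B;Y) - I(A;Y) - I(B;Y)] / H(Y): positive values mean the
    pair is synergistic (jointly more informative than separately),
    negative values mean redundancy.  Edges are classed strong / moderate /
    weak at the configured percent-entropy thresholds.
    """
    factors = list(factors)
    h_y = _entropy(data.groupby(outcome, observed=True).size().to_numpy())
    if h_y == 0.0:
        raise ValueError("outcome is constant: H(Y) = 0")
    uni = {f: 100.0 * _mutual_information(data, [f], outcome) / h_y for f in factors}
    pairwise = {}
    strength = {}
    for a, b in itertools.combinations(factors, 2):
        joint = 100.0 * _mutual_information(data, [a, b], outcome) / h_y
        info = joint - uni[a] - uni[b]
        pairwise[(a, b)] = info
        mag = abs(info)
        strength[(a, b)] = (
            "strong" if mag >= strong_threshold
            else "moderate" if mag >= moderate_threshold
            else "weak"
        )
    return EntropyGraph(univariate=uni, pairwise=pairwise, strength_class=strength,
                        outcome_entropy=h_y)
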