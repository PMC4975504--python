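"""Multifactor dimensionality reduction: cell labeling, CV search, entropy graphs."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from geneenv.mdr import (
    FactorSet,
    balanced_accuracy,
    cross_validate,
    entropy_graph,
    label_cells,
    permutation_significance,
    search_best_models,
)


def make_df(**cols) -> pd.DataFrame:
    return pd.DataFrame(cols)


class TestLabelCells:
    def test_ratio_rule_on_single_factor(self):
        # cell x=1 has 30 cases / 10 controls; overall ratio 40:40 = 1
        df = make_df(
            status=[1] * 30 + [0] * 10 + [1] * 10 + [0] * 30,
            x=[1] * 40 + [0] * 40,
        )
        fs = FactorSet.from_data(df, ["x"])
        model = label_cells(df, fs)
        cells = {level: model.high_risk[i] for i, level in enumerate(fs.levels[0])}
        assert cells[1] and not cells[0]

    def test_empty_cell_defaults_low_risk(self):
        df = make_df(status=[1, 1, 0, 0], x=[0, 0, 0, 0], y=[0, 1, 0, 1])
        fs = FactorSet(("x", "y"), ((0, 1), (0, 1)))
        model = label_cells(df, fs)
        # cells with x=1 never occur in training -> low risk
        assert not model.high_risk[2] and not model.high_risk[3]

    def test_zero_control_nonempty_cell_high_risk(self):
        df = make_df(status=[1, 1, 1, 0, 0, 0], x=[1, 1, 1, 0, 0, 0])
        fs = FactorSet.from_data(df, ["x"])
        model = label_cells(df, fs)
        assert model.high_risk[list(fs.levels[0]).index(1)]

    def test_tie_at_threshold_is_high_risk(self):
        # cell ratio exactly equals the overall ratio -> high (>= rule)
        df = make_df(status=[1, 0] * 10, x=[0, 0, 1, 1] * 5)
        fs = FactorSet.from_data(df, ["x"])
        model = label_cells(df, fs)
        assert model.high_risk.all()

    def test_two_factor_labels_match_bruteforce(self, rng):
        n = 300
        df = make_df(
            status=rng.integers(0, 2, n),
            a=rng.integers(0, 3, n),
            b=rng.integers(0, 2, n),
        )
        fs = FactorSet.from_data(df, ["a", "b"])
        model = label_cells(df, fs)
        threshold = (df.status == 1).sum() / (df.status == 0).sum()
        for i, (la, lb) in enumerate(itertools.product(fs.levels[0], fs.levels[1])):
            cell = df[(df.a == la) & (df.b == lb)]
            cases = (cell.status == 1).sum()
            ctrls = (cell.status == 0).sum()
            if len(cell) == 0:
                expected = False
            elif ctrls == 0:
                expected = cases > 0
            else:
                expected = cases / ctrls >= threshold
            assert model.high_risk[i] == expected

    def test_single_class_training_rejected(self):
        df = make_df(status=[1, 1, 1], x=[0, 1, 0])
        with pytest.raises(ValueError, match="cases and controls"):
            label_cells(df, FactorSet.from_data(df, ["x"]))


class TestBalancedAccuracy:
    def test_perfect_separation(self):
        df = make_df(status=[1] * 5 + [0] * 5, x=[1] * 5 + [0] * 5)
        fs = FactorSet.from_data(df, ["x"])
        model = label_cells(df, fs)
        assert balanced_accuracy(model, df) == 1.0

    def test_hand_computed_confusion_matrix(self):
        train = make_df(status=[1, 1, 1, 0, 1, 0, 0, 0], x=[1, 1, 1, 1, 0, 0, 0, 0])
        fs = FactorSet.from_data(train, ["x"])
        model = label_cells(train, fs)  # x=1 high (3:1), x=0 low (1:3)
        test = make_df(status=[1, 1, 0, 0, 1, 0, 0, 0], x=[1, 0, 1, 0, 1, 1, 0, 0])
        # cases: x = 1,0,1 -> predictions 1,0,1 -> sensitivity 2/3
        # controls: x = 1,0,1,0,0 -> predictions 1,0,1,0,0 -> specificity 3/5
        expected = (2 / 3 + 3 / 5) / 2
        assert balanced_accuracy(model, test) == pytest.approx(expected)

    def test_uninformative_labels_near_chance(self, rng):
        accs = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            train = make_df(status=r.integers(0, 2, 400), x=r.integers(0, 2, 400))
            test = make_df(status=r.integers(0, 2, 400), x=r.integers(0, 2, 400))
            fs = FactorSet(("x",), ((0, 1),))
            accs.append(balanced_accuracy(label_cells(train, fs), test))
        assert np.mean(accs) == pytest.approx(0.5, abs=0.03)

    def test_single_class_test_rejected(self):
        train = make_df(status=[1, 0, 1, 0], x=[1, 0, 1, 0])
        fs = FactorSet.from_data(train, ["x"])
        model = label_cells(train, fs)
        with pytest.raises(ValueError):
            balanced_accuracy(model, make_df(status=[1, 1], x=[0, 1]))


class TestCrossValidate:
    def test_perfect_predictor_all_evaluations(self):
        df = make_df(status=[1] * 100 + [0] * 100, x=[1] * 100 + [0] * 100)
        fs = FactorSet.from_data(df, ["x"])
        res = cross_validate(df, fs, folds=10, repeats=10, seed=1)
        assert res["n_evaluations"] == 100
        assert res["mean_testing_accuracy"] == 1.0
        assert (res["accuracies"] == 1.0).all()

    def test_pure_noise_factor_near_chance(self, rng):
        df = make_df(status=rng.integers(0, 2, 600), x=rng.integers(0, 2, 600))
        res = cross_validate(df, FactorSet.from_data(df, ["x"]), folds=5, repeats=4, seed=2)
        assert res["mean_testing_accuracy"] == pytest.approx(0.5, abs=0.06)

    def test_identical_seed_identical_folds(self, small_cohort):
        fs = FactorSet.from_data(small_cohort, ["t2dm"])
        r1 = cross_validate(small_cohort, fs, folds=5, repeats=2, seed=7)
        r2 = cross_validate(small_cohort, fs, folds=5, repeats=2, seed=7)
        assert (r1["accuracies"] == r2["accuracies"]).all()

    def test_too_few_subjects_per_fold_rejected(self):
        df = make_df(status=[1, 0, 1, 0], x=[0, 1, 0, 1])
        with pytest.raises(ValueError):
            cross_validate(df, FactorSet.from_data(df, ["x"]), folds=10)


class TestSearch:
    def test_enumerates_all_subsets(self, small_cohort):
        res = search_best_models(
            small_cohort,
            ["genotype_dominant", "t2dm", "hyperlipidemia", "smoking"],
            max_size=4, folds=4, repeats=1, seed=0,
        )
        assert len(res.all_models) == 15  # C(4,1)+C(4,2)+C(4,3)+C(4,4)
        assert set(res.best_per_size) == {1, 2, 3, 4}

    def test_matches_bruteforce_on_tiny_data(self, rng):
        n = 200
        df = make_df(
            status=rng.integers(0, 2, n),
            a=rng.integers(0, 2, n),
            b=rng.integers(0, 2, n),
            c=rng.integers(0, 3, n),
        )
        factors = ["a", "b", "c"]
        folds, repeats, seed = 4, 2, 5
        res = search_best_models(df, factors, max_size=3, folds=folds,
                                 repeats=repeats, seed=seed)
        # independent brute force on the same splits
        from geneenv.mdr import _cv_splits

        splits = _cv_splits(df, "status", folds, repeats, seed)
        combos = [c for k in (1, 2, 3) for c in itertools.combinations(factors, k)]
        accs = {c: [] for c in combos}
        for tr, te in splits:
            for c in combos:
                fs = FactorSet.from_data(df, c)
                m = label_cells(df.iloc[tr], fs)
                accs[c].append(balanced_accuracy(m, df.iloc[te]))
        for c in combos:
            assert res.all_models[c]["testing_accuracy"] == pytest.approx(
                float(np.mean(accs[c]))
            )

    def test_embedded_interaction_recovered(self):
        from geneenv.synthetic import CohortConfig, simulate_cohort

        hits = 0
        for seed in range(10):
            cfg = CohortConfig(
                n_cases=1000, n_controls=1000, genotype_or=1.0,
                covariate_ors={}, interaction_ors={"t2dm": 2.0}, seed=seed,
            )
            df = simulate_cohort(cfg)
            df["g"] = (df["genotype"] != "GG").astype(int)
            res = search_best_models(df, ["g", "t2dm", "smoking", "drinking"],
                                     max_size=2, folds=5, repeats=2, seed=seed)
            if set(res.best_per_size[2]["factors"]) == {"g", "t2dm"}:
                hits += 1
        assert hits >= 8

    def test_fixed_seed_identical_result(self, small_cohort):
        kw = dict(max_size=2, folds=5, repeats=2, seed=3)
        r1 = search_best_models(small_cohort, ["genotype_dominant", "t2dm"], **kw)
        r2 = search_best_models(small_cohort, ["genotype_dominant", "t2dm"], **kw)
        assert r1.best_per_size[2]["cvc"] == r2.best_per_size[2]["cvc"]
        assert r1.overall_best_accuracy == r2.overall_best_accuracy


class TestPermutationSignificance:
    def test_strong_signal_small_p(self):
        df = make_df(status=[1] * 150 + [0] * 150, x=[1] * 150 + [0] * 150,
                     z=list(np.tile([0, 1], 150)))
        p = permutation_significance(df, ["x", "z"], n_perm=50, max_size=2,
                                     folds=4, repeats=1, seed=4)
        assert p <= 1 / 51 + 1e-12

    def test_null_data_not_significant(self, rng):
        df = make_df(status=rng.integers(0, 2, 300), x=rng.integers(0, 2, 300))
        p = permutation_significance(df, ["x"], n_perm=40, max_size=1,
                                     folds=4, repeats=1, seed=6)
        assert p > 0.05

    def test_p_never_zero(self):
        df = make_df(status=[1] * 50 + [0] * 50, x=[1] * 50 + [0] * 50)
        p = permutation_significance(df, ["x"], n_perm=10, max_size=1,
                                     folds=3, repeats=1, seed=1)
        assert p >= 1 / 11


class TestEntropyGraph:
    def test_independent_factor_near_zero(self, rng):
        df = make_df(status=rng.integers(0, 2, 5000), x=rng.integers(0, 2, 5000))
        eg = entropy_graph(df, ["x"])
        assert eg.univariate["x"] == pytest.approx(0.0, abs=0.2)

    def test_xor_outcome_pure_synergy(self):
        # exact XOR grid: univariate information 0, pairwise 100% of H(Y)
        rows = [(a, b) for a in (0, 1) for b in (0, 1) for _ in range(25)]
        df = pd.DataFrame(rows, columns=["a", "b"])
        df["status"] = df["a"] ^ df["b"]
        eg = entropy_graph(df, ["a", "b"])
        assert eg.univariate["a"] == pytest.approx(0.0, abs=1e-9)
        assert eg.pairwise[("a", "b")] == pytest.approx(100.0, abs=1e-9)
        assert eg.strength_class[("a", "b")] == "strong"

    def test_duplicated_factor_pure_redundancy(self, rng):
        a = rng.integers(0, 2, 2000)
        y = ((a + (rng.random(2000) < 0.3)) > 0).astype(int)
        df = make_df(status=y, a=a, b=a.copy())
        eg = entropy_graph(df, ["a", "b"])
        assert eg.pairwise[("a", "b")] == pytest.approx(-eg.univariate["a"], abs=1e-9)

    def test_symmetric_in_factor_order(self, small_cohort):
        e1 = entropy_graph(small_cohort, ["genotype_dominant", "t2dm"])
        e2 = entropy_graph(small_cohort, ["t2dm", "genotype_dominant"])
        assert e1.pairwise[("genotype_dominant", "t2dm")] == pytest.approx(
            e2.pairwise[("t2dm", "genotype_dominant")], abs=1e-12
        )

    def test_constant_outcome_rejected(self):
        df = make_df(status=[1, 1, 1, 1], x=[0, 1, 0, 1])
        with pytest.raises(ValueError, match="constant"):
            entropy_graph(df, ["x"])
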