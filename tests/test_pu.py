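"""Transductive PU learner: fraction contract, sweep, robustness, metrics."""

import numpy as np
import pandas as pd
import pytest

from mirreg.pu import (
    DEFAULT_P_GRID,
    PUConfig,
    PUDataset,
    TransductivePU,
    cross_validate,
    evaluate,
    holdout_experiment,
    positive_count,
    positives_at,
    robust_positives,
)


def separable_dataset(seed=0, n_pos=8, n_unl=60, planted_frac=0.1, shift=3.0, d=5):
    """Positives cluster at +shift in every feature; a planted fraction of
    the unlabeled pool comes from the positive cluster."""
    rng = np.random.default_rng(seed)
    n_plant = max(1, int(round(planted_frac * n_unl)))
    X_pos = rng.normal(shift, 1.0, size=(n_pos, d))
    X_plant = rng.normal(shift, 1.0, size=(n_plant, d))
    X_bg = rng.normal(0.0, 1.0, size=(n_unl - n_plant, d))
    X_unl = np.vstack([X_plant, X_bg])
    unl_ids = [f"plant{i}" for i in range(n_plant)] + [
        f"bg{i}" for i in range(n_unl - n_plant)
    ]
    data = PUDataset.from_arrays(X_pos, [f"pos{i}" for i in range(n_pos)],
                                 X_unl, unl_ids)
    planted = {i for i in unl_ids if i.startswith("plant")}
    return data, planted


class TestFractionContract:
    def test_small_p_floors_at_one(self):
        data, _ = separable_dataset(n_unl=20)
        res = TransductivePU(data, seed=0).fit(0.05)
        assert res.k == 1  # round(0.05 * 20) = 1

    @pytest.mark.parametrize("U", [10, 50])
    def test_exact_k_across_grid(self, U):
        data, _ = separable_dataset(seed=U, n_unl=U)
        model = TransductivePU(data, seed=1)
        ks = []
        for p in DEFAULT_P_GRID:
            expected = positive_count(p, U)
            if expected >= U:
                with pytest.raises(ValueError):
                    model.fit(p)
                continue
            res = model.fit(p)
            assert res.k == expected == len(res.positive_ids)
            ks.append(res.k)
        assert ks == sorted(ks)  # monotone in p

    def test_p_out_of_range_rejected(self):
        data, _ = separable_dataset()
        model = TransductivePU(data)
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                model.fit(bad)

    def test_degenerate_identical_features_warns(self):
        data = PUDataset.from_arrays(
            np.ones((3, 4)), ["a", "b", "c"], np.ones((6, 4)),
            [f"u{i}" for i in range(6)],
        )
        with pytest.warns(UserWarning, match="identical"):
            res = TransductivePU(data).fit(0.3)
        # ties broken by identifier: round(0.3*6)=2 smallest ids win
        assert res.positive_ids == {"u0", "u1"}


class TestFitting:
    def test_separable_instance_recovers_planted_positives(self):
        data, planted = separable_dataset(seed=3, n_unl=60, planted_frac=0.1)
        res = TransductivePU(data, seed=0).fit(0.10)
        assert res.positive_ids == planted

    def test_same_seed_reproduces_labels_and_scores(self):
        data, _ = separable_dataset(seed=5)
        r1 = TransductivePU(data, seed=9).fit(0.25)
        r2 = TransductivePU(data, seed=9).fit(0.25)
        pd.testing.assert_series_equal(r1.labels, r2.labels)
        pd.testing.assert_series_equal(r1.scores, r2.scores)

    def test_summary_mentions_fit_facts(self):
        data, _ = separable_dataset()
        res = TransductivePU(data).fit(0.2)
        text = res.summary()
        assert "positive fraction p" in text and "0.20" in text
        assert "feature weights" in text

    def test_disjoint_identifier_contract(self):
        with pytest.raises(ValueError, match="both sets"):
            PUDataset.from_arrays(np.zeros((2, 2)), ["x", "y"],
                                  np.zeros((2, 2)), ["y", "z"])


class TestSweep:
    def test_default_grid_yields_19_labelings(self):
        data, _ = separable_dataset(n_unl=50)
        results = TransductivePU(data, seed=2).sweep()
        assert len(results) == 19
        counts = [r.k for r in results]
        assert counts == sorted(counts)

    def test_singleton_grid_equals_direct_fit(self):
        data, _ = separable_dataset(seed=4)
        model = TransductivePU(data, seed=4)
        (swept,) = model.sweep([0.5])
        direct = model.fit(0.5)
        pd.testing.assert_series_equal(swept.labels, direct.labels)

    def test_non_increasing_grid_rejected(self):
        data, _ = separable_dataset()
        with pytest.raises(ValueError, match="increasing"):
            TransductivePU(data).sweep([0.5, 0.3])


class TestRobustPositives:
    def test_nested_sets_from_fixed_scores(self):
        scores = pd.Series(np.linspace(1, 0, 40), index=[f"u{i:02d}" for i in range(40)])
        sets = [positives_at(scores, p) for p in DEFAULT_P_GRID]
        for a, b in zip(sets, sets[1:]):
            assert a <= b  # nested in p

    def test_intersection_semantics(self):
        class Fake:
            def __init__(self, ids):
                self.positive_ids = set(ids)
        assert robust_positives([Fake("abc"), Fake("ab"), Fake("abd")]) == {"a", "b"}
        assert robust_positives([Fake("ab"), Fake("cd")]) == set()

    def test_random_labelings_against_set_oracle(self):
        rng = np.random.default_rng(17)
        universe = [f"u{i}" for i in range(30)]
        class Fake:
            def __init__(self, ids):
                self.positive_ids = set(ids)
        labelings = [
            Fake(rng.choice(universe, size=int(rng.integers(1, 30)), replace=False))
            for _ in range(8)
        ]
        got = robust_positives(labelings)
        expected = {
            u for u in universe if all(u in lab.positive_ids for lab in labelings)
        }
        assert got == expected

    def test_robust_subset_of_every_per_p_set(self):
        data, _ = separable_dataset(seed=6, n_unl=40)
        results = TransductivePU(data, seed=6).sweep()
        robust = robust_positives(results)
        for r in results:
            assert robust <= r.positive_ids


class TestEvaluate:
    def _fake(self, pos, neg, p=0.5):
        class Fake:
            positive_ids = set(pos)
            negative_ids = set(neg)
            p_ = p
        f = Fake()
        f.p = p
        return f

    def test_recall_counting(self):
        res = self._fake(["a", "b", "c"], ["d"])
        ev = evaluate(res, known_positive_ids={"a", "b", "c", "x"},
                      unlabeled_ids={"a", "b", "c", "d"})
        assert ev.recall == 0.75

    def test_all_negative_removal_rate_one(self):
        res = self._fake([], ["a", "b"])
        ev = evaluate(res, {"z"} | set(), {"a", "b"})
        assert ev.removal_rate == 1.0

    def test_empty_known_positives_rejected(self):
        with pytest.raises(ValueError, match="recall undefined"):
            evaluate(self._fake(["a"], []), set(), {"a"})

    def test_random_counting_oracle(self):
        rng = np.random.default_rng(23)
        universe = [f"u{i}" for i in range(50)]
        for _ in range(20):
            pos = set(rng.choice(universe, size=20, replace=False))
            neg = set(universe) - pos
            known = set(rng.choice(universe, size=int(rng.integers(1, 20)), replace=False))
            unl = set(rng.choice(universe, size=30, replace=False))
            ev = evaluate(self._fake(pos, neg), known, unl)
            assert ev.recall == len(pos & known) / len(known)
            assert ev.removal_rate == len(neg & unl) / len(unl)


class TestExperiments:
    def test_holdout_table_shape(self):
        rng = np.random.default_rng(1)
        positives = pd.DataFrame(rng.normal(3, 1, (20, 4)),
                                 index=[f"pos{i}" for i in range(20)])
        unlabeled = pd.DataFrame(rng.normal(0, 1, (60, 4)),
                                 index=[f"u{i}" for i in range(60)])
        table = holdout_experiment(positives, unlabeled, seed=0)
        assert set(table["holdout_fraction"]) == {0.1, 0.3, 0.5, 0.7, 0.9}
        assert len(table) == 5 * 19
        assert table["recall"].between(0, 1).all()
        assert table["removal_rate"].between(0, 1).all()

    def test_zero_fraction_skipped_with_warning(self):
        rng = np.random.default_rng(2)
        positives = pd.DataFrame(rng.normal(3, 1, (6, 3)),
                                 index=[f"pos{i}" for i in range(6)])
        unlabeled = pd.DataFrame(rng.normal(0, 1, (20, 3)),
                                 index=[f"u{i}" for i in range(20)])
        with pytest.warns(UserWarning, match="moves no positives"):
            table = holdout_experiment(positives, unlabeled, fractions=[0.0, 0.5],
                                       grid=[0.2, 0.4], seed=0)
        assert set(table["holdout_fraction"]) == {0.5}

    def test_recall_monotone_on_fixed_scores(self):
        # the qualitative shape: with one score vector, larger p keeps
        # strictly more positives, so recall grows and removal shrinks
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.normal(size=80), index=[f"u{i}" for i in range(80)])
        known = set(rng.choice(scores.index, size=10, replace=False))
        unl = set(scores.index)
        recalls, removals = [], []
        for p in DEFAULT_P_GRID:
            pos = positives_at(scores, p)
            recalls.append(len(pos & known) / len(known))
            removals.append(len(unl - pos) / len(unl))
        assert recalls == sorted(recalls)
        assert removals == sorted(removals, reverse=True)

    def test_cv_leave_one_out_recall_binary(self):
        rng = np.random.default_rng(4)
        positives = pd.DataFrame(rng.normal(3, 1, (5, 3)),
                                 index=[f"pos{i}" for i in range(5)])
        unlabeled = pd.DataFrame(rng.normal(0, 1, (30, 3)),
                                 index=[f"u{i}" for i in range(30)])
        table = cross_validate(positives, unlabeled, folds=5, grid=[0.3], seed=1)
        assert len(table) == 1
        # mean of 5 binary per-fold recalls
        assert (table["recall"] * 5).round(6).iloc[0] == int((table["recall"] * 5).iloc[0])

    def test_cv_deterministic(self):
        rng = np.random.default_rng(5)
        positives = pd.DataFrame(rng.normal(3, 1, (10, 3)),
                                 index=[f"pos{i}" for i in range(10)])
        unlabeled = pd.DataFrame(rng.normal(0, 1, (30, 3)),
                                 index=[f"u{i}" for i in range(30)])
        t1 = cross_validate(positives, unlabeled, folds=5, grid=[0.2, 0.6], seed=7)
        t2 = cross_validate(positives, unlabeled, folds=5, grid=[0.2, 0.6], seed=7)
        pd.testing.assert_frame_equal(t1, t2)

    def test_cv_separable_high_recall_at_large_p(self):
        rng = np.random.default_rng(6)
        positives = pd.DataFrame(rng.normal(3, 1, (15, 4)),
                                 index=[f"pos{i}" for i in range(15)])
        unlabeled = pd.DataFrame(rng.normal(0, 1, (50, 4)),
                                 index=[f"u{i}" for i in range(50)])
        table = cross_validate(positives, unlabeled, folds=5,
                               grid=[0.5, 0.7, 0.9], seed=2)
        assert (table["recall"] >= 0.9).all()

    def test_too_many_folds_rejected(self):
        positives = pd.DataFrame(np.zeros((3, 2)), index=list("abc"))
        unlabeled = pd.DataFrame(np.ones((4, 2)), index=list("wxyz"))
        with pytest.raises(ValueError, match="folds"):
            cross_validate(positives, unlabeled, folds=4)
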