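"""Ensemble building, majority-vote fusion, and accuracy metrics."""

import numpy as np
import pytest

from bootsvm import (
    OptimizerSettings,
    accuracy_vs_size,
    build_classifier,
    build_ensemble,
    ensemble_predict,
    per_class_cc,
    percent_cc,
)


class TestPercentCC:
    def test_direct_formula(self):
        true = np.array(list("aaabbbbbccc"))
        pred = true.copy()
        pred[[0, 5]] = ["b", "c"]  # 9 of 11 correct
        assert percent_cc(true, pred) == pytest.approx(100 * 9 / 11)

    def test_identical_vectors(self):
        v = np.array(["x", "y", "x"])
        assert percent_cc(v, v) == 100.0

    def test_disjoint_label_sets(self):
        assert percent_cc(np.array(["a", "a"]), np.array(["b", "b"])) == 0.0

    def test_empty_and_mismatched_rejected(self):
        with pytest.raises(ValueError):
            percent_cc(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            percent_cc(np.array(["a"]), np.array(["a", "b"]))


class TestPerClassCC:
    def test_row_normalised_diagonal(self):
        true = np.array(["A", "A", "B", "B"])
        pred = np.array(["A", "B", "B", "B"])
        accs, cm = per_class_cc(true, pred)
        assert accs == {"A": 50.0, "B": 100.0}
        assert cm.sum() == 4

    def test_perfect_prediction(self):
        true = np.array(["A", "B", "C", "A"])
        accs, _ = per_class_cc(true, true)
        assert all(v == 100.0 for v in accs.values())

    def test_confusion_rows_sum_to_class_counts(self, rng):
        true = rng.choice(["A", "B", "C"], size=30)
        pred = rng.choice(["A", "B", "C"], size=30)
        accs, cm = per_class_cc(true, pred)
        for i, cls in enumerate(np.unique(np.concatenate([true, pred]))):
            assert cm[i].sum() == np.sum(true == cls)

    def test_class_absent_from_true_omitted(self):
        true = np.array(["A", "A", "B", "B"])
        pred = np.array(["A", "C", "B", "B"])
        accs, cm = per_class_cc(true, pred)
        assert set(accs) == {"A", "B"}
        assert cm.shape == (3, 3)


class TestBuildClassifier:
    def test_strong_signal_high_accuracy(self, signal_dataset, tiny_settings):
        passed = 0
        for seed in range(20):
            tc = build_classifier(signal_dataset, seed, settings=tiny_settings)
            passed += tc.test_accuracy >= 80.0
        assert passed >= 18

    def test_params_within_bounds_and_determinism(self, signal_dataset, tiny_settings):
        a = build_classifier(signal_dataset, 3, settings=tiny_settings)
        b = build_classifier(signal_dataset, 3, settings=tiny_settings)
        assert a.test_accuracy == b.test_accuracy
        assert a.opt_params == b.opt_params
        assert a.opt_value == b.opt_value
        assert a.opt_params.bounds.contains(a.opt_params.log2C, a.opt_params.log2gamma)

    def test_accuracy_scored_on_test_rows_only(self, signal_dataset, tiny_settings):
        tc = build_classifier(signal_dataset, 5, settings=tiny_settings)
        assert np.intersect1d(tc.split.train_idx, tc.split.test_idx).size == 0
        assert tc.split.test_idx.size == 6  # 8/8 classes at fraction 1/3

    def test_grid_optimizer_variant(self, signal_dataset, tiny_settings):
        tc = build_classifier(
            signal_dataset, 5, settings=tiny_settings, optimizer="grid"
        )
        assert tc.eval_count >= 121
        with pytest.raises(ValueError, match="unknown optimizer"):
            build_classifier(signal_dataset, 5, optimizer="annealing")


class TestBuildEnsemble:
    def test_cumulative_mean_curve(self, signal_dataset, tiny_settings):
        ens = build_ensemble(
            signal_dataset, n_members=5, settings=tiny_settings, master_seed=2
        )
        acc = np.array([m.test_accuracy for m in ens.members])
        assert ens.accuracy_vs_size[0] == acc[0]
        assert ens.accuracy_vs_size[-1] == pytest.approx(ens.avg_test_accuracy)
        expected = np.cumsum(acc) / np.arange(1, 6)
        assert np.allclose(accuracy_vs_size(ens), expected)
        assert np.allclose(ens.accuracy_vs_size, expected)

    def test_single_member_average(self, signal_dataset, tiny_settings):
        ens = build_ensemble(
            signal_dataset, n_members=1, settings=tiny_settings, master_seed=3
        )
        assert ens.avg_test_accuracy == ens.members[0].test_accuracy

    def test_null_signal_accuracy_near_base_rate(self, null_dataset, tiny_settings):
        ens = build_ensemble(
            null_dataset, n_members=20, settings=tiny_settings, master_seed=4
        )
        # balanced two-class null: majority-class rate is 50%
        assert abs(ens.avg_test_accuracy - 50.0) <= 15.0

    def test_leakage_guard(self, signal_dataset, tiny_settings):
        # no member's test rows may appear in its bootstrap in-bag sets
        # (the objective is built on train_idx only); audited via splits
        ens = build_ensemble(
            signal_dataset, n_members=4, settings=tiny_settings, master_seed=5
        )
        for m in ens.members:
            assert np.intersect1d(m.split.train_idx, m.split.test_idx).size == 0
            union = np.union1d(m.split.train_idx, m.split.test_idx)
            assert union.size == signal_dataset.n_samples

    def test_parallel_equals_sequential(self, signal_dataset, tiny_settings):
        seq = build_ensemble(
            signal_dataset, n_members=4, settings=tiny_settings, master_seed=6,
            n_workers=1,
        )
        par = build_ensemble(
            signal_dataset, n_members=4, settings=tiny_settings, master_seed=6,
            n_workers=2,
        )
        assert seq.avg_test_accuracy == par.avg_test_accuracy
        for a, b in zip(seq.members, par.members):
            assert a.test_accuracy == b.test_accuracy
            assert a.opt_params == b.opt_params

    def test_zero_members_rejected(self, signal_dataset):
        with pytest.raises(ValueError):
            build_ensemble(signal_dataset, n_members=0)


@pytest.fixture(scope="module")
def ensemble(signal_dataset):
    return build_ensemble(
        signal_dataset,
        n_members=5,
        settings=OptimizerSettings(n_boot=10, restarts=1),
        master_seed=8,
    )


class TestEnsemblePredict:
    def test_votes_sum_to_member_count(self, ensemble, signal_dataset):
        res = ensemble_predict(ensemble, signal_dataset.matrix)
        assert (res.vote_matrix.sum(axis=1) == 5).all()
        assert res.labels.shape == (signal_dataset.n_samples,)

    def test_unanimous_vote_fraction_one(self, ensemble, signal_dataset):
        res = ensemble_predict(ensemble, signal_dataset.matrix)
        unanimous = res.vote_matrix.max(axis=1) == 5
        assert unanimous.any()
        assert (res.vote_fraction[unanimous] == 1.0).all()

    def test_winning_fraction_consistent(self, ensemble, signal_dataset):
        res = ensemble_predict(ensemble, signal_dataset.matrix)
        idx = [list(res.classes).index(l) for l in res.labels]
        assert np.allclose(
            res.vote_fraction, res.vote_matrix[np.arange(len(idx)), idx] / 5
        )

    def test_tie_breaks_to_first_sorted_class(self, null_dataset):
        # two members voting differently on null-ish data must sometimes
        # tie; the winner is then the first class in sorted order
        ens = build_ensemble(
            null_dataset, n_members=2,
            settings=OptimizerSettings(n_boot=10, restarts=1), master_seed=9,
        )
        res = ensemble_predict(ens, null_dataset.matrix)
        ties = res.vote_matrix[:, 0] == res.vote_matrix[:, 1]
        assert (res.labels[ties] == res.classes[0]).all()

    def test_dimension_mismatch(self, ensemble):
        with pytest.raises(ValueError):
            ensemble_predict(ensemble, np.ones((3, 4)))
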