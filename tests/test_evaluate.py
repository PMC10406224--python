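"""Volume-wise metrics, stratified folds, reports, Welch tests."""

import math

import numpy as np
import pandas as pd
import pytest

from ichseg.evaluate import (
    ConfusionCounts,
    FoldAssignment,
    MetricConfig,
    confusion_counts,
    make_report,
    stratified_volume_folds,
    volume_metrics,
    welch_pairwise,
)


def hand_welch(a, b):
    """Independent Welch t / df computation from the textbook formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    from scipy.stats import t as tdist

    return 2 * tdist.sf(abs(t), df)


class TestConfusionCounts:
    def test_perfect_prediction(self):
        gt = np.zeros((4, 4, 2), dtype=np.uint8)
        gt[1:3, 1:3, 0] = 1
        c = confusion_counts(gt, gt)
        assert (c.tp, c.fp, c.fn) == (4, 0, 0)

    def test_volume_additivity_over_slices(self):
        # slice counts (2,1,0) and (0,1,3) sum to (2,2,3)
        pred = np.zeros((3, 3, 2), dtype=np.uint8)
        gt = np.zeros((3, 3, 2), dtype=np.uint8)
        gt[0, 0:2, 0] = 1
        pred[0, 0:2, 0] = 1  # 2 TP slice 0
        pred[2, 2, 0] = 1    # 1 FP slice 0
        gt[0, 0:3, 1] = 1    # 3 FN slice 1
        pred[2, 0, 1] = 1    # 1 FP slice 1
        c = confusion_counts(pred, gt)
        assert (c.tp, c.fp, c.fn) == (2, 2, 3)

    def test_empty_both(self):
        z = np.zeros((2, 2, 2))
        assert confusion_counts(z, z) == ConfusionCounts(0, 0, 0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((2, 2)), np.zeros((3, 2)))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0)


class TestVolumeMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((0, 0, 0), (1.0, 1.0, 1.0)),
            ((0, 3, 0), (0.25, 0.25, 1.0)),
            ((5, 0, 0), (1.0, 1.0, 1.0)),
        ],
    )
    def test_epsilon_stabilized_triples(self, counts, expected):
        got = volume_metrics(ConfusionCounts(*counts), MetricConfig(epsilon=1))
        assert got == pytest.approx(expected)

    def test_epsilon_to_zero_recovers_classical_metrics(self):
        c = ConfusionCounts(10, 5, 3)
        for eps in (1e-3, 1e-6):
            d, p, r = volume_metrics(c, MetricConfig(epsilon=eps))
            assert d == pytest.approx(2 * 10 / (2 * 10 + 5 + 3), abs=1e-3)
            assert p == pytest.approx(10 / 15, abs=1e-3)
            assert r == pytest.approx(10 / 13, abs=1e-3)

    def test_scaling_counts_moves_metrics_toward_classical_value(self):
        c1 = ConfusionCounts(2, 2, 2)
        c10 = ConfusionCounts(20, 20, 20)
        classical = 2 * 2 / (2 * 2 + 2 + 2)
        d1 = volume_metrics(c1)[0]
        d10 = volume_metrics(c10)[0]
        assert abs(d10 - classical) < abs(d1 - classical)


class TestStratifiedFolds:
    def _manifest(self, n, n_ich):
        return pd.DataFrame(
            {
                "volume_id": [f"v{i:03d}" for i in range(n)],
                "ich": [i < n_ich for i in range(n)],
            }
        )

    def test_fold_sizes_51_volumes_5_folds(self):
        m = self._manifest(51, 51)
        for seed in range(20):
            folds = stratified_volume_folds(m, 5, seed=seed)
            sizes = sorted(
                sum(1 for f in folds.assignment.values() if f == k) for k in range(5)
            )
            assert sizes == [10, 10, 10, 10, 11]

    def test_every_volume_in_exactly_one_fold(self):
        m = self._manifest(30, 12)
        folds = stratified_volume_folds(m, 5, seed=0)
        assert sorted(folds.assignment) == sorted(m["volume_id"])

    def test_ich_spread_75_volumes_36_ich_10_folds(self):
        m = self._manifest(75, 36)
        for seed in range(20):
            folds = stratified_volume_folds(m, 10, seed=seed)
            ich_ids = set(m.loc[m["ich"], "volume_id"])
            per_fold = [
                sum(1 for v in folds.test_volumes(k) if v in ich_ids) for k in range(10)
            ]
            assert min(per_fold) >= 3

    def test_deterministic_given_seed(self):
        m = self._manifest(20, 8)
        a = stratified_volume_folds(m, 4, seed=5)
        b = stratified_volume_folds(m, 4, seed=5)
        assert a.assignment == b.assignment

    def test_too_few_ich_volumes_rejected(self):
        with pytest.raises(ValueError):
            stratified_volume_folds(self._manifest(20, 3), 5, seed=0)

    def test_train_test_partition(self):
        m = self._manifest(17, 9)
        folds = stratified_volume_folds(m, 3, seed=1)
        for k in range(3):
            test = set(folds.test_volumes(k))
            train = set(folds.train_volumes(k))
            assert test | train == set(m["volume_id"])
            assert not (test & train)


class TestMakeReport:
    def _rows(self, metrics, ich_flags):
        return pd.DataFrame(
            {
                "volume_id": [f"v{i}" for i in range(len(metrics))],
                "ich": ich_flags,
                "dice": metrics,
                "precision": metrics,
                "recall": metrics,
            }
        )

    def test_subset_means_match_manual_aggregation(self):
        rows = self._rows([0.2, 0.4, 0.9, 1.0], [True, True, False, False])
        rep = make_report(rows, method="m")
        assert rep.summary["all_volumes"]["dice"]["mean"] == pytest.approx(0.625)
        assert rep.summary["ich_volumes"]["dice"]["mean"] == pytest.approx(0.3)
        assert rep.summary["ich_volumes"]["dice"]["sd"] == pytest.approx(0.1)

    def test_single_volume_sd_zero(self):
        rep = make_report(self._rows([0.5], [True]))
        assert rep.summary["ich_volumes"]["dice"]["sd"] == 0.0

    def test_all_ich_dataset_subsets_coincide(self):
        rows = self._rows([0.3, 0.6], [True, True])
        rep = make_report(rows)
        assert rep.summary["all_volumes"] == rep.summary["ich_volumes"]

    def test_duplicate_volume_rejected(self):
        rows = self._rows([0.5, 0.6], [True, True])
        rows.loc[1, "volume_id"] = "v0"
        with pytest.raises(ValueError):
            make_report(rows)

    def test_subtype_attribution_counts(self):
        rows = self._rows([0.2, 0.8, 0.5], [True, True, True])
        rows["iph"] = [True, True, False]
        rows["sdh"] = [True, False, False]
        rep = make_report(rows)
        assert rep.summary["per_subtype"]["iph"]["n"] == 2
        assert rep.summary["per_subtype"]["iph"]["dice_mean"] == pytest.approx(0.5)
        assert rep.summary["per_subtype"]["sdh"]["n"] == 1


class TestWelch:
    def test_textbook_samples_match_hand_formula(self):
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([2.0, 3, 4, 5, 6])
        rows = {
            "m1": pd.DataFrame({"dice": a}),
            "m2": pd.DataFrame({"dice": b}),
        }
        pmat = welch_pairwise(rows)
        assert pmat.loc["m1", "m2"] == pytest.approx(hand_welch(a, b), abs=1e-10)

    def test_unequal_sizes_and_variances(self, rng):
        a = rng.normal(0.5, 0.3, size=9)
        b = rng.normal(0.7, 0.05, size=14)
        rows = {"a": pd.DataFrame({"dice": a}), "b": pd.DataFrame({"dice": b})}
        pmat = welch_pairwise(rows)
        assert pmat.loc["a", "b"] == pytest.approx(hand_welch(a, b), abs=1e-10)

    def test_symmetric_with_unit_diagonal(self, rng):
        rows = {
            k: pd.DataFrame({"dice": rng.random(6)}) for k in ("x", "y", "z")
        }
        pmat = welch_pairwise(rows)
        assert np.allclose(pmat.values, pmat.values.T, atol=1e-12)
        assert np.allclose(np.diag(pmat.values), 1.0)

    def test_identical_constant_samples_give_p_one(self):
        rows = {
            "a": pd.DataFrame({"dice": [0.5, 0.5, 0.5]}),
            "b": pd.DataFrame({"dice": [0.5, 0.5, 0.5]}),
        }
        assert welch_pairwise(rows).loc["a", "b"] == 1.0
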