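import logging

import numpy as np
import pytest

from dpseaac import (
    ConfusionCounts,
    EncodingConfig,
    GeneratorSpec,
    LabeledDataset,
    compute_metrics,
    cp20,
    generate_dataset,
    independent_test,
    jackknife,
    kfold_cv,
    roc_auc,
    sweep_distance,
)

CONFIG1 = dict(C=32.0, gamma=2.0)


def small_planted_dataset(n=12, seed=0, **kw):
    spec = GeneratorSpec(n_pos=n, n_neg=n, length_range=(60, 90), seed=seed,
                         **kw)
    return generate_dataset(spec)


class TestComputeMetrics:
    def test_no_false_negatives_gives_sn_1(self):
        rep = compute_metrics(ConfusionCounts(n_plus=10, n_minus=10, fn=0, fp=3))
        assert rep.sn == 1.0

    def test_perfect_prediction_gives_mcc_1(self):
        rep = compute_metrics(ConfusionCounts(n_plus=8, n_minus=12, fn=0, fp=0))
        assert rep.mcc == 1.0 and rep.acc == 1.0 and rep.sp == 1.0

    def test_total_disagreement_gives_mcc_minus_1(self):
        rep = compute_metrics(ConfusionCounts(n_plus=8, n_minus=12, fn=8, fp=12))
        assert rep.mcc == -1.0 and rep.acc == 0.0

    def test_half_errors_give_mcc_0(self):
        rep = compute_metrics(ConfusionCounts(n_plus=10, n_minus=20, fn=5, fp=10))
        assert rep.mcc == pytest.approx(0.0)

    def test_zero_denominator_reported_undefined(self):
        # every sample predicted positive -> TN = FN = 0
        rep = compute_metrics(ConfusionCounts(n_plus=5, n_minus=5, fn=0, fp=5))
        assert rep.mcc is None and not rep.mcc_defined

    def test_counts_validation(self):
        with pytest.raises(ValueError):
            ConfusionCounts(n_plus=5, n_minus=5, fn=6, fp=0)

    def test_agrees_with_bruteforce_tally(self):
        """Sn/Sp/Acc match a per-sample tally on many random vectors."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            y = np.where(rng.random(n) < 0.5, 1, -1)
            if len(set(y)) < 2:
                continue
            p = np.where(rng.random(n) < 0.5, 1, -1)
            rep = compute_metrics(ConfusionCounts.from_predictions(y, p))
            tp = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
            tn = sum(1 for a, b in zip(y, p) if a == -1 and b == -1)
            assert rep.acc == pytest.approx((tp + tn) / n)
            assert rep.sn == pytest.approx(tp / np.sum(y == 1))
            assert rep.sp == pytest.approx(tn / np.sum(y == -1))


class TestRocAuc:
    def test_perfect_ordering(self):
        points, auc = roc_auc([3.0, 2.0, -1.0, -2.0], [1, 1, -1, -1])
        assert auc == 1.0
        assert any(np.array_equal(p, [0.0, 1.0]) for p in points)

    def test_auc_equals_mann_whitney_oracle(self):
        """AUC equals P(score+ > score-) + P(tie)/2 by exhaustive pair
        comparison, including with ties."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            y = np.r_[np.ones(n // 2 + 1, dtype=int),
                      -np.ones(n - n // 2 - 1 + 1, dtype=int)]
            dv = np.round(rng.normal(size=y.size), 1)  # coarse -> ties
            _, auc = roc_auc(dv, y)
            pos = dv[y == 1]
            neg = dv[y == -1]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(wins / (pos.size * neg.size))

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        y = np.where(rng.random(300) < 0.4, 1, -1)
        dv = rng.normal(size=300) + (y == 1) * 0.8
        _, auc = roc_auc(dv, y)
        assert auc == pytest.approx(roc_auc_score(y, dv))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        y = np.where(rng.random(100) < 0.5, 1, -1)
        y[:2] = [1, -1]
        dv = rng.normal(size=100)
        _, auc1 = roc_auc(dv, y)
        _, auc2 = roc_auc(np.exp(3 * dv) + 7, y)
        assert auc1 == pytest.approx(auc2)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestJackknife:
    def test_separable_toy_perfect(self):
        ds = small_planted_dataset(n=5, seed=2, enrichment=20.0)
        config = EncodingConfig(alphabet=cp20(), d_max=1)
        rep = jackknife(ds, config, **CONFIG1)
        assert rep.acc == 1.0

    def test_shuffled_labels_near_chance(self):
        ds = small_planted_dataset(n=15, seed=3, enrichment=1.0)
        config = EncodingConfig(alphabet=cp20(), d_max=1)
        rep = jackknife(ds, config, **CONFIG1)
        assert 0.2 <= rep.acc <= 0.8  # chance on a null set of 30

    def test_performs_n_training_rounds(self, caplog):
        ds = small_planted_dataset(n=4, seed=1)
        config = EncodingConfig(alphabet=cp20(), d_max=1)
        with caplog.at_level(logging.DEBUG, logger="dpseaac.evaluation"):
            jackknife(ds, config, **CONFIG1)
        rounds = [r for r in caplog.records if "jackknife round" in r.message]
        assert len(rounds) == len(ds)

    def test_requires_two_per_class(self):
        ds = LabeledDataset(
            small_planted_dataset(n=3, seed=1).records[:4], [1, 1, 1, -1]
        )
        config = EncodingConfig(alphabet=cp20(), d_max=1)
        with pytest.raises(ValueError):
            jackknife(ds, config, **CONFIG1)


class TestKfold:
    def test_same_seed_same_report(self):
        ds = small_planted_dataset(n=10, seed=4, enrichment=3.0)
        config = EncodingConfig(alphabet=cp20(), d_max=1)
        r1 = kfold_cv(ds, config, k=5, seed=9, **CONFIG1)
        r2 = kfold_cv(ds, config, k=5, seed=9, **CONFIG1)
        assert r1.acc == r2.acc and r1.auc == r2.auc

    def test_k_equal_n_reduces_to_jackknife(self):
        ds = small_planted_dataset(n=5, seed=5)
        config = EncodingConfig(alphabet=cp20(), d_max=1)
        loo = kfold_cv(ds, config, k=len(ds), seed=0, **CONFIG1)
        jk = jackknife(ds, config, **CONFIG1)
        assert loo.acc == jk.acc and loo.counts == jk.counts

    def test_k_exceeding_minority_errors(self):
        ds = small_planted_dataset(n=4, seed=6)
        config = EncodingConfig(alphabet=cp20(), d_max=1)
        with pytest.raises(ValueError):
            kfold_cv(ds, config, k=5, seed=0, **CONFIG1)


def test_sweep_distance_rows_and_baseline():
    ds = small_planted_dataset(n=8, seed=7)
    table, best_d = sweep_distance(ds, cp20(), [0, 1], k=4, seed=1, **CONFIG1)
    assert len(table) == 2
    assert set(table["d"]) == {0, 1}
    assert best_d in (0, 1)
    table0, best0 = sweep_distance(ds, cp20(), [0], k=4, seed=1, **CONFIG1)
    assert len(table0) == 1 and best0 == 0


class TestIndependentTest:
    def test_disjoint_sets_deterministic(self):
        train_ds = small_planted_dataset(n=10, seed=8)
        test_ds = small_planted_dataset(n=6, seed=9)
        test_ds = LabeledDataset(
            [r.__class__(id="t_" + r.id, seq=r.seq) for r in test_ds.records],
            test_ds.labels,
        )
        config = EncodingConfig(alphabet=cp20(), d_max=1)
        r1 = independent_test(train_ds, test_ds, config, **CONFIG1)
        r2 = independent_test(train_ds, test_ds, config, **CONFIG1)
        assert r1.acc == r2.acc and r1.acc > 0.7

    def test_overlap_warns_resubstitution(self):
        ds = small_planted_dataset(n=6, seed=10)
        config = EncodingConfig(alphabet=cp20(), d_max=1)
        with pytest.warns(UserWarning, match="share"):
            rep = independent_test(ds, ds, config, **CONFIG1)
        assert rep.acc >= 0.9  # resubstitution on separable data

    def test_empty_test_set_errors(self):
        ds = small_planted_dataset(n=4, seed=11)
        empty = LabeledDataset([], [])
        config = EncodingConfig(alphabet=cp20(), d_max=1)
        with pytest.raises(ValueError):
            independent_test(ds, empty, config, **CONFIG1)
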