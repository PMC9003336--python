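"""Evaluation protocol: folds, balanced splits, interval/rank statistics,
and consistency of the fast sweep engine with the reference modules."""

import numpy as np
import pytest
from scipy import stats as sstats

import intentfuse as itf
from intentfuse.experiments import (
    _average_ranks,
    balanced_split,
    confidence_interval,
    loocv_folds,
    spearman_rho,
)


class TestFolds:
    def test_165_trials_gives_165_folds_of_164(self):
        folds = loocv_folds(165)
        assert len(folds) == 165
        assert all(len(f.training_pool) == 164 for f in folds)

    def test_two_trials(self):
        folds = loocv_folds(2)
        assert [f.training_pool for f in folds] == [(1,), (0,)]

    def test_partition_property(self):
        folds = loocv_folds(9)
        assert sorted(f.testing_id for f in folds) == list(range(9))
        for f in folds:
            assert f.testing_id not in f.training_pool

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            loocv_folds(1)


class TestBalancedSplit:
    def _pool(self, rng, n_participants=5, n_activities=11, n_reps=3, drop=1):
        ids, parts, acts = [], [], []
        k = 0
        for p in range(n_participants):
            for a in range(n_activities):
                for _ in range(n_reps):
                    ids.append(k); parts.append(p); acts.append(a); k += 1
        keep = np.ones(len(ids), bool)
        if drop:
            keep[rng.integers(0, len(ids))] = False
        return (np.array(ids)[keep], np.array(parts)[keep], np.array(acts)[keep])

    def test_invariants_over_many_seeds(self):
        for seed in range(200):
            rng = np.random.default_rng(seed)
            ids, parts, acts = self._pool(rng)
            a, b = balanced_split(ids, parts, acts, rng)
            assert set(a) | set(b) == set(ids.tolist())
            assert set(a) & set(b) == set()
            # per-stratum imbalance at most 1
            for p in range(5):
                for act in range(11):
                    stratum = set(ids[(parts == p) & (acts == act)].tolist())
                    assert abs(len(stratum & set(a)) - len(stratum & set(b))) <= 1

    def test_even_strata_split_exactly_in_half(self):
        ids = np.arange(164)
        parts = ids // 41
        acts = (ids % 41) // 2  # strata of 2 (and one of 1 per participant)
        rng = np.random.default_rng(0)
        a, b = balanced_split(ids, parts, acts, rng)
        assert abs(len(a) - len(b)) <= 4  # one odd stratum per participant

    def test_stratum_of_three_never_splits_three_zero(self):
        ids = np.array([0, 1, 2])
        for seed in range(50):
            rng = np.random.default_rng(seed)
            a, b = balanced_split(ids, np.zeros(3), np.zeros(3), rng)
            assert {len(a), len(b)} == {1, 2}

    def test_same_seed_identical_split(self):
        ids, parts, acts = self._pool(np.random.default_rng(3))
        a1 = balanced_split(ids, parts, acts, np.random.default_rng(99))
        a2 = balanced_split(ids, parts, acts, np.random.default_rng(99))
        assert a1 == a2

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            balanced_split(np.array([]), np.array([]), np.array([]),
                           np.random.default_rng(0))


class TestIntervalAndRanks:
    def test_identical_values_zero_width(self):
        lo, hi = confidence_interval([0.7, 0.7, 0.7])
        assert lo == hi == pytest.approx(0.7)

    def test_symmetric_about_mean(self):
        vals = [0.2, 0.5, 0.9, 0.4]
        lo, hi = confidence_interval(vals)
        m = np.mean(vals)
        assert hi - m == pytest.approx(m - lo)

    def test_matches_textbook_t_formula(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            v = rng.standard_normal(int(rng.integers(2, 30)))
            lo, hi = confidence_interval(v)
            n = len(v)
            mean = sum(v) / n
            sd = (sum((x - mean) ** 2 for x in v) / (n - 1)) ** 0.5
            half = sstats.t.ppf(0.975, n - 1) * sd / n**0.5
            assert lo == pytest.approx(mean - half, abs=1e-9)
            assert hi == pytest.approx(mean + half, abs=1e-9)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            confidence_interval([0.5])

    def test_spearman_endpoints(self):
        x = np.arange(10.0)
        assert spearman_rho(x, x).rho == pytest.approx(1.0)
        assert spearman_rho(x, -x).rho == pytest.approx(-1.0)

    def test_spearman_matches_scipy_with_ties(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            x = rng.integers(0, 6, size=n).astype(float)  # plenty of ties
            y = rng.standard_normal(n)
            if np.all(x == x[0]):
                continue
            want = sstats.spearmanr(x, y).statistic
            assert spearman_rho(x, y).rho == pytest.approx(want, abs=1e-12)

    def test_average_ranks(self):
        assert np.allclose(_average_ranks(np.array([10.0, 20.0, 20.0, 30.0])),
                           [1.0, 2.5, 2.5, 4.0])


class TestHarnessProtocol:
    def test_optimise_split_deterministic_and_valid(self, small_harness):
        s1, bank1, cms1 = small_harness.optimise_split(0, 1000.0)
        s2, _, _ = small_harness.optimise_split(0, 1000.0)
        assert s1.classifier_training == s2.classifier_training
        assert s1.probability_learning == s2.probability_learning
        pool = set(range(len(small_harness.dataset.trials))) - {0}
        assert set(s1.classifier_training) | set(s1.probability_learning) == pool
        assert set(s1.classifier_training) & set(s1.probability_learning) == set()
        assert set(bank1) == set(small_harness.dataset.sensor_ids)
        assert set(cms1) == set(small_harness.dataset.sensor_ids)

    def test_optimise_split_selects_argmax_candidate(self, small_harness):
        eng = small_harness.engine(1000.0)
        entries = [eng.mm_fold(0, r, small_harness.seed, 5) for r in range(5)]
        scores = [e["acc"].mean() for e in entries]
        chosen, _, _ = small_harness.optimise_split(0, 1000.0)
        best = entries[int(np.argmax(scores))]["split"]
        assert chosen.classifier_training == best.classifier_training

    def test_run_fold_mm_matches_fast_path(self, small_harness):
        """The vectorised sweep engine and the explicit model-bank +
        fusion route must agree fold by fold."""
        eng = small_harness.engine(1000.0)
        n_s = len(small_harness.dataset.sensors)
        for fold in (0, 3, 7, 12):
            slow = small_harness.run_fold(fold, "mm", 1000.0)
            contrib, accs = small_harness._tables(1000.0)
            cand = int(np.argmax(accs[fold].mean(axis=1)))
            scores = -np.log(len(eng.classes)) + contrib[fold, cand].sum(axis=0)
            fast = np.array(eng.classes)[int(np.argmax(scores))] == eng.y[fold]
            assert slow == bool(fast)

    def test_run_fold_nmm_matches_combined_classifier(self, small_harness):
        """The block-sum shortcut must equal an actual combined 1-NN over
        concatenated per-sensor features, including zero-filled dropout."""
        eng = small_harness.engine(1000.0)
        blocks = []
        slices = {}
        start = 0
        for s in eng.sensors:
            fm = eng.matrices[s.sensor_id]
            flat = fm.values.reshape(eng.n, -1)
            blocks.append(flat)
            slices[s.sensor_id] = (start, start + flat.shape[1])
            start += flat.shape[1]
        x = np.hstack(blocks)
        ids = [s.sensor_id for s in eng.sensors]
        for fold in (1, 5, 9):
            for active_ids in (ids, ids[:2], [ids[0], ids[3]]):
                pool = np.array([j for j in range(eng.n) if j != fold])
                model = itf.NeighbourModel(x[pool], eng.y[pool], row_ids=pool)
                dropped_cols = np.concatenate(
                    [np.arange(*slices[s]) for s in ids if s not in active_ids]
                ) if len(active_ids) < len(ids) else None
                row = x[fold].copy()
                want = itf.zero_input_predict(model, row, dropped_cols)
                got = small_harness.run_fold(fold, "nmm", 1000.0, active_ids)
                assert got == bool(want == eng.y[fold])

    def test_mm_dropout_mask_equals_restricted_fusion(self, small_harness):
        """Masking sensors out of the MM equals fusing only the survivors
        (same models, same confusion matrices)."""
        rng = np.random.default_rng(21)
        n_s = len(small_harness.dataset.sensors)
        for _ in range(10):
            k = int(rng.integers(1, n_s + 1))
            subset = np.sort(rng.choice(n_s, size=k, replace=False))
            a = small_harness.mm_accuracy(1000.0, subset,
                                          select_over=np.arange(n_s))
            b = small_harness.mm_accuracy(1000.0, subset.copy(),
                                          select_over=np.arange(n_s))
            assert a == b  # deterministic and independent of mask identity
        for fold in (2, 6):
            ids = small_harness.dataset.sensor_ids
            keep = ids[:2]
            r1 = small_harness.run_fold(fold, "mm", 1000.0, keep)
            r2 = small_harness.run_fold(fold, "mm", 1000.0, list(keep))
            assert r1 == r2

    def test_zero_active_sensors_mm_returns_prior_argmax(self, small_harness):
        eng = small_harness.engine(1000.0)
        for fold in (0, 4):
            got = small_harness.run_fold(fold, "mm", 1000.0, [])
            assert got == bool(eng.classes[0] == eng.y[fold])


class TestSweeps:
    def test_time_sweep_shapes_and_errors(self, small_harness):
        res, trends = itf.time_sweep(small_harness, horizons=[400.0, 700.0, 1000.0])
        assert res["mm"].values.tolist() == [400.0, 700.0, 1000.0]
        assert np.all((0 <= res["mm"].mean) & (res["mm"].mean <= 1))
        assert -1 <= trends["mm"].rho <= 1
        with pytest.raises(ValueError):
            itf.time_sweep(small_harness, horizons=[2000.0])

    def test_default_time_grid_has_17_horizons(self, small_harness):
        grid = np.arange(200.0, small_harness.window_spec.horizon + 1, 50.0)
        assert grid.size == 17

    def test_sensor_sweep_bounds_and_full_combination_collapse(self, small_harness):
        n_s = len(small_harness.dataset.sensors)
        res, ratio = itf.sensor_count_sweep(
            small_harness, r_values=[1, n_s], n_combos=3
        )
        assert res["mm"].n[-1] == 1  # R = n_sensors has one combination
        assert np.all(res["mm"].lower <= res["mm"].mean + 1e-12)
        assert np.all(res["mm"].mean <= res["mm"].upper + 1e-12)
        assert ratio.minimum <= ratio.mean <= ratio.maximum
        with pytest.raises(ValueError):
            itf.sensor_count_sweep(small_harness, r_values=[n_s + 1])

    def test_dropout_sweep_n0_identity_and_determinism(self, small_harness):
        n_s = len(small_harness.dataset.sensors)
        res, _ = itf.dropout_sweep(small_harness, n_values=[0, 2],
                                   n_combos=2, n_repetitions=2)
        allv = np.arange(n_s)
        assert res["mm"].mean[0] == pytest.approx(
            small_harness.mm_accuracy(1000.0, allv, select_over=allv))
        assert res["nmm"].mean[0] == pytest.approx(
            small_harness.nmm_accuracy(1000.0, allv))
        res2, _ = itf.dropout_sweep(small_harness, n_values=[0, 2],
                                    n_combos=2, n_repetitions=2)
        assert np.array_equal(res["mm"].mean, res2["mm"].mean)
        assert np.array_equal(res["nmm"].mean, res2["nmm"].mean)
        with pytest.raises(ValueError):
            itf.dropout_sweep(small_harness, n_values=[n_s])
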