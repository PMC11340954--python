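import numpy as np
import pytest

import stackpep as sp
from stackpep.selection import SelectionStep, SelectionTrace, _awclr_ranking
from stackpep.stacking import ProbabilityMatrix


def toy_pm(n=60, n_models=4, signal=(0, 1), seed=0, noise_scale=1.0):
    rng = np.random.default_rng(seed)
    y = (np.arange(n) % 3 == 0).astype(float)
    X = rng.random((n, n_models)) * noise_scale
    for j in signal:
        X[:, j] = np.clip(0.6 * y + 0.4 * rng.random(n), 0, 1)
    folds = np.arange(n) % 5
    keys = [f"m{j}" for j in range(n_models)]
    return ProbabilityMatrix(X, keys, y, folds)


class FakeModel:
    def __init__(self, key, auc):
        self.model_key, self.cv_auc = key, auc
        from stackpep.metrics import MetricsReport
        self.cv_metrics = MetricsReport(0, 0, 0, 0, 0, 0, 0, auc, 0, AUC=auc)


def fake_models_for(pm, aucs=None):
    aucs = aucs or {k: sp.roc_auc(pm.labels, pm.values[:, j])
                    for j, k in enumerate(pm.model_keys)}
    out = []
    for k in pm.model_keys:
        m = FakeModel(k, aucs[k])
        m.cv_metrics.ACC = 0.9
        out.append(m)
    return out


class TestSAAUC:
    def test_trace_is_nested_and_auc_ordered(self):
        pm = toy_pm()
        trace = sp.saauc(fake_models_for(pm), pm, seed=0)
        assert len(trace.steps) == 4
        for a, b in zip(trace.steps, trace.steps[1:]):
            assert set(a.members) < set(b.members)
        # first member is the best single model by AUC
        aucs = {k: sp.roc_auc(pm.labels, pm.values[:, j])
                for j, k in enumerate(pm.model_keys)}
        assert trace.steps[0].members == [max(aucs, key=aucs.get)]

    def test_full_step_equals_fit_meta_on_all(self):
        pm = toy_pm()
        trace = sp.saauc(fake_models_for(pm), pm, seed=0)
        meta = sp.fit_meta(pm.select(trace.steps[-1].members), seed=0)
        assert trace.steps[-1].auc == pytest.approx(meta.cv_metrics.AUC)


class TestSAWC:
    def test_addition_order_follows_global_awclr(self):
        pm = toy_pm()
        trace = sp.sawc(fake_models_for(pm), pm, seed=0)
        full = sp.fit_meta(pm, "LR", seed=0)
        expect = _awclr_ranking(sp.extract_awclr(full))
        assert trace.steps[-1].members == expect
        for a, b in zip(trace.steps, trace.steps[1:]):
            assert set(a.members) < set(b.members)

    def test_hand_stepped_small_trace(self):
        """4-model trace equals manual walk-through with a reference fit."""
        pm = toy_pm(seed=5)
        trace = sp.sawc(fake_models_for(pm), pm, seed=0)
        ranking = _awclr_ranking(
            sp.extract_awclr(sp.fit_meta(pm, "LR", seed=0)))
        for X in range(1, 5):
            ref = sp.fit_meta(pm.select(ranking[:X]), "LR", seed=0)
            assert trace.steps[X - 1].members == ranking[:X]
            assert trace.steps[X - 1].auc == pytest.approx(ref.cv_metrics.AUC)


class TestSDIWC:
    def test_two_models_survivor_has_larger_awclr(self):
        pm = toy_pm(n_models=2, signal=(0,))
        trace = sp.sdiwc(fake_models_for(pm), pm, seed=0)
        assert len(trace.steps) == 2
        first = trace.steps[0]
        survivor = max(first.awclr, key=lambda k: first.awclr[k])
        assert trace.steps[1].members == [survivor]

    def test_single_deletion_per_step(self):
        pm = toy_pm(n_models=6, signal=(0, 3))
        trace = sp.sdiwc(fake_models_for(pm), pm, seed=0)
        assert [s.X for s in trace.steps] == [6, 5, 4, 3, 2, 1]
        for a, b in zip(trace.steps, trace.steps[1:]):
            removed = set(a.members) - set(b.members)
            assert len(removed) == 1
            victim = removed.pop()
            low = min(a.awclr.values())
            assert a.awclr[victim] == low

    def test_noise_column_deleted_early(self):
        hits = 0
        for seed in range(5):
            pm = toy_pm(n_models=4, signal=(0, 1, 2), seed=seed)
            pm.values[:, 3] = np.random.default_rng(seed).random(len(pm.labels))
            trace = sp.sdiwc(fake_models_for(pm), pm, seed=seed)
            deleted_first_two = set(trace.steps[0].members) - set(
                trace.steps[2].members)
            if "m3" in deleted_first_two:
                hits += 1
        assert hits >= 4

    def test_needs_two_models(self):
        pm = toy_pm(n_models=1, signal=(0,))
        with pytest.raises(ValueError):
            sp.sdiwc(fake_models_for(pm), pm, seed=0)

    def test_matches_naive_reimplementation(self):
        """Member deletion sequence equals an independent brute-force loop."""
        from sklearn.linear_model import LogisticRegression

        def naive_sdiwc(pm):
            keys = list(pm.model_keys)
            seq = []
            while len(keys) > 1:
                idx = [pm.model_keys.index(k) for k in keys]
                lr = LogisticRegression(C=1.0, max_iter=5000, random_state=0)
                lr.fit(pm.values[:, idx], pm.labels)
                aw = dict(zip(keys, np.abs(lr.coef_.ravel())))
                low = min(aw.values())
                victim = max(k for k, v in aw.items() if v == low)
                seq.append(victim)
                keys.remove(victim)
            return seq, keys

        for seed in (0, 1, 2):
            pm = toy_pm(n=60, n_models=6, signal=(0, 2), seed=seed)
            trace = sp.sdiwc(fake_models_for(pm), pm, seed=0)
            got = [(set(a.members) - set(b.members)).pop()
                   for a, b in zip(trace.steps, trace.steps[1:])]
            want, survivor = naive_sdiwc(pm)
            assert got == want
            assert trace.steps[-1].members == survivor


class TestAccuracyPrefilter:
    def test_baseline_from_imbalanced_counts(self):
        y = np.concatenate([np.ones(313), np.zeros(2908)])
        base = sp.majority_class_baseline(y)
        assert base == pytest.approx(2908 / 3221)
        models = [FakeModel("hi", 0.9), FakeModel("lo", 0.6)]
        models[0].cv_metrics.ACC = 0.95
        models[1].cv_metrics.ACC = 0.89
        kept = sp.filter_by_accuracy(models, y)
        assert [m.model_key for m in kept] == ["hi"]

    def test_balanced_baseline_half(self):
        assert sp.majority_class_baseline([0, 1, 0, 1]) == 0.5

    def test_all_below_warns_empty(self):
        m = FakeModel("x", 0.5)
        m.cv_metrics.ACC = 0.4
        with pytest.warns(UserWarning, match="baseline"):
            assert sp.filter_by_accuracy([m], [0, 0, 1, 1]) == []


class TestSelectBest:
    def _trace(self, aucs):
        t = SelectionTrace("SAAUC")
        t.steps = [SelectionStep(x, [f"m{i}" for i in range(x)], a, 0.0)
                   for x, a in enumerate(aucs, start=1)]
        return t

    def test_argmax(self):
        assert self._trace([0.7, 0.9, 0.85]).best_X == 2

    def test_tie_takes_smallest_x(self):
        t = self._trace([0.7, 0.9, 0.8, 0.8, 0.9])
        assert t.best_X == 2

    def test_monotone_takes_full_set(self):
        assert self._trace([0.6, 0.7, 0.8]).best_X == 3

    def test_empty_trace_errors(self):
        with pytest.raises(ValueError):
            SelectionTrace("SAAUC").best_step()

    def test_select_best_returns_members(self):
        t = self._trace([0.7, 0.9])
        assert sp.select_best(t) == ["m0", "m1"]

    def test_plateau_detector(self):
        t = self._trace([0.5, 0.89, 0.9, 0.8995, 0.899])
        assert t.plateau_X() == 3
        assert self._trace([0.5, 0.9, 0.5, 0.9, 0.5]).plateau_X() is None


def test_informative_columns_retained_in_best_subset():
    """Complementary signal columns survive selection amid noise columns.

    Each signal column detects a disjoint half of the positives, so the
    argmax-AUC subset needs both; noise columns should be pruned.
    """
    retained = 0
    runs = 20
    for seed in range(runs):
        rng = np.random.default_rng(seed)
        n, s, t = 80, 2, 3
        y = (np.arange(n) % 4 == 0).astype(float)
        half = rng.random(n) < 0.5  # which signal column sees each positive
        X = rng.random((n, s + t)) * 0.5
        X[:, 0] = np.where(y.astype(bool) & half, 0.8 + 0.2 * rng.random(n),
                           0.4 * rng.random(n))
        X[:, 1] = np.where(y.astype(bool) & ~half, 0.8 + 0.2 * rng.random(n),
                           0.4 * rng.random(n))
        pm = ProbabilityMatrix(X, [f"m{j}" for j in range(s + t)], y,
                               np.arange(n) % 5)
        trace = sp.sdiwc(fake_models_for(pm), pm, seed=seed)
        if {"m0", "m1"} <= set(trace.best_members):
            retained += 1
    assert retained / runs >= 0.9
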