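"""Metrics, curves, the DeLong test, folds and hyperparameter search."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from ubisite.evaluation import (Confusion, DEFAULT_DT, SearchError,
                                auprc, auroc, compute_metrics, confusion_at,
                                delong_test, evaluate_scores, hp_search,
                                pr_points, roc_points, stratified_kfold,
                                threshold_at_fpr)


def _metrics_oracle(tp, fp, tn, fn):
    """Direct-formula oracle, independent of the implementation."""
    out = {}
    out["precision"] = tp / (tp + fp) if tp + fp else 0.0
    out["recall"] = tp / (tp + fn) if tp + fn else 0.0
    pr, rc = out["precision"], out["recall"]
    out["f1"] = 2 * pr * rc / (pr + rc) if pr + rc else 0.0
    out["accuracy"] = (tp + tn) / (tp + fp + tn + fn)
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    out["mcc"] = ((tp * tn - fp * fn) / den) if den else 0.0
    return out


def _mann_whitney_auroc(scores, labels):
    """All-pairs oracle: P(pos > neg) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _average_precision_oracle(scores, labels):
    """Rank-based oracle: sum precision-at-k over positive hits."""
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    hits = 0
    total = 0.0
    # ties: group scores, all members of a tie group share the group stats
    i = 0
    s = scores[order]
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:
            j += 1
        group_pos = y[i:j].sum()
        if group_pos:
            prec = (hits + group_pos) / j
            total += group_pos * prec
        hits += group_pos
        i = j
    return total / labels.sum()


class TestConfusionAt:
    def test_simple_example(self):
        c = confusion_at([0.9, 0.1], [1, 0], 0.4)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 0, 1, 0)

    def test_zero_threshold_everything_positive(self):
        c = confusion_at([0.3, 0.0, 0.8], [1, 0, 0], 0.0)
        assert (c.fp, c.tn) == (2, 0)

    def test_boundary_score_counts_positive(self):
        c = confusion_at([0.4], [1], 0.4)
        assert c.tp == 1

    def test_matches_loop_oracle(self, rng):
        for _ in range(50):
            s = rng.random(30)
            y = (rng.random(30) < 0.3).astype(int)
            t = rng.random()
            c = confusion_at(s, y, t)
            tp = sum(1 for si, yi in zip(s, y) if si >= t and yi == 1)
            fp = sum(1 for si, yi in zip(s, y) if si >= t and yi == 0)
            fn = sum(1 for si, yi in zip(s, y) if si < t and yi == 1)
            tn = sum(1 for si, yi in zip(s, y) if si < t and yi == 0)
            assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)


class TestComputeMetrics:
    def test_perfect_classifier(self):
        rep = compute_metrics(Confusion(tp=50, fp=0, tn=50, fn=0))
        assert (rep.precision, rep.recall, rep.f1, rep.accuracy,
                rep.mcc) == (1, 1, 1, 1, 1)

    def test_symmetric_chance(self):
        rep = compute_metrics(Confusion(tp=25, fp=25, tn=25, fn=25))
        assert rep.mcc == 0.0
        assert rep.accuracy == 0.5

    def test_degenerate_cells_flagged_not_raised(self):
        rep = compute_metrics(Confusion(tp=0, fp=0, tn=10, fn=0))
        assert rep.precision == 0.0
        assert "precision" in rep.degenerate
        assert "mcc" in rep.degenerate

    def test_random_confusions_match_oracle(self, rng):
        for _ in range(200):
            tp, fp, tn, fn = rng.integers(0, 50, size=4)
            if tp + fp + tn + fn == 0:
                continue
            rep = compute_metrics(Confusion(int(tp), int(fp), int(tn),
                                            int(fn)))
            ora = _metrics_oracle(tp, fp, tn, fn)
            for name, val in ora.items():
                assert getattr(rep, name) == pytest.approx(val, abs=1e-12)


class TestRoc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_chance_level_on_independent_scores(self):
        rng = np.random.Generator(np.random.PCG64(17))
        s = rng.random(2000)
        y = (rng.random(2000) < 0.3).astype(int)
        assert abs(auroc(s, y) - 0.5) < 0.03

    def test_matches_mann_whitney_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            s = np.round(rng.random(n), 2)  # rounding forces ties
            y = (rng.random(n) < 0.4).astype(int)
            if y.sum() in (0, n):
                continue
            assert auroc(s, y) == pytest.approx(
                _mann_whitney_auroc(s, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        s = rng.random(200)
        y = (rng.random(200) < 0.3).astype(int)
        assert auroc(np.exp(5 * s), y) == pytest.approx(auroc(s, y),
                                                        abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_points([0.5, 0.6], [1, 1])


class TestPr:
    def test_perfect_separation(self):
        assert auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_give_prevalence(self):
        y = np.array([1, 0, 0, 0, 1])
        assert auprc(np.full(5, 0.5), y) == pytest.approx(0.4)

    def test_matches_rank_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            s = np.round(rng.random(n), 2)
            y = (rng.random(n) < 0.4).astype(int)
            if y.sum() == 0:
                continue
            assert auprc(s, y) == pytest.approx(
                _average_precision_oracle(s, y), abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_points([0.5, 0.6], [0, 0])


class TestThresholdAtFpr:
    def test_small_fixture(self):
        res = threshold_at_fpr([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 0], 0.05)
        assert res.threshold == pytest.approx(0.8)
        assert res.achieved_fpr == 0.0
        assert not res.unreachable

    def test_loose_target_admits_one_fp(self):
        res = threshold_at_fpr([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 0], 0.5)
        assert res.threshold == pytest.approx(0.4)
        assert res.achieved_fpr == pytest.approx(0.5)

    def test_achieved_never_exceeds_target(self, rng):
        for _ in range(50):
            s = rng.random(40)
            y = (rng.random(40) < 0.4).astype(int)
            if len(np.unique(y)) < 2:
                continue
            target = float(rng.uniform(0.02, 0.5))
            res = threshold_at_fpr(s, y, target)
            neg = s[y == 0]
            assert np.mean(neg >= res.threshold) <= target

    def test_unreachable_target_flagged(self):
        res = threshold_at_fpr([0.5, 0.5], [1, 0], 0.3)
        assert res.unreachable
        assert res.achieved_fpr == 0.0
        assert res.threshold > 0.5

    def test_threshold_free_metrics_invariant_to_strategy(self, rng):
        """Evaluating the same scores at DT=0.4 and at a fixed FPR changes
        only the confusion-based metrics, never AUROC/AUPRC."""
        s = rng.random(300)
        y = (rng.random(300) < 0.3).astype(int)
        at_dt = evaluate_scores(s, y, threshold=DEFAULT_DT)
        t = threshold_at_fpr(s, y, 0.05).threshold
        at_fpr = evaluate_scores(s, y, threshold=t)
        assert at_dt.auroc == at_fpr.auroc
        assert at_dt.auprc == at_fpr.auprc


def _bootstrap_delong_p(scores_a, scores_b, labels, n_boot=2000, seed=0):
    """Stratified-bootstrap oracle for the AUROC-difference p-value."""
    rng = np.random.Generator(np.random.PCG64(seed))
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.r_[rng.choice(pos, len(pos)), rng.choice(neg, len(neg))]
        y = labels[idx]
        deltas[b] = (_mann_whitney_auroc(scores_a[idx], y)
                     - _mann_whitney_auroc(scores_b[idx], y))
    observed = (_mann_whitney_auroc(scores_a, labels)
                - _mann_whitney_auroc(scores_b, labels))
    z = observed / deltas.std(ddof=1)
    return float(2 * norm.sf(abs(z)))


class TestDeLong:
    def test_identical_classifiers(self):
        rng = np.random.Generator(np.random.PCG64(3))
        s = rng.random(50)
        y = (rng.random(50) < 0.4).astype(int)
        res = delong_test(s, s, y)
        assert res.delta == 0.0
        assert res.p_value == 1.0

    def test_delta_matches_auroc_difference(self, rng):
        for _ in range(30):
            n = int(rng.integers(20, 80))
            sa, sb = rng.random(n), rng.random(n)
            y = (rng.random(n) < 0.4).astype(int)
            if len(np.unique(y)) < 2:
                continue
            res = delong_test(sa, sb, y)
            expected = (_mann_whitney_auroc(sa, y)
                        - _mann_whitney_auroc(sb, y))
            assert res.delta == pytest.approx(expected, abs=1e-12)
            assert res.auc_a == pytest.approx(_mann_whitney_auroc(sa, y),
                                              abs=1e-12)

    def test_p_value_against_bootstrap_oracle(self):
        """On a 300-sample fixture the asymptotic p is close to a
        2,000-resample stratified-bootstrap p."""
        rng = np.random.Generator(np.random.PCG64(8))
        n = 300
        y = np.r_[np.ones(100, dtype=int), np.zeros(200, dtype=int)]
        signal = y + rng.standard_normal(n)
        sa = signal + 0.6 * rng.standard_normal(n)
        sb = signal + 1.1 * rng.standard_normal(n)
        res = delong_test(sa, sb, y)
        p_boot = _bootstrap_delong_p(sa, sb, y)
        # both are estimates of the same tail probability; compare on the
        # z scale where Monte-Carlo error is roughly additive
        z_delong = abs(norm.isf(res.p_value / 2))
        z_boot = abs(norm.isf(p_boot / 2))
        assert abs(z_delong - z_boot) < 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            delong_test([0.1, 0.2], [0.3, 0.4], [1, 1])


class TestStratifiedKfold:
    def test_divisible_case_exact_proportions(self):
        y = np.r_[np.ones(50, dtype=int), np.zeros(250, dtype=int)]
        folds = stratified_kfold(y, k=5, seed=1)
        for fold in folds:
            assert y[fold].sum() == 10
            assert len(fold) == 60

    def test_folds_partition_indices(self):
        y = (np.arange(103) % 3 == 0).astype(int)
        folds = stratified_kfold(y, k=5, seed=2)
        flat = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(flat, np.arange(103))

    def test_same_seed_identical(self):
        y = (np.arange(60) % 4 == 0).astype(int)
        a = stratified_kfold(y, k=3, seed=9)
        b = stratified_kfold(y, k=3, seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_small_class_rejected(self):
        y = np.r_[np.ones(3, dtype=int), np.zeros(50, dtype=int)]
        with pytest.raises(ValueError):
            stratified_kfold(y, k=5)


class TestHpSearch:
    def test_single_point_space(self):
        best, trials = hp_search(lambda p: 1.0, {"lr": [1e-3]}, n_trials=1,
                                 seed=0)
        assert best == {"lr": 1e-3}
        assert len(trials) == 1

    def test_best_trial_bookkeeping(self):
        def objective(params):
            return -(params["x"] - 0.3) ** 2

        best, trials = hp_search(objective, {"x": ("uniform", 0, 1)},
                                 n_trials=25, seed=4)
        best_logged = max((t for t in trials if t.state == "complete"),
                          key=lambda t: t.value)
        assert objective(best) == pytest.approx(best_logged.value, abs=1e-12)

    def test_failed_trials_skipped(self):
        calls = {"n": 0}

        def flaky(params):
            calls["n"] += 1
            if params["x"] < 0.5:
                raise RuntimeError("bad region")
            return params["x"]

        best, trials = hp_search(flaky, {"x": ("uniform", 0, 1)},
                                 n_trials=20, seed=1)
        assert best["x"] >= 0.5
        assert any(t.state == "failed" for t in trials)

    def test_all_failed_raises(self):
        def always_fails(params):
            raise RuntimeError("nope")

        with pytest.raises(SearchError):
            hp_search(always_fails, {"x": [1]}, n_trials=3, seed=0)

    def test_selects_class_weighting_when_it_helps(self):
        """On a task where (by construction) one flag value scores higher,
        the search must pick that value."""
        def oracle_objective(params):
            base = 0.4 if params["class_weighting"] else 0.2
            return base + 0.01 * params["num_blocks"]

        best, _ = hp_search(
            oracle_objective,
            {"class_weighting": [True, False], "num_blocks": ("int", 1, 3)},
            n_trials=20, seed=2)
        assert best["class_weighting"] is True
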