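"""Screening statistics, combination optimisation, and benchmarks."""

import itertools
import math

import numpy as np
import pytest

from pharmensemble.clustering import Clustering, Fingerprint
from pharmensemble.ensemble import (CombinationResult, ConfusionMatrix,
                                    HitMatrix, ScreeningStats, accuracy,
                                    best_combination, classify,
                                    cluster_medoid, confusion,
                                    evaluate_combination, gain_percent,
                                    greedy_combination, mcc,
                                    optimization_curve, random_benchmark,
                                    recall, screen, universal_hypothesis)
from pharmensemble.selection import TestSetPair


# ----------------------------------------------------------------------
# statistics
# ----------------------------------------------------------------------

@pytest.mark.parametrize("row,mode,expected", [
    ([1, 0, 0], "hit_once", "active"),
    ([1, 0, 0], "hit_twice", "inactive"),
    ([1, 1, 0], "hit_twice", "active"),
    ([0, 0, 0], "hit_once", "inactive"),
])
def test_classify_rules(row, mode, expected):
    assert classify(row, mode) == expected


def test_confusion_hand_counted():
    preds = ["active", "inactive", "active", "active", "inactive"]
    truth = ["active", "active", "inactive", "active", "inactive"]
    cm = confusion(preds, truth)
    assert (cm.TP, cm.FN, cm.FP, cm.TN) == (2, 1, 1, 1)
    with pytest.raises(ValueError):
        confusion(["active"], [])


@pytest.mark.parametrize("cm,exp_mcc,exp_acc,exp_rec", [
    # single-hypothesis screening rows reported for a 1423/286 validation set
    (ConfusionMatrix(TP=639, FN=784, TN=227, FP=59), 0.184, 0.507, 0.449),
    (ConfusionMatrix(TP=459, FN=964, TN=250, FP=36), 0.162, 0.415, 0.323),
    (ConfusionMatrix(TP=399, FN=1024, TN=251, FP=35), 0.136, 0.380, 0.280),
])
def test_statistics_reference_values(cm, exp_mcc, exp_acc, exp_rec):
    assert mcc(cm) == pytest.approx(exp_mcc, abs=5e-4)
    assert accuracy(cm) == pytest.approx(exp_acc, abs=5e-4)
    assert recall(cm) == pytest.approx(exp_rec, abs=5e-4)


def test_mcc_extremes_and_zero_convention():
    assert mcc(ConfusionMatrix(10, 0, 10, 0)) == 1.0
    assert mcc(ConfusionMatrix(5, 5, 5, 5)) == 0.0
    assert mcc(ConfusionMatrix(0, 0, 5, 5)) == 0.0   # zero denominator factor


def test_label_inversion_flips_mcc_sign():
    rng = np.random.default_rng(0)
    for _ in range(20):
        tp, fp, tn, fn = rng.integers(1, 50, 4)
        cm = ConfusionMatrix(int(tp), int(fp), int(tn), int(fn))
        inv = ConfusionMatrix(TP=int(fn), FP=int(tn), TN=int(fp), FN=int(tp))
        assert mcc(inv) == pytest.approx(-mcc(cm))


def test_gain_percent_reference():
    """Optimized 0.920 vs random mean 0.773 gives a 19.02% gain."""
    assert gain_percent(0.920, 0.773) == pytest.approx(19.02, abs=5e-3)
    assert gain_percent(0.5, 0.5) == 0.0


# ----------------------------------------------------------------------
# toy hit matrices
# ----------------------------------------------------------------------

def toy_matrix(rng, n_comp=10, n_hyp=4):
    hits = rng.random((n_comp, n_hyp)) < 0.4
    cids = [f"c{i}" for i in range(n_comp)]
    hids = [f"h{j}" for j in range(n_hyp)]
    return HitMatrix(cids, hids, hits)


def toy_pair(cids, n_act):
    rest = cids[n_act:]
    half = len(rest) // 2
    return TestSetPair(cids[:n_act], rest[:half], rest[half:], "random")


def naive_best(hm, pair, metric, mode, k):
    """Independent brute-force oracle: re-derives every score from raw
    loops over subsets, compounds and labels."""
    need = 1 if mode == "hit_once" else 2
    best_score, best_set = None, None
    for combo in itertools.combinations(sorted(hm.hyp_ids), k):
        cols = [hm.hyp_ids.index(h) for h in combo]
        vals = []
        for neg in (pair.decoys, pair.assumed_inactives):
            tp = fn = fp = tn = 0
            for cid in pair.actives:
                row = hm.hits[hm.compound_ids.index(cid)]
                if sum(bool(row[c]) for c in cols) >= need:
                    tp += 1
                else:
                    fn += 1
            for cid in neg:
                row = hm.hits[hm.compound_ids.index(cid)]
                if sum(bool(row[c]) for c in cols) >= need:
                    fp += 1
                else:
                    tn += 1
            if metric == "recall":
                vals.append(tp / (tp + fn))
            elif metric == "accuracy":
                vals.append((tp + tn) / (tp + fn + fp + tn))
            else:
                den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
                vals.append((tp * tn - fp * fn) / den if den else 0.0)
        score = sum(vals) / 2
        if best_score is None or score > best_score:
            best_score, best_set = score, combo
    return best_score, best_set


class TestOptimizer:
    def test_full_set_is_only_candidate(self):
        hm = toy_matrix(np.random.default_rng(0))
        pair = toy_pair(hm.compound_ids, 4)
        res = best_combination(hm, pair, "mcc", "hit_once", k=4)
        assert set(res.hyp_ids) == set(hm.hyp_ids)

    def test_matches_naive_oracle_on_random_instances(self):
        """Exhaustive optimizer equals an independently coded naive
        enumerator (score and winning set) on 50 random toy instances."""
        rng = np.random.default_rng(42)
        for trial in range(50):
            n_comp = int(rng.integers(6, 13))
            n_hyp = int(rng.integers(2, 7))
            hm = toy_matrix(rng, n_comp, n_hyp)
            n_act = int(rng.integers(2, n_comp - 3))
            pair = toy_pair(hm.compound_ids, n_act)
            metric = ["mcc", "accuracy", "recall"][trial % 3]
            mode = ["hit_once", "hit_twice"][trial % 2]
            for k in range(1, n_hyp + 1):
                res = best_combination(hm, pair, metric, mode, k)
                oracle_score, oracle_set = naive_best(hm, pair, metric, mode, k)
                assert res.score() == pytest.approx(oracle_score)
                assert tuple(sorted(res.hyp_ids)) == oracle_set

    def test_budget_guard(self):
        hm = toy_matrix(np.random.default_rng(1), n_hyp=6)
        pair = toy_pair(hm.compound_ids, 4)
        with pytest.raises(ValueError, match="greedy"):
            best_combination(hm, pair, "mcc", "hit_once", k=3, budget=2)
        res = greedy_combination(hm, pair, "mcc", "hit_once", k=3)
        assert len(res.hyp_ids) == 3

    def test_stats_average_of_pairs(self):
        hm = toy_matrix(np.random.default_rng(3))
        pair = toy_pair(hm.compound_ids, 4)
        res = evaluate_combination(hm, list(hm.hyp_ids[:2]), "hit_once", pair)
        for m in ("mcc", "accuracy", "recall"):
            avg = (res.stats_vs_decoys.metric(m)
                   + res.stats_vs_assumed.metric(m)) / 2
            assert res.stats_avg.metric(m) == pytest.approx(avg)

    def test_empty_combination_rejected(self):
        hm = toy_matrix(np.random.default_rng(4))
        pair = toy_pair(hm.compound_ids, 4)
        with pytest.raises(ValueError):
            evaluate_combination(hm, [], "hit_once", pair)


class TestDominanceProperties:
    """Structural orderings that must hold on any hit matrix."""

    def test_hit_twice_subset_of_hit_once(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            hm = toy_matrix(rng, 12, 5)
            combo = list(hm.hyp_ids[:3])
            once = {c for i, c in enumerate(hm.compound_ids)
                    if classify(hm.columns(combo)[i], "hit_once") == "active"}
            twice = {c for i, c in enumerate(hm.compound_ids)
                     if classify(hm.columns(combo)[i], "hit_twice") == "active"}
            assert twice <= once

    def test_optimized_beats_random_draws(self):
        rng = np.random.default_rng(8)
        for trial in range(20):
            hm = toy_matrix(rng, 10, 5)
            pair = toy_pair(hm.compound_ids, 4)
            k = int(rng.integers(1, 5))
            opt = best_combination(hm, pair, "mcc", "hit_once", k).score()
            rb = random_benchmark(hm, pair, "mcc", "hit_once", k,
                                  optimized=opt, seed=trial)
            assert opt >= max(rb.scores) - 1e-12

    def test_recall_curve_nondecreasing_under_hit_once(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            hm = toy_matrix(rng, 10, 5)
            pair = toy_pair(hm.compound_ids, 4)
            curve, _ = optimization_curve(hm, pair, "recall", "hit_once")
            scores = [r.score() for r in curve]
            assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_adding_hypothesis_monotone_hit_once(self):
        rng = np.random.default_rng(10)
        hm = toy_matrix(rng, 15, 5)
        pair = toy_pair(hm.compound_ids, 6)
        sub = evaluate_combination(hm, list(hm.hyp_ids[:2]), "hit_once", pair)
        sup = evaluate_combination(hm, list(hm.hyp_ids[:3]), "hit_once", pair)
        assert sup.cm_vs_decoys.TP >= sub.cm_vs_decoys.TP
        assert sup.cm_vs_decoys.TN <= sub.cm_vs_decoys.TN

    def test_confusion_conservation(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            hm = toy_matrix(rng, 12, 4)
            pair = toy_pair(hm.compound_ids, 5)
            res = evaluate_combination(hm, list(hm.hyp_ids[:2]),
                                       "hit_once", pair)
            for cm, negs in ((res.cm_vs_decoys, pair.decoys),
                             (res.cm_vs_assumed, pair.assumed_inactives)):
                assert cm.TP + cm.FN == len(pair.actives)
                assert cm.TN + cm.FP == len(negs)


class TestRandomBenchmark:
    def test_identical_columns_zero_sd(self):
        hits = np.tile(np.array([[1], [0], [1], [0]], bool), (1, 4))
        hm = HitMatrix([f"c{i}" for i in range(4)],
                       [f"h{j}" for j in range(4)], hits)
        pair = TestSetPair(["c0", "c2"], ["c1"], ["c3"], "random")
        rb = random_benchmark(hm, pair, "recall", "hit_once", k=2, seed=0)
        assert rb.sd == 0.0

    def test_gain_zero_when_equal(self):
        hits = np.ones((4, 3), bool)
        hm = HitMatrix([f"c{i}" for i in range(4)],
                       [f"h{j}" for j in range(3)], hits)
        pair = TestSetPair(["c0", "c1"], ["c2"], ["c3"], "random")
        rb = random_benchmark(hm, pair, "recall", "hit_once", k=2, seed=0)
        assert rb.gain_pct == pytest.approx(0.0)


class TestUniversal:
    def test_medoid_total_distance_tiebreak(self):
        fps = {"a": Fingerprint("P3D", frozenset({1, 2})),
               "b": Fingerprint("P3D", frozenset({1, 2})),
               "c": Fingerprint("P3D", frozenset({9}))}
        # d(a,b)=0.1-like symmetric case: a and b tie; smaller id wins
        assert cluster_medoid(["a", "b", "c"], fps) == "a"

    def test_single_member_clusters_pick_member(self, small_world):
        from pharmensemble.clustering import compound_p3d
        conf = small_world.conformers()
        fps = {cid: compound_p3d(cfs) for cid, cfs in conf.items()}
        first = [c[0] for c in small_world.ground_truth_clustering().clusters]
        clus = Clustering("planted", [[f] for f in first])
        with pytest.raises(ValueError):
            universal_hypothesis(Clustering("planted", [first]), fps, conf)
        # >=2 singleton clusters: the picks are exactly the members
        hyp = universal_hypothesis(clus, fps, conf, pick="centroid", seed=0)
        # pseudo-cluster of one rep per template is geometrically
        # incompatible, so no universal hypothesis survives
        assert hyp is None

    def test_random_pick_deterministic_per_seed(self, small_world):
        from pharmensemble.clustering import compound_p3d
        conf = small_world.conformers()
        fps = {cid: compound_p3d(cfs) for cid, cfs in conf.items()}
        clus = small_world.ground_truth_clustering()
        a = universal_hypothesis(clus, fps, conf, pick="random", seed=5)
        b = universal_hypothesis(clus, fps, conf, pick="random", seed=5)
        assert (a is None) == (b is None)
        if a is not None:
            assert a.hyp_id == b.hyp_id


def test_screen_block_structure(small_world):
    hm = screen(small_world.templates, small_world.conformers())
    member = small_world.memberships
    tpl_col = {t.hyp_id: j for j, t in enumerate(small_world.templates)}
    for i, cid in enumerate(hm.compound_ids):
        row = hm.hits[i]
        if cid in member:   # active: hits exactly its own template
            expected = np.zeros(len(small_world.templates), bool)
            expected[tpl_col[member[cid]]] = True
            assert (row == expected).all()
        else:               # inactive: hits nothing
            assert not row.any()


def test_screen_requires_hypotheses(small_world):
    with pytest.raises(ValueError):
        screen([], small_world.conformers())
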