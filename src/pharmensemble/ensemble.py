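"""Screening, statistics, and the search for the best linear combination.

A set of pharmacophore hypotheses screens a compound set into a boolean
hit matrix (compounds x hypotheses).  Under the hit-once rule a
compound is predicted active when at least one hypothesis in the
combination matches it; under hit-twice, at least two.  Performance is
summarised by the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

accuracy (TP+TN)/total and recall TP/(TP+FN), each computed on the two
halves of a paired test set — actives vs true decoys and the same
actives vs assumed inactives — and averaged.  The optimizer
exhaustively enumerates all k-subsets of the hypothesis pool and
returns the subset maximising the averaged metric; benchmarks compare
it against random equal-size combinations and against a single
"universal" hypothesis built from one representative per cluster.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import config
from .clustering import Clustering, Fingerprint, soergel
from .pharmacophore import (ConformerFeatures, PharmacophoreHypothesis,
                            compound_matches, generate_hypotheses, select_best)


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------

@dataclass
class HitMatrix:
    compound_ids: list[str]
    hyp_ids: list[str]
    hits: np.ndarray          # bool, (n_compounds, n_hypotheses)

    def __post_init__(self):
        self.hits = np.asarray(self.hits, dtype=bool)
        if self.hits.shape != (len(self.compound_ids), len(self.hyp_ids)):
            raise ValueError("hit matrix shape does not match id lists")

    def columns(self, hyp_ids: Sequence[str]) -> np.ndarray:
        idx = [self.hyp_ids.index(h) for h in hyp_ids]
        return self.hits[:, idx]

    def rows(self, compound_ids: Sequence[str]) -> np.ndarray:
        idx = [self.compound_ids.index(c) for c in compound_ids]
        return self.hits[idx, :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.hits.astype(int), index=self.compound_ids,
                            columns=self.hyp_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HitMatrix":
        return cls([str(i) for i in df.index], [str(c) for c in df.columns],
                   df.to_numpy().astype(bool))


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class ScreeningStats:
    mcc: float
    accuracy: float
    recall: float

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix) -> "ScreeningStats":
        return cls(mcc(cm), accuracy(cm), recall(cm))

    @classmethod
    def average(cls, a: "ScreeningStats", b: "ScreeningStats") -> "ScreeningStats":
        return cls((a.mcc + b.mcc) / 2, (a.accuracy + b.accuracy) / 2,
                   (a.recall + b.recall) / 2)

    def metric(self, name: str) -> float:
        return getattr(self, name)


@dataclass
class CombinationResult:
    hyp_ids: tuple[str, ...]
    hit_mode: str                       # hit_once | hit_twice
    stats_vs_decoys: ScreeningStats
    stats_vs_assumed: ScreeningStats
    stats_avg: ScreeningStats
    optimized_metric: str = "mcc"
    cm_vs_decoys: ConfusionMatrix | None = None
    cm_vs_assumed: ConfusionMatrix | None = None

    def score(self) -> float:
        return self.stats_avg.metric(self.optimized_metric)


# ----------------------------------------------------------------------
# screening and statistics
# ----------------------------------------------------------------------

def screen(hypotheses: Sequence[PharmacophoreHypothesis],
           conformers: Mapping[str, Sequence[ConformerFeatures]]) -> HitMatrix:
    """Match every compound against every hypothesis."""
    if not hypotheses:
        raise ValueError("screen() needs at least one hypothesis")
    cids = list(conformers)
    hids = [h.hyp_id for h in hypotheses]
    hits = np.zeros((len(cids), len(hypotheses)), dtype=bool)
    for i, cid in enumerate(cids):
        confs = conformers[cid]
        if not confs:
            import warnings
            warnings.warn(f"compound {cid} has no conformers; all-false row")
            continue
        for j, h in enumerate(hypotheses):
            hits[i, j] = compound_matches(h, confs)
    return HitMatrix(cids, hids, hits)


def classify(hit_row: Sequence[bool], mode: str) -> str:
    """hit_once: active iff >=1 hypothesis hits; hit_twice: iff >=2."""
    need = {"hit_once": 1, "hit_twice": 2}[mode]
    return "active" if int(np.sum(hit_row)) >= need else "inactive"


def confusion(predictions: Sequence[str],
              true_labels: Sequence[str]) -> ConfusionMatrix:
    if len(predictions) != len(true_labels):
        raise ValueError("predictions and labels differ in length")
    tp = fp = tn = fn = 0
    for p, t in zip(predictions, true_labels):
        if t == "active":
            if p == "active":
                tp += 1
            else:
                fn += 1
        else:
            if p == "active":
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(TP=tp, FP=fp, TN=tn, FN=fn)


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is 0."""
    den = ((cm.TP + cm.FP) * (cm.TP + cm.FN)
           * (cm.TN + cm.FP) * (cm.TN + cm.FN))
    if den == 0:
        return 0.0
    return (cm.TP * cm.TN - cm.FP * cm.FN) / math.sqrt(den)


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("accuracy undefined on an empty confusion matrix")
    return (cm.TP + cm.TN) / cm.total


def recall(cm: ConfusionMatrix) -> float:
    if cm.TP + cm.FN == 0:
        raise ValueError("recall undefined with no actives")
    return cm.TP / (cm.TP + cm.FN)


# ----------------------------------------------------------------------
# combination evaluation and optimisation
# ----------------------------------------------------------------------

def _pair_confusions(hm: HitMatrix, combo: Sequence[str], mode: str,
                     pair) -> tuple[ConfusionMatrix, ConfusionMatrix]:
    need = {"hit_once": 1, "hit_twice": 2}[mode]
    cols = [hm.hyp_ids.index(h) for h in combo]
    sub = hm.hits[:, cols]
    counts = sub.sum(axis=1)
    row = {c: i for i, c in enumerate(hm.compound_ids)}

    def cm_for(neg_ids):
        act = [row[c] for c in pair.actives]
        neg = [row[c] for c in neg_ids]
        tp = int((counts[act] >= need).sum())
        fn = len(act) - tp
        fp = int((counts[neg] >= need).sum())
        tn = len(neg) - fp
        return ConfusionMatrix(TP=tp, FP=fp, TN=tn, FN=fn)

    return cm_for(pair.decoys), cm_for(pair.assumed_inactives)


def evaluate_combination(hm: HitMatrix, combo: Sequence[str], mode: str,
                         pair, metric: str = "mcc") -> CombinationResult:
    """Statistics of one hypothesis combination on a paired test set:
    computed separately against decoys and assumed inactives, then
    averaged elementwise."""
    if not combo:
        raise ValueError("combination must contain at least one hypothesis")
    missing = set(combo) - set(hm.hyp_ids)
    if missing:
        raise ValueError(f"unknown hypothesis ids: {sorted(missing)}")
    cm_d, cm_a = _pair_confusions(hm, combo, mode, pair)
    s_d = ScreeningStats.from_confusion(cm_d)
    s_a = ScreeningStats.from_confusion(cm_a)
    return CombinationResult(tuple(combo), mode, s_d, s_a,
                             ScreeningStats.average(s_d, s_a),
                             optimized_metric=metric,
                             cm_vs_decoys=cm_d, cm_vs_assumed=cm_a)


def best_combination(hm: HitMatrix, pair, metric: str = "mcc",
                     mode: str = "hit_once", k: int = 1,
                     budget: int = config.SUBSET_BUDGET) -> CombinationResult:
    """Exhaustive search over all k-subsets of the hypothesis pool.

    Returns the subset maximising the averaged metric; ties break to
    the lexicographically smallest sorted id tuple (guaranteed by
    enumerating sorted ids in lexicographic order with strict
    improvement).
    """
    n = len(hm.hyp_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    n_subsets = math.comb(n, k)
    if n_subsets > budget:
        raise ValueError(
            f"C({n},{k}) = {n_subsets} exceeds the enumeration budget "
            f"({budget}); use greedy_combination instead")
    best: CombinationResult | None = None
    for combo in itertools.combinations(sorted(hm.hyp_ids), k):
        res = evaluate_combination(hm, combo, mode, pair, metric)
        if best is None or res.score() > best.score():
            best = res
    return best


def greedy_combination(hm: HitMatrix, pair, metric: str = "mcc",
                       mode: str = "hit_once", k: int = 1) -> CombinationResult:
    """Non-exhaustive forward selection fallback for large pools."""
    chosen: list[str] = []
    remaining = sorted(hm.hyp_ids)
    best: CombinationResult | None = None
    for _ in range(k):
        step_best = None
        for h in remaining:
            res = evaluate_combination(hm, sorted(chosen + [h]), mode, pair, metric)
            if step_best is None or res.score() > step_best.score():
                step_best = res
                pick = h
        chosen.append(pick)
        remaining.remove(pick)
        best = step_best
    return best


def optimization_curve(hm: HitMatrix, pair, metric: str = "mcc",
                       mode: str = "hit_once",
                       k_max: int | None = None,
                       budget: int = config.SUBSET_BUDGET
                       ) -> tuple[list[CombinationResult], CombinationResult]:
    """Best combination for every length k = 1..k_max, plus the global
    argmax over the curve (ties to the smallest k)."""
    if k_max is None:
        k_max = len(hm.hyp_ids)
    if k_max > len(hm.hyp_ids):
        raise ValueError("k_max exceeds the number of hypotheses")
    curve = [best_combination(hm, pair, metric, mode, k, budget)
             for k in range(1, k_max + 1)]
    best = max(curve, key=lambda r: r.score())   # first max -> smallest k
    return curve, best


@dataclass
class RandomBenchmark:
    mean: float
    sd: float
    gain_pct: float
    optimized: float
    scores: list[float]


def gain_percent(optimized: float, random_mean: float) -> float:
    """Percent increase of the optimized statistic over the random mean."""
    return 100.0 * (optimized - random_mean) / random_mean


def random_benchmark(hm: HitMatrix, pair, metric: str = "mcc",
                     mode: str = "hit_once", k: int = 1,
                     optimized: float | None = None,
                     n_draws: int = config.RANDOM_DRAWS,
                     seed: int = 0) -> RandomBenchmark:
    """Score ``n_draws`` uniform random k-subsets and report their mean,
    sample SD, and the percent gain of the optimized score over the
    random mean."""
    rng = np.random.default_rng(seed)
    ids = sorted(hm.hyp_ids)
    scores = []
    for _ in range(n_draws):
        combo = sorted(rng.choice(ids, size=k, replace=False))
        scores.append(evaluate_combination(hm, combo, mode, pair, metric).score())
    if optimized is None:
        optimized = best_combination(hm, pair, metric, mode, k).score()
    mean = float(np.mean(scores))
    sd = float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0
    gain = gain_percent(optimized, mean) if mean != 0 else float("nan")
    return RandomBenchmark(mean, sd, gain, optimized, scores)


# ----------------------------------------------------------------------
# universal (single-hypothesis) benchmark
# ----------------------------------------------------------------------

def cluster_medoid(members: Sequence[str],
                   fps: Mapping[str, Fingerprint]) -> str:
    """Member minimising total Soergel distance to the rest; ties break
    to the smallest id."""
    best_id, best_tot = None, None
    for m in sorted(members):
        tot = sum(soergel(fps[m], fps[o]) for o in members if o != m)
        if best_tot is None or tot < best_tot:
            best_id, best_tot = m, tot
    return best_id


def universal_hypothesis(clustering: Clustering,
                         fps: Mapping[str, Fingerprint],
                         conformers: Mapping[str, Sequence[ConformerFeatures]],
                         pick: str = "centroid", seed: int = 0,
                         background: Mapping[str, Sequence[ConformerFeatures]]
                         | None = None,
                         **gen_kwargs) -> PharmacophoreHypothesis | None:
    """One hypothesis covering the whole ligand space: pick a single
    representative per cluster (fingerprint medoid or seeded random
    pick), pool the picks as one pseudo-cluster, and run hypothesis
    generation + selection on it.  May return None when no candidate
    meets the match-rate requirement."""
    if len(clustering.clusters) < 2:
        raise ValueError("universal hypothesis needs >= 2 clusters")
    rng = np.random.default_rng(seed)
    picks: list[str] = []
    for members in clustering.clusters:
        if len(members) == 1:
            picks.append(members[0])
        elif pick == "centroid":
            picks.append(cluster_medoid(members, fps))
        elif pick == "random":
            picks.append(str(rng.choice(sorted(members))))
        else:
            raise ValueError(f"unknown pick mode {pick!r}")
    reps = {p: conformers[p] for p in picks}
    cands = generate_hypotheses(reps, background=background,
                                source_cluster="universal", seed=seed,
                                **gen_kwargs)
    return select_best(cands)
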