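"""Diversity-based selection and assembly of paired test sets.

Sphere exclusion over a distance function (typically Soergel distance on
fingerprints) yields diverse subsets: a seed compound is picked at
random, everything within the exclusion radius is discarded, and the
loop repeats on the surviving pool.  The same primitive serves three
jobs: picking per-cluster representatives for model building, picking
"most diverse" compound sets of a requested size (radius found by
bisection), and assembling the three paired test-set schemes (random /
most diverse / cluster-population-proportional actives, each paired
with the most diverse true decoys and assumed inactives).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import config
from .clustering import Clustering

DistanceFn = Callable[[str, str], float]


@dataclass
class SphereSelection:
    """Result of a sphere-exclusion run; ``padded`` lists items added by
    max-min fill after the pool was exhausted (they may violate the
    radius separation guarantee)."""
    ids: list[str]
    padded: list[str] = field(default_factory=list)
    radius: float = config.SPHERE_RADIUS

    def __iter__(self):
        return iter(self.ids)

    def __len__(self):
        return len(self.ids)


def sphere_exclusion(items: Sequence[str], distance_fn: DistanceFn,
                     radius: float = config.SPHERE_RADIUS,
                     n_target: int | None = None,
                     seed: int = 0,
                     first_seed: str | None = None) -> SphereSelection:
    """Sphere-exclusion diversity selection.

    Repeatedly picks a seed uniformly at random from the unexcluded
    pool, keeps it, and excludes every item within ``radius`` of it.
    Stops when the pool is empty or ``n_target`` is reached; if the
    target is still unmet the selection is padded with excluded items
    farthest from the current selection (max-min distance), flagged in
    the result.  ``first_seed`` forces the initial pick (used in tests
    and to make selections reproducible beyond the RNG seed).
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    pool = [str(i) for i in items]
    if not pool:
        warnings.warn("sphere_exclusion called with an empty pool")
        return SphereSelection([], radius=radius)
    rng = np.random.default_rng(seed)
    excluded: list[str] = []
    selected: list[str] = []
    while pool and (n_target is None or len(selected) < n_target):
        if first_seed is not None and not selected:
            if first_seed not in pool:
                raise ValueError(f"first_seed {first_seed!r} not in pool")
            pick = first_seed
        else:
            pick = pool[int(rng.integers(len(pool)))]
        selected.append(pick)
        keep, drop = [], []
        for x in pool:
            (drop if distance_fn(pick, x) <= radius else keep).append(x)
        excluded.extend(d for d in drop if d != pick)
        pool = keep
    padded: list[str] = []
    if n_target is not None and len(selected) < n_target:
        candidates = list(excluded)
        while candidates and len(selected) < n_target:
            best = max(candidates,
                       key=lambda c: min(distance_fn(c, s) for s in selected))
            selected.append(best)
            padded.append(best)
            candidates.remove(best)
    return SphereSelection(selected, padded=padded, radius=radius)


def most_diverse(items: Sequence[str], distance_fn: DistanceFn, n: int,
                 seed: int = 0, iters: int = 40) -> SphereSelection:
    """The n most diverse items: exclusion radius grown/shrunk by bisection
    until the unconstrained selection size reaches n, then capped at n
    (padding by max-min fill if the pool thins out faster than n)."""
    items = [str(i) for i in items]
    if n >= len(items):
        if n > len(items):
            raise ValueError(f"requested {n} items from a pool of {len(items)}")
        return SphereSelection(list(items), radius=0.0)
    lo, hi = 0.0, 1.0
    # ensure hi exceeds the max pairwise distance actually present
    hi = max(hi, max((distance_fn(a, b) for i, a in enumerate(items)
                      for b in items[i + 1:]), default=1.0) + 1e-9)
    radius = hi
    for _ in range(iters):
        mid = (lo + hi) / 2
        size = len(sphere_exclusion(items, distance_fn, radius=mid, seed=seed))
        if size > n:
            lo = mid
        elif size < n:
            hi = mid
        else:
            radius = mid
            break
    else:
        radius = hi
    return sphere_exclusion(items, distance_fn, radius=radius,
                            n_target=n, seed=seed)


def _quota(n: int, reps_per_50: float, min_reps: int) -> int:
    return max(min_reps, math.floor(n * reps_per_50 / 50.0 + 0.5))


def representatives(clustering: Clustering, distance_fn: DistanceFn,
                    reps_per_50: float = config.REPS_PER_50,
                    min_reps: int = config.MIN_REPS,
                    radius: float = config.SPHERE_RADIUS,
                    seed: int = 0) -> dict[int, list[str]]:
    """Per-cluster representative ids, in number proportional to cluster size.

    A cluster of n members gets max(min_reps, round(n * reps_per_50 / 50))
    representatives via sphere exclusion within the cluster (the whole
    cluster if smaller than its quota).  The default rate puts 10
    representatives on a 533-member cluster.
    """
    out: dict[int, list[str]] = {}
    for ci, members in enumerate(clustering.clusters):
        q = _quota(len(members), reps_per_50, min_reps)
        if q >= len(members):
            out[ci] = list(members)
            continue
        sel = sphere_exclusion(members, distance_fn, radius=radius,
                               n_target=q, seed=seed + ci)
        out[ci] = sel.ids
    return out


def largest_remainder(sizes: Sequence[int], total: int) -> list[int]:
    """Proportional integer quotas summing exactly to ``total``."""
    sizes = np.asarray(sizes, dtype=float)
    if sizes.sum() <= 0:
        raise ValueError("sizes must sum to a positive value")
    exact = total * sizes / sizes.sum()
    base = np.floor(exact).astype(int)
    rem = total - int(base.sum())
    order = np.argsort(-(exact - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base.tolist()


@dataclass
class TestSetPair:
    """One paired test set: the same actives screened against true decoys
    and against assumed inactives."""
    __test__ = False   # looks like a test class to pytest; it is not

    actives: list[str]
    decoys: list[str]
    assumed_inactives: list[str]
    scheme: str   # random | diverse | populated

    def __post_init__(self):
        roles = [set(self.actives), set(self.decoys), set(self.assumed_inactives)]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = roles[i] & roles[j]
                if overlap:
                    raise ValueError(f"ids appear in two roles: {sorted(overlap)[:5]}")

    def to_dict(self) -> dict:
        return {"scheme": self.scheme, "actives": self.actives,
                "decoys": self.decoys,
                "assumed_inactives": self.assumed_inactives}


def build_test_sets(actives_pool: Sequence[str], decoys_pool: Sequence[str],
                    assumed_pool: Sequence[str], clustering: Clustering,
                    distance_fn: DistanceFn,
                    n_per_role: int = config.N_PER_ROLE,
                    seed: int = 0) -> dict[str, TestSetPair]:
    """Assemble the three paired test-set schemes.

    Actives are drawn (i) uniformly at random, (ii) as the most diverse
    subset, and (iii) per-cluster in proportion to cluster populations
    (largest-remainder rounding).  Each scheme is paired with the
    ``n_per_role`` most diverse true decoys and most diverse assumed
    inactives, shared across schemes.
    """
    actives_pool = [str(i) for i in actives_pool]
    for name, pool in (("actives", actives_pool), ("decoys", decoys_pool),
                       ("assumed", assumed_pool)):
        if len(pool) < n_per_role:
            raise ValueError(f"{name} pool has {len(pool)} compounds; "
                             f"{n_per_role} required (deficit "
                             f"{n_per_role - len(pool)})")
    rng = np.random.default_rng(seed)
    decoys = most_diverse(decoys_pool, distance_fn, n_per_role, seed=seed).ids
    assumed = most_diverse(assumed_pool, distance_fn, n_per_role, seed=seed).ids

    out: dict[str, TestSetPair] = {}
    # (i) random
    rand = list(rng.choice(actives_pool, size=n_per_role, replace=False))
    out["random"] = TestSetPair([str(x) for x in rand], decoys, assumed, "random")
    # (ii) most diverse
    div = most_diverse(actives_pool, distance_fn, n_per_role, seed=seed).ids
    out["diverse"] = TestSetPair(div, decoys, assumed, "diverse")
    # (iii) populated: proportional to cluster sizes within the pool
    pool_set = set(actives_pool)
    groups = [[i for i in c if i in pool_set] for c in clustering.clusters]
    if clustering.special_class:
        extra = [i for i in clustering.special_class if i in pool_set]
        if extra:
            groups.append(extra)
    groups = [g for g in groups if g]
    if not groups:
        raise ValueError("no clustered compounds in the actives pool")
    quotas = largest_remainder([len(g) for g in groups], n_per_role)
    pop: list[str] = []
    for g, q in zip(groups, quotas):
        if q > len(g):   # reallocate impossible surplus at random from the rest
            q = len(g)
        pop.extend(str(x) for x in rng.choice(g, size=q, replace=False))
    if len(pop) < n_per_role:
        rest = [i for i in actives_pool if i not in set(pop)]
        fill = rng.choice(rest, size=n_per_role - len(pop), replace=False)
        pop.extend(str(x) for x in fill)
    out["populated"] = TestSetPair(pop, decoys, assumed, "populated")
    return out
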