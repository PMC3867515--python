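"""Synthetic labelled fixtures with planted pharmacophore structure.

A planted world contains a handful of template pharmacophores
(4-6 typed feature points each), "active" compounds generated by
jittering a template's points (Gaussian noise per coordinate, default
sigma 0.2 Å) plus a few spurious extra features, and "inactive"
compounds that match no template (random feature clouds or
geometry-distorted template copies, both verified at generation time
with the actual match operation).  Compounds are feature-point clouds
rather than real molecules: this isolates the clustering, hypothesis
generation and combination optimisation machinery from conformer
generation variance, while exercising the exact same code paths the
molecular pipeline uses.

Every world is verified before it is returned: each active matches its
own template (and only its own, so the hit matrix against the planted
templates is block-structured) and no inactive matches any template.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import config
from .clustering import Clustering
from .pharmacophore import (ConformerFeatures, FeaturePoint,
                            PharmacophoreHypothesis, compound_matches)

FEATURE_TYPES = ("A", "D", "H", "P", "R")

BOX = 12.0            # Å, template feature points live in [0, BOX]^3
MIN_SEP = 2.5         # Å, minimum separation between template features
SPURIOUS_TYPE = "H"            # spurious decoration feature type
SPURIOUS_SHELL = (20.0, 60.0)  # Å from core centre, beyond fingerprint range
N_CONFORMERS = 10     # jittered conformers per active
INACTIVE_SCALE = (1.6, 2.2)   # distance-distortion range for hard inactives


@dataclass
class PlantedWorld:
    templates: list[PharmacophoreHypothesis]
    actives: dict[str, list[ConformerFeatures]]
    inactives: dict[str, list[ConformerFeatures]]
    memberships: dict[str, str]          # active id -> template id
    seed: int
    noise_sigma: float

    def conformers(self) -> dict[str, list[ConformerFeatures]]:
        out = dict(self.actives)
        out.update(self.inactives)
        return out

    def ground_truth_clustering(self) -> Clustering:
        groups: dict[str, list[str]] = {t.hyp_id: [] for t in self.templates}
        for cid, tid in self.memberships.items():
            groups[tid].append(cid)
        return Clustering(method="planted",
                          clusters=[sorted(groups[t.hyp_id])
                                    for t in self.templates])


def _center_bins(pts: np.ndarray, iters: int = 200, relax: float = 0.3,
                 min_sep: float = MIN_SEP) -> np.ndarray:
    """Relax feature points so pairwise distances sit at distance-bin
    centres (half-integers for 1 Å bins), keeping them below the
    fingerprint's clamping range.  Bin-centred template geometry makes
    the planted cluster structure resolvable by the binned triplet
    fingerprint despite coordinate jitter."""
    pts = pts.copy()
    k = len(pts)
    top = config.P3D_MAX_DIST - config.P3D_BIN_WIDTH / 2
    for _ in range(iters):
        for i in range(k):
            for j in range(i + 1, k):
                v = pts[j] - pts[i]
                d = float(np.linalg.norm(v))
                t = np.floor(d / config.P3D_BIN_WIDTH) * config.P3D_BIN_WIDTH \
                    + config.P3D_BIN_WIDTH / 2
                t = min(max(t, min_sep), top)
                corr = (t - d) / 2 * relax * v / d
                pts[i] -= corr
                pts[j] += corr
    return pts


def _sample_template(rng: np.random.Generator, tid: str,
                     n_features_range: tuple[int, int],
                     tolerance: float) -> PharmacophoreHypothesis:
    k = int(rng.integers(n_features_range[0], n_features_range[1] + 1))
    types = [FEATURE_TYPES[i] for i in rng.integers(0, len(FEATURE_TYPES), k)]
    pts: list[np.ndarray] = []
    while len(pts) < k:
        p = rng.uniform(0, BOX, 3)
        if all(np.linalg.norm(p - q) >= MIN_SEP for q in pts):
            pts.append(p)
    return PharmacophoreHypothesis(hyp_id=tid, feature_types=types,
                                   ref_coords=_center_bins(np.array(pts)),
                                   tolerance_rmsd=tolerance,
                                   source_cluster=tid)


def _jittered_active(rng: np.random.Generator, tpl: PharmacophoreHypothesis,
                     cid: str, sigma: float,
                     n_conformers: int) -> list[ConformerFeatures]:
    """Conformer ensemble of one active.

    Each conformer is an independent jitter of the template's points
    (per-coordinate Gaussian noise).  On top of the pharmacophore core
    every active carries one spurious hydrophobic decoration — a
    feature point far outside the core at a compound-specific position
    (random direction, radius drawn once per compound), jittered like
    the core across conformers.  It stands in for peripheral structure
    unrelated to binding: it contributes only clamped top-bin triplet
    keys to the fingerprint and offers the hypothesis search a decoy
    point whose position is consistent within a compound but not
    between compounds.
    """
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    radius = rng.uniform(*SPURIOUS_SHELL)
    arm = np.full(3, BOX / 2) + radius * direction
    confs = []
    for c in range(n_conformers):
        coords = tpl.ref_coords + rng.normal(0.0, sigma, tpl.ref_coords.shape)
        points = [FeaturePoint(t, tuple(xyz))
                  for t, xyz in zip(tpl.feature_types, coords)]
        points.append(FeaturePoint(
            SPURIOUS_TYPE, tuple(arm + rng.normal(0.0, sigma, 3))))
        confs.append(ConformerFeatures(cid, c, points))
    return confs


def _random_inactive(rng: np.random.Generator,
                     templates: list[PharmacophoreHypothesis],
                     cid: str) -> ConformerFeatures:
    if rng.random() < 0.5 or not templates:
        # random feature cloud
        k = int(rng.integers(3, 7))
        points = [FeaturePoint(FEATURE_TYPES[int(rng.integers(5))],
                               tuple(rng.uniform(0, BOX, 3)))
                  for _ in range(k)]
    else:
        # distance-distorted copy of a template (same types, wrong geometry)
        tpl = templates[int(rng.integers(len(templates)))]
        scale = rng.uniform(*INACTIVE_SCALE)
        centre = tpl.ref_coords.mean(axis=0)
        coords = centre + scale * (tpl.ref_coords - centre)
        points = [FeaturePoint(t, tuple(xyz))
                  for t, xyz in zip(tpl.feature_types, coords)]
    return ConformerFeatures(cid, 0, points)


def generate_world(n_templates: int = 3, actives_per_template: int = 10,
                   n_inactives: int = 30, noise_sigma: float = 0.2,
                   seed: int = 0,
                   n_features_range: tuple[int, int] = (5, 6),
                   n_conformers: int = N_CONFORMERS,
                   tolerance: float = config.MATCH_RMSD_TOL,
                   max_retries: int = 50) -> PlantedWorld:
    """Generate and verify a planted world; deterministic for a fixed seed.

    Verification is done with the real match operation.  If a sampled
    configuration fails (e.g. two templates land close enough that an
    active cross-matches), the whole world is resampled from a derived
    sub-seed, up to ``max_retries`` times.
    """
    if min(n_templates, actives_per_template, n_inactives) <= 0:
        raise ValueError("world dimensions must be positive")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    for attempt in range(max_retries):
        rng = np.random.default_rng((seed, attempt))
        templates = [_sample_template(rng, f"tpl{t}", n_features_range, tolerance)
                     for t in range(n_templates)]
        actives: dict[str, list[ConformerFeatures]] = {}
        memberships: dict[str, str] = {}
        ok = True
        for t, tpl in enumerate(templates):
            for j in range(actives_per_template):
                cid = f"act-t{t}-{j:03d}"
                confs = _jittered_active(rng, tpl, cid, noise_sigma,
                                         n_conformers)
                hit = [compound_matches(other, confs) for other in templates]
                if not (hit[t] and sum(hit) == 1):
                    ok = False
                    break
                actives[cid] = confs
                memberships[cid] = tpl.hyp_id
            if not ok:
                break
        if not ok:
            continue
        inactives: dict[str, list[ConformerFeatures]] = {}
        for j in range(n_inactives):
            cid = f"inact-{j:03d}"
            for _ in range(200):   # inactives can be resampled locally
                cf = _random_inactive(rng, templates, cid)
                if not any(compound_matches(tpl, [cf]) for tpl in templates):
                    inactives[cid] = [cf]
                    break
            else:
                ok = False
                break
        if ok:
            return PlantedWorld(templates, actives, inactives, memberships,
                                seed=seed, noise_sigma=noise_sigma)
    raise RuntimeError(
        f"could not generate a verified world after {max_retries} attempts "
        f"(n_templates={n_templates}, sigma={noise_sigma}, seed={seed})")


# ----------------------------------------------------------------------
# end-to-end recovery pipeline
# ----------------------------------------------------------------------

@dataclass
class RecoveryResult:
    """Outcome of running the full screening pipeline on a planted world."""
    n_templates: int
    n_clusters: int                  # clusters found (Kelley level)
    hypotheses: list[PharmacophoreHypothesis]
    combination_ids: tuple[str, ...]
    recall: float                    # averaged recall of the K-length combination
    mcc: float
    templates_recovered: int         # planted templates matched one-to-one

    @property
    def clustering_recovered(self) -> bool:
        return self.n_clusters == self.n_templates


def hypothesis_matches_template(h: PharmacophoreHypothesis,
                                tpl: PharmacophoreHypothesis) -> bool:
    """Same feature-type multiset and compatible geometry (the hypothesis
    matches the template's reference points within its RMSD tolerance)."""
    if sorted(h.feature_types) != sorted(tpl.feature_types):
        return False
    ref = ConformerFeatures(tpl.hyp_id, 0,
                            [FeaturePoint(t, tuple(x)) for t, x in
                             zip(tpl.feature_types, tpl.ref_coords)])
    return compound_matches(h, [ref])


def planted_recovery(world: PlantedWorld, seed: int = 0) -> RecoveryResult:
    """Run the full pipeline on a planted world and score the recovery.

    Clusters the actives on consensus P3D fingerprints (Kelley cut, no
    size-capped resplitting — planted worlds are balanced by design),
    selects sphere-exclusion representatives, builds one hypothesis per
    cluster, screens everything, and optimizes the K-length combination
    for averaged recall under hit-once, splitting the inactives into a
    decoy half and an assumed-inactive half.
    """
    from .clustering import cluster_compounds, compound_p3d, soergel
    from .ensemble import best_combination, screen
    from .pharmacophore import generate_hypotheses, select_best
    from .selection import TestSetPair, representatives

    K = len(world.templates)
    ids = sorted(world.actives)
    fps = {i: compound_p3d(world.actives[i]) for i in ids}
    clus = cluster_compounds(ids, [fps[i] for i in ids], method="P3D",
                             max_size_fraction=None)
    reps = representatives(clus, lambda a, b: soergel(fps[a], fps[b]),
                           seed=seed)
    hyps = []
    for ci, members in reps.items():
        cands = generate_hypotheses(
            {m: world.actives[m] for m in members},
            background=dict(world.inactives),
            source_cluster=f"cluster{ci}", seed=seed)
        best = select_best(cands)
        if best is not None:
            hyps.append(best)
    hm = screen(hyps, world.conformers())
    inactive_ids = sorted(world.inactives)
    half = len(inactive_ids) // 2
    pair = TestSetPair(ids, inactive_ids[:half], inactive_ids[half:], "random")
    result = best_combination(hm, pair, metric="recall", mode="hit_once",
                              k=min(K, len(hyps)))
    chosen = [h for h in hyps if h.hyp_id in result.hyp_ids]
    recovered = 0
    for tpl in world.templates:
        if any(hypothesis_matches_template(h, tpl) for h in chosen):
            recovered += 1
    return RecoveryResult(n_templates=K, n_clusters=len(clus.clusters),
                          hypotheses=hyps, combination_ids=result.hyp_ids,
                          recall=result.stats_avg.recall,
                          mcc=result.stats_avg.mcc,
                          templates_recovered=recovered)


# ----------------------------------------------------------------------
# serialisation to pipeline input formats
# ----------------------------------------------------------------------

def world_to_inputs(world: PlantedWorld,
                    out_dir: str | Path | None = None
                    ) -> tuple[pd.DataFrame, dict, Clustering]:
    """Serialise a world into the formats the pipeline consumes.

    Returns (activity table, conformer features, ground-truth
    clustering).  The activity table is a raw-style record list
    (compound_id, measure=Ki, value in nM, units) with pseudo-Ki drawn
    log-uniformly inside each label's range (actives <= 100 nM,
    inactives > 1000 nM), so the curation module reproduces the planted
    labels exactly.  With ``out_dir`` set, writes activities.csv,
    features.json and clustering.json.
    """
    rng = np.random.default_rng((world.seed, 987654321))
    rows = []
    for cid in sorted(world.actives):
        ki = 10.0 ** rng.uniform(0.0, 2.0)          # 1..100 nM
        rows.append({"compound_id": cid, "measure": "Ki", "value": ki,
                     "units": "nM", "species": "human", "preparation": "cloned"})
    for cid in sorted(world.inactives):
        ki = 10.0 ** rng.uniform(3.001, 5.0)        # >1000 nM
        rows.append({"compound_id": cid, "measure": "Ki", "value": ki,
                     "units": "nM", "species": "human", "preparation": "cloned"})
    activities = pd.DataFrame(rows)
    conformers = world.conformers()
    clustering = world.ground_truth_clustering()
    if out_dir is not None:
        from . import io as pio
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        activities.to_csv(out / "activities.csv", index=False)
        pio.write_features(conformers, out / "features.json")
        pio.write_clustering(clustering, out / "clustering.json")
        pio.write_hypotheses(world.templates, out / "templates.json")
    return activities, conformers, clustering
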