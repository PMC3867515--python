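"""Pharmacophore features, hypothesis matching, and per-cluster model building.

A pharmacophore hypothesis is an abstract arrangement of typed
interaction features — hydrogen-bond acceptor (A), donor (D),
hydrophobic group (H), positively charged group (P) and aromatic ring
(R) — stored as reference 3D coordinates plus the derived inter-feature
distance matrix.  A conformer matches a hypothesis when some
type-consistent injective assignment of hypothesis features to the
conformer's perceived feature points superposes (least-squares,
Kabsch) with RMSD at or below the tolerance (default 2 Å); a compound
matches when any of its conformers does.

Hypothesis generation enumerates feature k-tuples (k = 4..7, largest
first) from each cluster representative's conformers, keeps candidates
mapping at least half of the representatives, scores selectivity as
1 − (fraction of a background set matched), and selects the best
candidate lexicographically: most features, then highest matching rate,
then best selectivity.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import config

FEATURE_TYPES = ("A", "D", "H", "P", "R")


@dataclass(frozen=True)
class FeaturePoint:
    ftype: str
    xyz: tuple[float, float, float]

    def __post_init__(self):
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if not all(math.isfinite(c) for c in self.xyz):
            raise ValueError("feature coordinates must be finite")


@dataclass
class ConformerFeatures:
    compound_id: str
    conformer_index: int
    points: list[FeaturePoint]

    def coords(self) -> np.ndarray:
        return np.array([p.xyz for p in self.points], dtype=float)

    def types(self) -> list[str]:
        return [p.ftype for p in self.points]


@dataclass
class PharmacophoreHypothesis:
    hyp_id: str
    feature_types: list[str]          # length 4..7
    ref_coords: np.ndarray            # (k, 3) reference geometry, Angstrom
    tolerance_rmsd: float = config.MATCH_RMSD_TOL
    source_cluster: str = ""
    match_rate: float = float("nan")
    selectivity: float = float("nan")
    dist: np.ndarray = field(default=None)  # derived from ref_coords

    def __post_init__(self):
        self.ref_coords = np.asarray(self.ref_coords, dtype=float)
        k = len(self.feature_types)
        if not 4 <= k <= 7:
            raise ValueError(f"hypothesis needs 4-7 features, got {k}")
        if self.ref_coords.shape != (k, 3):
            raise ValueError("ref_coords shape must be (n_features, 3)")
        if any(t not in FEATURE_TYPES for t in self.feature_types):
            raise ValueError(f"unknown feature type in {self.feature_types}")
        if self.dist is None:
            diff = self.ref_coords[:, None, :] - self.ref_coords[None, :, :]
            self.dist = np.linalg.norm(diff, axis=-1)
        else:
            self.dist = np.asarray(self.dist, dtype=float)

    def to_dict(self) -> dict:
        return {"hyp_id": self.hyp_id, "feature_types": list(self.feature_types),
                "ref_coords": self.ref_coords.tolist(),
                "dist": self.dist.tolist(),
                "tolerance_rmsd": self.tolerance_rmsd,
                "source_cluster": self.source_cluster,
                "match_rate": self.match_rate, "selectivity": self.selectivity,
                "selectivity_definition": "1 - background match fraction"}

    @classmethod
    def from_dict(cls, d: dict) -> "PharmacophoreHypothesis":
        return cls(hyp_id=d["hyp_id"], feature_types=list(d["feature_types"]),
                   ref_coords=np.array(d["ref_coords"], dtype=float),
                   tolerance_rmsd=float(d.get("tolerance_rmsd",
                                              config.MATCH_RMSD_TOL)),
                   source_cluster=d.get("source_cluster", ""),
                   match_rate=float(d.get("match_rate", "nan")),
                   selectivity=float(d.get("selectivity", "nan")),
                   dist=np.array(d["dist"], dtype=float) if "dist" in d else None)


# ----------------------------------------------------------------------
# feature perception
# ----------------------------------------------------------------------

def perceive_features(mol, conformer_index: int = 0) -> ConformerFeatures:
    """Perceive A/D/H/P/R feature points on an RDKit conformer.

    Acceptors, donors and charged-nitrogen centres come from the SMARTS
    patterns in config; hydrophobic atoms are grouped into connected
    components whose centroids become H points; aromatic rings
    contribute R points at their centroids.
    """
    from rdkit import Chem
    if mol is None:
        raise ValueError("cannot perceive features on a null molecule")
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no 3D conformers")
    conf = mol.GetConformer(conformer_index)
    pos = conf.GetPositions()
    cid = mol.GetProp("_Name") if mol.HasProp("_Name") else "?"

    points: list[FeaturePoint] = []
    for ftype in ("A", "D", "P"):
        patt = Chem.MolFromSmarts(config.FEATURE_SMARTS[ftype])
        seen = set()
        for matchatoms in mol.GetSubstructMatches(patt):
            a = matchatoms[0]
            if a in seen:
                continue
            seen.add(a)
            points.append(FeaturePoint(ftype, tuple(pos[a])))

    # hydrophobic: matched atoms -> connected components -> centroids
    patt = Chem.MolFromSmarts(config.FEATURE_SMARTS["H"])
    hydro = {m[0] for m in mol.GetSubstructMatches(patt)}
    unvisited = set(hydro)
    while unvisited:
        stack = [unvisited.pop()]
        comp = set(stack)
        while stack:
            a = stack.pop()
            for nb in mol.GetAtomWithIdx(a).GetNeighbors():
                i = nb.GetIdx()
                if i in unvisited:
                    unvisited.remove(i)
                    comp.add(i)
                    stack.append(i)
        centroid = pos[sorted(comp)].mean(axis=0)
        points.append(FeaturePoint("H", tuple(centroid)))

    # aromatic rings -> centroids
    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(a).GetIsAromatic() for a in ring):
            centroid = pos[list(ring)].mean(axis=0)
            points.append(FeaturePoint("R", tuple(centroid)))

    if not points:
        warnings.warn(f"no pharmacophore features perceived for {cid}")
    return ConformerFeatures(str(cid), conformer_index, points)


def generate_conformers(mol, seed: int = 0,
                        per_rotatable: int = config.CONF_PER_ROTATABLE,
                        max_conf: int = config.CONF_MAX,
                        energy_window: float = config.CONF_ENERGY_WINDOW):
    """Embed a conformer ensemble honouring the generation contract:
    up to ``per_rotatable`` conformers per rotatable bond, at most
    ``max_conf`` total, within ``energy_window`` kcal/mol of the minimum
    (MMFF94 energies).  Returns the molecule with conformers attached."""
    from rdkit import Chem
    from rdkit.Chem import AllChem
    from rdkit.Chem.Descriptors import NumRotatableBonds
    mol = Chem.AddHs(mol)
    n = min(max_conf, max(1, per_rotatable * max(1, int(NumRotatableBonds(mol)))))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    AllChem.EmbedMultipleConfs(mol, numConfs=n, params=params)
    energies = []
    props = AllChem.MMFFGetMoleculeProperties(mol)
    for c in mol.GetConformers():
        if props is None:
            energies.append(0.0)
            continue
        ff = AllChem.MMFFGetMoleculeForceField(mol, props, confId=c.GetId())
        energies.append(ff.CalcEnergy() if ff is not None else 0.0)
    if energies:
        emin = min(energies)
        for c, e in zip(list(mol.GetConformers()), energies):
            if e - emin > energy_window:
                mol.RemoveConformer(c.GetId())
    return Chem.RemoveHs(mol)


# ----------------------------------------------------------------------
# matching
# ----------------------------------------------------------------------

def kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimum RMSD between paired point sets after optimal rigid-body
    superposition (rotation allowed, no reflection)."""
    P = np.asarray(P, float) - np.mean(P, axis=0)
    Q = np.asarray(Q, float) - np.mean(Q, axis=0)
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    trace = S[0] + S[1] + d * S[2]
    msd = ((P ** 2).sum() + (Q ** 2).sum() - 2.0 * trace) / len(P)
    return math.sqrt(max(msd, 0.0))


def match(h: PharmacophoreHypothesis,
          cf: ConformerFeatures) -> tuple[bool, float | None]:
    """Does a conformer's feature set satisfy a hypothesis?

    Searches type-consistent injective assignments of hypothesis
    features to conformer points, pruning any partial assignment whose
    pairwise distances deviate from the hypothesis geometry by more
    than twice the RMSD tolerance, and superposing survivors by Kabsch.
    Returns (matched, best RMSD over surviving assignments) — RMSD is
    None when no assignment survives pruning.
    """
    k = len(h.feature_types)
    pts = cf.coords()
    types = cf.types()
    cand = [[i for i, t in enumerate(types) if t == ft]
            for ft in h.feature_types]
    if any(not c for c in cand):
        return False, None
    # visit scarce features first to prune early
    order = sorted(range(k), key=lambda i: len(cand[i]))
    prune = 2.0 * h.tolerance_rmsd
    best = [None]

    def backtrack(pos: int, assigned: dict[int, int]):
        if pos == k:
            hyp_idx = list(assigned.keys())
            pt_idx = [assigned[i] for i in hyp_idx]
            rmsd = kabsch_rmsd(h.ref_coords[hyp_idx], pts[pt_idx])
            if best[0] is None or rmsd < best[0]:
                best[0] = rmsd
            return
        i = order[pos]
        for p in cand[i]:
            if p in assigned.values():
                continue
            ok = True
            for j, q in assigned.items():
                d_pts = float(np.linalg.norm(pts[p] - pts[q]))
                if abs(h.dist[i, j] - d_pts) > prune:
                    ok = False
                    break
            if ok:
                assigned[i] = p
                backtrack(pos + 1, assigned)
                del assigned[i]

    backtrack(0, {})
    if best[0] is None:
        return False, None
    return best[0] <= h.tolerance_rmsd, best[0]


def compound_matches(h: PharmacophoreHypothesis,
                     conformers: Sequence[ConformerFeatures]) -> bool:
    """A compound matches if any of its conformers matches."""
    return any(match(h, cf)[0] for cf in conformers)


# ----------------------------------------------------------------------
# hypothesis generation and selection
# ----------------------------------------------------------------------

def _enumerate_candidates(cf: ConformerFeatures, k_range: tuple[int, int],
                          cap: int, rng: np.random.Generator,
                          max_span: float = config.HYP_MAX_SPAN):
    """Feature k-tuples of one conformer, largest k first, capped with
    seeded uniform subsampling when the enumeration exceeds the cap.

    Tuples spanning more than ``max_span`` between any two features are
    discarded: a pharmacophore describes a binding-site arrangement, so
    features separated by more than a binding site's extent cannot
    belong to one hypothesis.
    """
    pts = cf.coords()
    n = len(cf.points)
    near = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1) <= max_span
    combos: list[tuple[int, ...]] = []
    for k in range(min(k_range[1], n), k_range[0] - 1, -1):
        for combo in itertools.combinations(range(n), k):
            if all(near[a, b] for a, b in itertools.combinations(combo, 2)):
                combos.append(combo)
        if len(combos) > 4 * cap:
            break
    if len(combos) > cap:
        idx = rng.choice(len(combos), size=cap, replace=False)
        combos = [combos[i] for i in sorted(idx)]
    return combos


def generate_hypotheses(reps: Mapping[str, Sequence[ConformerFeatures]],
                        background: Mapping[str, Sequence[ConformerFeatures]]
                        | None = None,
                        k_range: tuple[int, int] = config.K_RANGE,
                        tolerance_rmsd: float = config.MATCH_RMSD_TOL,
                        match_rate_min: float = config.MATCH_RATE_MIN,
                        cap: int = config.CANDIDATE_CAP,
                        source_cluster: str = "",
                        seed: int = 0) -> list[PharmacophoreHypothesis]:
    """Candidate hypotheses for one cluster from its representatives.

    ``reps`` maps representative compound ids to their conformer feature
    sets.  Candidates whose match rate over the representatives falls
    below ``match_rate_min`` are dropped; survivors get a selectivity of
    1 − (fraction of ``background`` compounds matched).  May return an
    empty list: some clusters yield no hypothesis meeting the
    requirements.
    """
    if len(reps) < 2:
        raise ValueError("hypothesis generation needs >= 2 representatives")
    rng = np.random.default_rng(seed)
    rep_ids = sorted(reps)
    out: list[PharmacophoreHypothesis] = []
    serial = 0
    for rid in rep_ids:
        for cf in reps[rid]:
            for combo in _enumerate_candidates(cf, k_range, cap, rng):
                types = [cf.points[i].ftype for i in combo]
                coords = cf.coords()[list(combo)]
                hyp = PharmacophoreHypothesis(
                    hyp_id=f"{source_cluster}/{rid}/c{cf.conformer_index}"
                           f"/n{len(combo)}/{serial}",
                    feature_types=types, ref_coords=coords,
                    tolerance_rmsd=tolerance_rmsd,
                    source_cluster=source_cluster)
                serial += 1
                hits = sum(compound_matches(hyp, reps[r]) for r in rep_ids)
                rate = hits / len(rep_ids)
                if rate < match_rate_min:
                    continue
                hyp.match_rate = rate
                if background:
                    bg_hits = sum(compound_matches(hyp, confs)
                                  for confs in background.values())
                    hyp.selectivity = 1.0 - bg_hits / len(background)
                else:
                    hyp.selectivity = 1.0
                out.append(hyp)
    return out


def select_best(candidates: Sequence[PharmacophoreHypothesis]
                ) -> PharmacophoreHypothesis | None:
    """Best hypothesis by the lexicographic rule: most features, then
    highest match rate, then highest selectivity, then smallest id."""
    if not candidates:
        return None
    return min(candidates,
               key=lambda h: (-len(h.feature_types), -h.match_rate,
                              -h.selectivity, h.hyp_id))
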