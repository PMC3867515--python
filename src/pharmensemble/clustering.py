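"""Fingerprints and hierarchical clustering of active compounds.

Two fingerprint kinds drive the automatic clustering:

* M2D — a MOLPRINT-2D-style atom-environment fingerprint.  Every heavy
  atom contributes one hashed key encoding the multiset of
  (topological distance, atom type) pairs within bond radius 2, with
  atom type = (element, aromatic flag, heavy-atom degree).
* P3D — a 3D pharmacophore-triplet fingerprint over typed feature
  points: every feature triplet is keyed by its sorted type triple and
  sorted 1 Å distance bins on [0, 15] Å (larger distances clamp to the
  top bin).

Compounds are compared with the Soergel distance (1 − Tanimoto on the
binary key sets), clustered agglomeratively, and the cut level is chosen
by the Kelley penalty, which balances average within-cluster spread
against the number of clusters.  Post-processing pools clusters below a
minimum size into a special class and recursively re-splits oversized
clusters.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from . import config


@dataclass(frozen=True)
class Fingerprint:
    kind: str                    # "M2D" | "P3D"
    features: frozenset[int]


def _hash_key(parts: tuple) -> int:
    """Stable 64-bit hash of a canonical tuple (run-independent)."""
    digest = hashlib.blake2b(repr(parts).encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big")


# ----------------------------------------------------------------------
# fingerprints
# ----------------------------------------------------------------------

def molprint2d(mol) -> Fingerprint:
    """Atom-environment fingerprint of an RDKit molecule.

    One key per heavy atom: the sorted multiset of (distance, type)
    pairs for all heavy atoms within topological distance <= 2,
    including the central atom at distance 0.  Invariant to input atom
    ordering because each environment is canonicalised by sorting.
    """
    from rdkit import Chem
    if mol is None:
        raise ValueError("unparsable structure (mol is None)")
    if mol.GetNumHeavyAtoms() == 0:
        raise ValueError("structure has no heavy atoms")
    mol = Chem.RemoveHs(mol)
    dmat = Chem.GetDistanceMatrix(mol)

    def atype(atom):
        return (atom.GetSymbol(), atom.GetIsAromatic(), atom.GetDegree())

    keys = set()
    for i, atom in enumerate(mol.GetAtoms()):
        env = []
        for j, other in enumerate(mol.GetAtoms()):
            d = int(dmat[i, j])
            if d <= config.M2D_RADIUS:
                env.append((d, atype(other)))
        keys.add(_hash_key(tuple(sorted(env))))
    return Fingerprint("M2D", frozenset(keys))


def molprint2d_from_smiles(smiles: str, compound_id: str = "?") -> Fingerprint:
    from rdkit import Chem
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES for compound {compound_id}: {smiles!r}")
    return molprint2d(mol)


def _ftype_xyz(point):
    """Accept FeaturePoint-like objects or (type, xyz) tuples."""
    if hasattr(point, "ftype"):
        return point.ftype, np.asarray(point.xyz, dtype=float)
    t, xyz = point
    return t, np.asarray(xyz, dtype=float)


def pharm3d_fp(points: Sequence) -> Fingerprint:
    """Pharmacophore-triplet fingerprint of typed 3D feature points.

    Keys combine the sorted type triple with the sorted distance bins of
    the triangle's sides, so a key is invariant under any relabeling of
    the three points.
    """
    pts = [_ftype_xyz(p) for p in points]
    if len(pts) < 3:
        warnings.warn(f"fewer than 3 feature points ({len(pts)}); "
                      "P3D fingerprint is empty")
        return Fingerprint("P3D", frozenset())
    n_bins = int(round(config.P3D_MAX_DIST / config.P3D_BIN_WIDTH))
    keys = set()
    n = len(pts)
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                trio = (pts[i], pts[j], pts[k])
                types = tuple(sorted(t for t, _ in trio))
                bins = []
                for a in range(3):
                    for b in range(a + 1, 3):
                        d = float(np.linalg.norm(trio[a][1] - trio[b][1]))
                        bins.append(min(int(d / config.P3D_BIN_WIDTH), n_bins - 1))
                keys.add(_hash_key((types, tuple(sorted(bins)))))
    return Fingerprint("P3D", frozenset(keys))


def compound_p3d(conformers: Sequence, min_fraction: float = 0.5) -> Fingerprint:
    """Consensus P3D fingerprint of a conformer ensemble.

    Keeps the triplet keys present in at least ``min_fraction`` of the
    compound's conformers (majority vote by default).  Conformational
    noise perturbs distance bins independently per conformer, so
    consensus keys track the underlying feature geometry far more
    stably than any single conformer's fingerprint.  With one conformer
    this reduces to ``pharm3d_fp``.
    """
    if not conformers:
        raise ValueError("compound_p3d needs at least one conformer")
    fps = [pharm3d_fp(cf.points if hasattr(cf, "points") else cf)
           for cf in conformers]
    counts: dict[int, int] = {}
    for fp in fps:
        for key in fp.features:
            counts[key] = counts.get(key, 0) + 1
    need = max(1, int(np.ceil(min_fraction * len(fps))))
    return Fingerprint("P3D", frozenset(k for k, c in counts.items()
                                        if c >= need))


def soergel(a: Fingerprint, b: Fingerprint) -> float:
    """Soergel distance = 1 − Tanimoto on binary key sets; 0 if both empty."""
    if a.kind != b.kind:
        raise ValueError(f"fingerprint kind mismatch: {a.kind} vs {b.kind}")
    if not a.features and not b.features:
        return 0.0
    inter = len(a.features & b.features)
    union = len(a.features | b.features)
    return 1.0 - inter / union


def distance_matrix(fps: Sequence[Fingerprint]) -> np.ndarray:
    """Square symmetric Soergel distance matrix."""
    n = len(fps)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = soergel(fps[i], fps[j])
    return dm


# ----------------------------------------------------------------------
# hierarchy + Kelley level selection
# ----------------------------------------------------------------------

def hierarchical_cluster(distances: np.ndarray,
                         linkage: str = config.LINKAGE) -> np.ndarray:
    """Agglomerative merge tree (scipy linkage matrix) of a distance matrix."""
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    return scipy_linkage(squareform(d, checks=False), method=linkage)


def kelley_level(Z: np.ndarray, distances: np.ndarray) -> int:
    """Number of clusters minimising the Kelley penalty.

    For every cut with k clusters the average spread is the mean, over
    clusters with >= 2 members, of their mean pairwise distance.
    Spreads are min-max normalised onto [1, N-1] and the penalty is
    normalised_spread(k) + k; the smallest k wins ties.  If every level
    has the same spread (e.g. all-equal distances) there is no
    informative level and 1 is returned with a warning.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if n < 3:
        return 1
    ks, spreads = [], []
    for k in range(1, n):
        labels = cut_tree(Z, n_clusters=k).ravel()
        sp = []
        for c in np.unique(labels):
            idx = np.where(labels == c)[0]
            if len(idx) < 2:
                continue
            sub = d[np.ix_(idx, idx)]
            sp.append(sub[np.triu_indices(len(idx), 1)].mean())
        if sp:
            ks.append(k)
            spreads.append(float(np.mean(sp)))
    spreads = np.array(spreads)
    if len(spreads) == 0 or np.ptp(spreads) == 0:
        warnings.warn("degenerate dendrogram: no informative cut level")
        return 1
    norm = 1.0 + (n - 2) * (spreads - spreads.min()) / np.ptp(spreads)
    penalty = norm + np.array(ks)
    return int(ks[int(np.argmin(penalty))])   # argmin takes first == smallest k


# ----------------------------------------------------------------------
# clustering container + post-processing
# ----------------------------------------------------------------------

@dataclass
class Clustering:
    method: str                           # P3D | M2D | manual
    clusters: list[list[str]]
    special_class: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def all_ids(self) -> list[str]:
        out = [i for c in self.clusters for i in c]
        out.extend(self.special_class)
        return out

    def to_dict(self) -> dict:
        return {"method": self.method, "clusters": self.clusters,
                "special_class": self.special_class, "params": self.params}

    @classmethod
    def from_dict(cls, d: dict) -> "Clustering":
        return cls(d["method"], [list(c) for c in d["clusters"]],
                   list(d.get("special_class", [])), dict(d.get("params", {})))


def _cut_ids(ids: Sequence[str], dm: np.ndarray, k: int,
             linkage: str) -> list[list[str]]:
    Z = hierarchical_cluster(dm, linkage)
    labels = cut_tree(Z, n_clusters=k).ravel()
    return [[ids[i] for i in np.where(labels == c)[0]]
            for c in np.unique(labels)]


def postprocess(clusters: list[list[str]],
                distance_fn: Callable[[str, str], float] | None = None,
                min_size: int = config.MIN_CLUSTER_SIZE,
                max_size: int | None = None,
                max_splits: int = config.MAX_SPLITS,
                linkage: str = config.LINKAGE,
                method: str = "unknown") -> Clustering:
    """Pool tiny clusters into a special class; re-split oversized ones.

    ``distance_fn`` (pairwise distance between compound ids) is required
    only when splitting can occur; splitting re-runs the same
    linkage/Kelley machinery on the oversized cluster, at most
    ``max_splits`` rounds.
    """
    work = [list(c) for c in clusters]
    if max_size is not None:
        for _ in range(max_splits):
            oversized = [c for c in work if len(c) > max_size]
            if not oversized:
                break
            if distance_fn is None:
                raise ValueError("splitting oversized clusters needs distance_fn")
            nxt = [c for c in work if len(c) <= max_size]
            for c in oversized:
                dm = np.zeros((len(c), len(c)))
                for i in range(len(c)):
                    for j in range(i + 1, len(c)):
                        dm[i, j] = dm[j, i] = distance_fn(c[i], c[j])
                Z = hierarchical_cluster(dm, linkage)
                k = kelley_level(Z, dm)
                if k <= 1:  # cannot split further
                    nxt.append(c)
                    continue
                nxt.extend(_cut_ids(c, dm, k, linkage))
            if nxt == work:
                break
            work = nxt
    special = [i for c in work if len(c) < min_size for i in c]
    kept = [c for c in work if len(c) >= min_size]
    return Clustering(method=method, clusters=kept, special_class=special,
                      params={"min_size": min_size, "max_size": max_size,
                              "max_splits": max_splits, "linkage": linkage})


def cluster_compounds(ids: Sequence[str], fps: Sequence[Fingerprint],
                      method: str,
                      linkage: str = config.LINKAGE,
                      min_size: int = config.MIN_CLUSTER_SIZE,
                      max_size_fraction: float | None = config.MAX_SIZE_FRACTION,
                      max_splits: int = config.MAX_SPLITS) -> Clustering:
    """Full pipeline: Soergel distances -> linkage -> Kelley cut -> postprocess."""
    if len(ids) != len(fps):
        raise ValueError("ids and fingerprints must align")
    ids = [str(i) for i in ids]
    dm = distance_matrix(fps)
    Z = hierarchical_cluster(dm, linkage)
    k = kelley_level(Z, dm)
    raw = _cut_ids(ids, dm, k, linkage)
    fp_by_id = dict(zip(ids, fps))
    max_size = (max(min_size, int(np.ceil(max_size_fraction * len(ids))))
                if max_size_fraction else None)
    out = postprocess(raw, distance_fn=lambda a, b: soergel(fp_by_id[a], fp_by_id[b]),
                      min_size=min_size, max_size=max_size,
                      max_splits=max_splits, linkage=linkage, method=method)
    out.params["kelley_k"] = k
    return out


def manual_clustering(assignments: dict[str, str]) -> Clustering:
    """Build a Clustering from user-supplied compound_id -> cluster_name."""
    groups: dict[str, list[str]] = {}
    for cid, name in assignments.items():
        groups.setdefault(str(name), []).append(str(cid))
    clusters = [sorted(groups[k]) for k in sorted(groups)]
    return Clustering(method="manual", clusters=clusters)
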