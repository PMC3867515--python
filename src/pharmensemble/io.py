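"""Plain-text serialisation of pipeline artefacts.

Everything is JSON or CSV so runs are diffable and auditable:
clusterings, conformer feature sets, hypotheses, hit matrices (dense
CSV or sparse coordinate triples) and test-set manifests.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .clustering import Clustering
from .ensemble import HitMatrix
from .pharmacophore import ConformerFeatures, FeaturePoint, PharmacophoreHypothesis
from .selection import TestSetPair


def write_clustering(clustering: Clustering, path: str | Path) -> None:
    Path(path).write_text(json.dumps(clustering.to_dict(), indent=2))


def read_clustering(path: str | Path) -> Clustering:
    return Clustering.from_dict(json.loads(Path(path).read_text()))


def write_features(conformers: Mapping[str, Sequence[ConformerFeatures]],
                   path: str | Path) -> None:
    doc = {cid: [{"conformer_index": cf.conformer_index,
                  "points": [[p.ftype, *p.xyz] for p in cf.points]}
                 for cf in confs]
           for cid, confs in conformers.items()}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_features(path: str | Path) -> dict[str, list[ConformerFeatures]]:
    doc = json.loads(Path(path).read_text())
    return {cid: [ConformerFeatures(cid, int(cf["conformer_index"]),
                                    [FeaturePoint(p[0], tuple(p[1:4]))
                                     for p in cf["points"]])
                  for cf in confs]
            for cid, confs in doc.items()}


def write_hypotheses(hyps: Sequence[PharmacophoreHypothesis],
                     path: str | Path) -> None:
    Path(path).write_text(json.dumps([h.to_dict() for h in hyps], indent=1))


def read_hypotheses(path: str | Path) -> list[PharmacophoreHypothesis]:
    return [PharmacophoreHypothesis.from_dict(d)
            for d in json.loads(Path(path).read_text())]


def write_hit_matrix(hm: HitMatrix, path: str | Path,
                     sparse: bool = False) -> None:
    path = Path(path)
    if sparse:
        lines = [f"{len(hm.compound_ids)} {len(hm.hyp_ids)}"]
        lines += [f"# compound {i} {c}" for i, c in enumerate(hm.compound_ids)]
        lines += [f"# hypothesis {j} {h}" for j, h in enumerate(hm.hyp_ids)]
        for i, j in zip(*hm.hits.nonzero()):
            lines.append(f"{i} {j}")
        path.write_text("\n".join(lines) + "\n")
    else:
        hm.to_frame().to_csv(path, index_label="compound_id")


def read_hit_matrix(path: str | Path) -> HitMatrix:
    df = pd.read_csv(path, index_col="compound_id")
    return HitMatrix.from_frame(df)


def write_test_sets(pairs: Mapping[str, TestSetPair], path: str | Path,
                    seed: int | None = None, params: dict | None = None) -> None:
    doc = {"seed": seed, "params": params or {},
           "schemes": {k: p.to_dict() for k, p in pairs.items()}}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_test_sets(path: str | Path) -> dict[str, TestSetPair]:
    doc = json.loads(Path(path).read_text())
    return {k: TestSetPair(d["actives"], d["decoys"],
                           d["assumed_inactives"], d["scheme"])
            for k, d in doc["schemes"].items()}
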