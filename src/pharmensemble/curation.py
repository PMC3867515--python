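"""Harmonise heterogeneous binding-affinity records to Ki (nM) and label compounds.

Activity databases mix Ki, IC50 and their negative log forms, measured on
different species and receptor preparations.  This module converts every
record to an equivalent Ki in nM (IC50 is assumed to equal 2*Ki; pKi and
pIC50 are log10 molar), aggregates duplicate records for a compound by
preferring human-receptor Ki data and taking a median, and assigns the
activity label used throughout the pipeline:

    Ki <= 100 nM          active
    100 < Ki <= 1000 nM   ambiguous (excluded from modelling and testing)
    Ki > 1000 nM          inactive
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from statistics import median
from typing import Iterable, Sequence

import pandas as pd

from . import config

MEASURES = ("Ki", "IC50", "pKi", "pIC50")
SPECIES = ("human", "rat", "other")
PREPARATIONS = ("cloned", "native", "unknown")


@dataclass(frozen=True)
class ActivityRecord:
    """One raw activity measurement for a compound."""

    compound_id: str
    measure: str                # Ki | IC50 | pKi | pIC50
    value: float                # nM for Ki/IC50, log10 molar for pKi/pIC50
    species: str = "other"      # human | rat | other
    preparation: str = "unknown"

    def __post_init__(self):
        if self.measure not in MEASURES:
            raise ValueError(
                f"{self.compound_id}: unknown measure {self.measure!r}")
        if self.species not in SPECIES:
            raise ValueError(
                f"{self.compound_id}: unknown species {self.species!r}")
        if not self.value > 0:
            raise ValueError(
                f"{self.compound_id}: non-positive value {self.value!r} "
                f"for measure {self.measure}")


@dataclass
class CompoundRecord:
    compound_id: str
    structure: str | None = None   # SMILES
    ki_nM: float | None = None
    label: str = "unlabeled"       # active | inactive | ambiguous | unlabeled


def normalize_units(value: float, units: str) -> float:
    """Convert a concentration to nM.  Accepts nM, uM/µM, M."""
    try:
        return value * config.UNIT_TO_NM[units]
    except KeyError:
        raise ValueError(f"unsupported units {units!r}; expected one of "
                         f"{sorted(config.UNIT_TO_NM)}") from None


def to_ki(record: ActivityRecord) -> float:
    """Equivalent Ki in nM for a single activity record.

    Ki passes through; IC50 is halved (IC50 assumed to be 2*Ki); pKi and
    pIC50 are converted off the log10 molar scale (Ki[nM] = 10**(9 - p)),
    with pIC50 routed through IC50 first.
    """
    m, v = record.measure, record.value
    if m == "Ki":
        return v
    if m == "IC50":
        return v * config.IC50_TO_KI
    if m == "pKi":
        return 10.0 ** (9.0 - v)
    # pIC50 -> IC50 in nM -> Ki
    return 10.0 ** (9.0 - v) * config.IC50_TO_KI


def _stratum(record: ActivityRecord) -> int:
    species = record.species if record.species in ("human", "rat") else "other"
    return config.STRATUM_ORDER.index((species, record.measure == "Ki"))


def aggregate(records: Sequence[ActivityRecord]) -> float:
    """Collapse duplicate records for one compound into a single Ki (nM).

    Only the most-preferred (species, measure) stratum present is kept —
    human Ki beats human IC50-type data, which beats rat Ki, and so on —
    then the median of the converted Ki values is returned (mean of the
    two central values for even counts).
    """
    if not records:
        raise ValueError("aggregate() requires at least one record")
    ids = {r.compound_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records span multiple compounds: {sorted(ids)}")
    best = min(_stratum(r) for r in records)
    kept = [r for r in records if _stratum(r) == best]
    return float(median(to_ki(r) for r in kept))


def label_compound(ki_nM: float) -> str:
    """Activity label from a Ki in nM (thresholds in config)."""
    if not ki_nM > 0:
        raise ValueError(f"Ki must be positive, got {ki_nM}")
    if ki_nM <= config.ACTIVE_KI_NM:
        return "active"
    if ki_nM > config.INACTIVE_KI_NM:
        return "inactive"
    return "ambiguous"


REQUIRED_COLUMNS = ("compound_id", "measure", "value")


def curate_table(activities: pd.DataFrame,
                 structures: dict[str, str] | None = None) -> tuple[pd.DataFrame, dict]:
    """Curate a raw activity table into one labelled row per compound.

    ``activities`` needs columns compound_id, measure, value and optionally
    smiles, units, species, preparation.  Returns the curated table
    (compound_id, smiles, ki_nM, label) and a JSON-able report with label
    counts and the ids excluded as ambiguous.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in activities.columns]
    if missing:
        raise ValueError(f"activity table lacks columns: {missing}")
    df = activities.copy()
    if "units" in df.columns:
        conc = df["measure"].isin(["Ki", "IC50"])
        df.loc[conc, "value"] = [
            normalize_units(v, u) for v, u in
            zip(df.loc[conc, "value"], df.loc[conc, "units"].fillna("nM"))
        ]
    if "species" not in df.columns:
        df["species"] = "other"
    if "preparation" not in df.columns:
        df["preparation"] = "unknown"

    rows, report = [], {"n_input_records": int(len(df)),
                        "counts": {}, "excluded_ambiguous": []}
    for cid, grp in df.groupby("compound_id", sort=True):
        recs = [ActivityRecord(str(cid), r.measure, float(r.value),
                               str(r.species), str(r.preparation))
                for r in grp.itertuples()]
        ki = aggregate(recs)
        label = label_compound(ki)
        smiles = None
        if structures and str(cid) in structures:
            smiles = structures[str(cid)]
        elif "smiles" in grp.columns:
            vals = grp["smiles"].dropna()
            smiles = str(vals.iloc[0]) if len(vals) else None
        if label == "ambiguous":
            report["excluded_ambiguous"].append(str(cid))
        rows.append({"compound_id": str(cid), "smiles": smiles,
                     "ki_nM": ki, "label": label})
    curated = pd.DataFrame(rows, columns=["compound_id", "smiles", "ki_nM", "label"])
    for lab in ("active", "ambiguous", "inactive"):
        report["counts"][lab] = int((curated["label"] == lab).sum())
    return curated, report


def read_structures_sdf(path: str | Path) -> dict[str, str]:
    """compound_id -> SMILES from an SDF keyed by molecule title or _Name."""
    from rdkit import Chem
    out: dict[str, str] = {}
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else None
        if name:
            out[name] = Chem.MolToSmiles(mol)
    return out


def write_outputs(curated: pd.DataFrame, report: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curated.to_csv(out / "curated.csv", index=False)
    (out / "curation_report.json").write_text(json.dumps(report, indent=2))
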