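"""Formulation tables: CSV round-trip, threshold labels, mixtures-out splits.

The CSV dialect is UTF-8 with a decimal point, one row per formulation and
time point.  Mandatory columns::

    a_monomer, b_monomer, n_a1, n_b, n_a2, terminus_start, terminus_end,
    polymer_feed, t_measure,
    drug1_name, drug1_smiles, drug1_feed, drug1_solubilized

and optionally ``drug2_*`` for coformulations plus free-form experimental
setting columns prefixed ``setting_``.  Rows without a measured
solubilization are kept and flagged prediction-only.  A column-mapping dict
can adapt other dialects to this schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .polymer import (DrugSpec, Formulation, MonomerSpec, PolymerSpec,
                      load_monomer_registry, loading_metrics)

__all__ = [
    "FormulationTable",
    "SplitPlan",
    "FormatError",
    "read_formulation_table",
    "write_formulation_table",
    "label_thresholds",
    "mixtures_out_split",
    "LC_THRESHOLDS",
    "LE_THRESHOLDS",
]

LC_THRESHOLDS = (10.0, 20.0, 30.0, 40.0)
LE_THRESHOLDS = (20.0, 40.0, 60.0, 80.0)

MANDATORY_COLUMNS = (
    "a_monomer", "b_monomer", "n_a1", "n_b", "n_a2",
    "polymer_feed", "t_measure", "drug1_name", "drug1_smiles", "drug1_feed",
)
KNOWN_COLUMNS = MANDATORY_COLUMNS + (
    "terminus_start", "terminus_end", "drug1_solubilized",
    "drug2_name", "drug2_smiles", "drug2_feed", "drug2_solubilized",
)


class FormatError(ValueError):
    pass


@dataclass
class FormulationTable:
    rows: List[Formulation]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def group_keys(self) -> List[Tuple[str, str, Tuple[str, ...]]]:
        return [f.group_key for f in self.rows]

    def measured(self) -> "FormulationTable":
        """Rows carrying a solubilization measurement for every drug."""
        keep = [f for f in self.rows
                if f.m_solubilized is not None and all(s is not None for s in f.m_solubilized)]
        return FormulationTable(rows=keep, provenance=self.provenance)


@dataclass
class SplitPlan:
    """Group-level TS/HS assignment (mixtures-out)."""

    assignment: Dict[Tuple[str, str, Tuple[str, ...]], str]
    fraction: float
    seed: int

    def side(self, formulation: Formulation) -> str:
        return self.assignment[formulation.group_key]

    def to_json(self) -> str:
        ser = {json.dumps(list((k[0], k[1], list(k[2])))): v
               for k, v in self.assignment.items()}
        return json.dumps({"fraction": self.fraction, "seed": self.seed,
                           "assignment": ser}, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        raw = json.loads(text)
        assignment = {}
        for key, side in raw["assignment"].items():
            a, b, drugs = json.loads(key)
            assignment[(a, b, tuple(drugs))] = side
        return cls(assignment=assignment, fraction=raw["fraction"], seed=raw["seed"])


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or value == ""


def read_formulation_table(
    path,
    registry: Optional[Dict[str, MonomerSpec]] = None,
    column_map: Optional[Mapping[str, str]] = None,
) -> FormulationTable:
    """Parse a formulation CSV into typed rows.

    Unknown columns produce a warning in ``provenance``; missing mandatory
    columns raise :class:`FormatError`.  Malformed rows are reported with
    their (1-based, header-exclusive) line numbers.
    """
    reg = registry if registry is not None else load_monomer_registry()
    frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"missing mandatory columns: {missing}")
    unknown = [c for c in frame.columns
               if c not in KNOWN_COLUMNS and not c.startswith("setting_")]
    notes = [f"warning: unknown columns ignored: {unknown}"] if unknown else []

    rows: List[Formulation] = []
    errors: List[str] = []
    for line, rec in enumerate(frame.to_dict("records"), start=1):
        try:
            a = reg[str(rec["a_monomer"])]
            b = reg[str(rec["b_monomer"])]
            t1 = reg[str(rec.get("terminus_start") or "Me")]
            t2 = reg[str(rec.get("terminus_end") or "Pip")]
            polymer = PolymerSpec(
                a_monomer=a, b_monomer=b,
                block_lengths=(int(rec["n_a1"]), int(rec["n_b"]), int(rec["n_a2"])),
                termini=(t1, t2),
            )
            drug_feeds = [(DrugSpec(str(rec["drug1_name"]), str(rec["drug1_smiles"])),
                           float(rec["drug1_feed"]))]
            sols: List[Optional[float]] = [
                None if _is_missing(rec.get("drug1_solubilized"))
                else float(rec["drug1_solubilized"])]
            if not _is_missing(rec.get("drug2_name")):
                drug_feeds.append((DrugSpec(str(rec["drug2_name"]), str(rec["drug2_smiles"])),
                                   float(rec["drug2_feed"])))
                sols.append(None if _is_missing(rec.get("drug2_solubilized"))
                            else float(rec["drug2_solubilized"]))
            settings = {k[len("setting_"):]: str(rec[k]) for k in frame.columns
                        if k.startswith("setting_") and not _is_missing(rec.get(k))}
            rows.append(Formulation(
                polymer=polymer,
                drug_feeds=tuple(drug_feeds),
                m_polymer_feed=float(rec["polymer_feed"]),
                t_measure=float(rec["t_measure"]),
                m_solubilized=tuple(sols),
                settings=settings,
            ))
        except (KeyError, ValueError) as exc:
            errors.append(f"row {line}: {exc}")
    if errors:
        raise FormatError("malformed rows:\n" + "\n".join(errors))
    return FormulationTable(rows=rows, provenance="; ".join([str(path)] + notes))


def write_formulation_table(table: FormulationTable, path) -> None:
    records = []
    for f in table.rows:
        rec: Dict[str, object] = {
            "a_monomer": f.polymer.a_monomer.name,
            "b_monomer": f.polymer.b_monomer.name,
            "n_a1": f.polymer.block_lengths[0],
            "n_b": f.polymer.block_lengths[1],
            "n_a2": f.polymer.block_lengths[2],
            "terminus_start": f.polymer.termini[0].name,
            "terminus_end": f.polymer.termini[1].name,
            "polymer_feed": f.m_polymer_feed,
            "t_measure": f.t_measure,
        }
        for i, (drug, feed) in enumerate(f.drug_feeds, start=1):
            rec[f"drug{i}_name"] = drug.name
            rec[f"drug{i}_smiles"] = drug.structure
            rec[f"drug{i}_feed"] = feed
            sol = None if f.m_solubilized is None else f.m_solubilized[i - 1]
            rec[f"drug{i}_solubilized"] = sol
        for k, v in f.settings.items():
            rec[f"setting_{k}"] = v
        records.append(rec)
    frame = pd.DataFrame(records)
    lead = [c for c in ("a_monomer", "b_monomer", "n_a1", "n_b", "n_a2",
                        "terminus_start", "terminus_end", "polymer_feed", "t_measure",
                        "drug1_name", "drug1_smiles", "drug1_feed", "drug1_solubilized",
                        "drug2_name", "drug2_smiles", "drug2_feed", "drug2_solubilized")
            if c in frame.columns]
    frame = frame[lead + [c for c in frame.columns if c not in lead]]
    frame.to_csv(path, index=False)


def label_thresholds(table: FormulationTable, kind: str, threshold: float,
                     total_cargo: bool = False) -> np.ndarray:
    """Binary labels: metric >= threshold (inclusive), first drug's metric."""
    if kind not in ("LC", "LE"):
        raise ValueError("kind must be 'LC' or 'LE'")
    labels = []
    for f in table.rows:
        metrics = loading_metrics(f, total_cargo=total_cargo)
        _, lc, le = metrics[0]
        value = lc if kind == "LC" else le
        labels.append(value >= threshold)
    return np.asarray(labels, dtype=bool)


def mixtures_out_split(
    table: FormulationTable,
    fraction: float = 0.8,
    seed: int = 0,
    labels: Optional[Sequence[bool]] = None,
) -> SplitPlan:
    """Group-aware stratified TS/HS split.

    All rows sharing (A monomer, B monomer, sorted drug names) land on the
    same side.  Greedy seeded bin-packing targets both the requested TS row
    share and, when labels are given, a holdout class ratio close to the
    full-table ratio.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    keys = table.group_keys
    y = np.ones(len(keys)) if labels is None else np.asarray(labels, dtype=float)
    groups: Dict[Tuple, Dict[str, float]] = {}
    for key, yi in zip(keys, y):
        g = groups.setdefault(key, {"size": 0.0, "pos": 0.0})
        g["size"] += 1
        g["pos"] += float(yi)

    total = float(len(keys))
    total_pos = float(y.sum())
    biggest = max(g["size"] for g in groups.values())
    warning = biggest > (1 - fraction) * total  # caller may inspect plan anyway

    rng = np.random.default_rng(seed)
    order = sorted(groups)  # deterministic base order
    rng.shuffle(order)
    order.sort(key=lambda k: -groups[k]["size"])  # stable: keeps shuffled tie order

    ts = {"size": 0.0, "pos": 0.0}
    hs = {"size": 0.0, "pos": 0.0}
    assignment: Dict[Tuple, str] = {}
    for key in order:
        g = groups[key]

        def cost(side_ts: bool) -> float:
            t_s = ts["size"] + (g["size"] if side_ts else 0.0)
            h_s = hs["size"] + (0.0 if side_ts else g["size"])
            t_p = ts["pos"] + (g["pos"] if side_ts else 0.0)
            h_p = hs["pos"] + (0.0 if side_ts else g["pos"])
            c = (t_s - fraction * total) ** 2 + (h_s - (1 - fraction) * total) ** 2
            if total_pos > 0:
                c += ((t_p - fraction * total_pos) ** 2
                      + (h_p - (1 - fraction) * total_pos) ** 2)
            return c

        side = "TS" if cost(True) <= cost(False) else "HS"
        assignment[key] = side
        tgt = ts if side == "TS" else hs
        tgt["size"] += g["size"]
        tgt["pos"] += g["pos"]
    plan = SplitPlan(assignment=assignment, fraction=fraction, seed=seed)
    return plan
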