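"""Domain types for ABA-triblock pOx/pOzi micelle formulations.

The building blocks of these micelles are 2-oxazoline / 2-oxazine repeat
units (a tertiary polyamide backbone: ``-[N(C(=O)R)-CH2-CH2(-CH2)]-``), two
chain termini (typically a methyl initiator and a piperidine quencher) and
one or two hydrophobic drug molecules.  This module owns

* structure construction: capping repeat units into valence-complete small
  molecules for descriptor computation, and assembling the T1-A-B-A-T2
  pseudotrimer used as the simplex-descriptor proxy for the full polymer;
* stoichiometry: drugs per chain and molar fractions of every micellar
  component;
* the two loading metrics, loading capacity (LC) and loading efficiency (LE).

Attachment points in repeat-unit SMILES are dummy atoms carrying atom-map
numbers, e.g. ``[*:1]N(C(C)=O)CC[*:2]``; map 1 is the backbone nitrogen end
and map 2 the backbone carbon end.  Termini carry a single ``[*:1]``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

from rdkit import Chem
from rdkit.Chem import Descriptors, rdmolops

__all__ = [
    "MonomerSpec",
    "PolymerSpec",
    "DrugSpec",
    "Formulation",
    "Stoichiometry",
    "StructureError",
    "ChemistryError",
    "build_capped_monomer",
    "build_pseudotrimer",
    "drugs_per_chain",
    "molar_fractions",
    "loading_metrics",
    "load_monomer_registry",
    "make_polymer",
]

_CH4_MASS = 16.043
_H_MASS = 1.008


class StructureError(ValueError):
    """Raised when an input structure violates a structural precondition."""


class ChemistryError(ValueError):
    """Raised when a chemically invalid operation is requested."""


def _attachment_atoms(mol: Chem.Mol) -> List[int]:
    """Indices of dummy (attachment) atoms, ordered by atom-map number."""
    dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    return [a.GetIdx() for a in sorted(dummies, key=lambda a: (a.GetAtomMapNum(), a.GetIdx()))]


def build_capped_monomer(repeat_unit: str, role: str = "A") -> Chem.Mol:
    """Convert an attachment-marked repeat unit into a capped small molecule.

    One attachment point is replaced by a hydrogen, the other by a methyl
    group.  A backbone *nitrogen* attachment is always capped with methyl
    (never hydrogen) so that the capped molecule keeps the tertiary amide
    substitution pattern of the polymer backbone.  Termini (one attachment
    point) are capped with a single methyl for the same reason.
    """
    mol = Chem.MolFromSmiles(repeat_unit)
    if mol is None:
        raise StructureError(f"unparsable repeat unit: {repeat_unit!r}")
    attach = _attachment_atoms(mol)
    is_terminus = role in ("terminus_start", "terminus_end")
    expected = 1 if is_terminus else 2
    if len(attach) != expected:
        raise StructureError(
            f"{role} unit must have exactly {expected} attachment point(s), "
            f"found {len(attach)}: {repeat_unit!r}"
        )

    rw = Chem.RWMol(mol)
    # Decide caps: every N-attachment gets methyl; among the rest, the first
    # gets the (single) methyl if none was used on an N, all others hydrogen.
    neighbors = []
    for idx in attach:
        nbrs = rw.GetAtomWithIdx(idx).GetNeighbors()
        if len(nbrs) != 1:
            raise StructureError("attachment dummy must have exactly one neighbor")
        neighbors.append(nbrs[0].GetIdx())

    caps: List[str] = []
    methyl_used = False
    for nbr in neighbors:
        if rw.GetAtomWithIdx(nbr).GetAtomicNum() == 7:
            caps.append("C")
            methyl_used = True
        else:
            caps.append("")
    if not methyl_used:
        caps[-1] = "C"  # carbon-carbon pair: H on the map-1 end, methyl on map-2
    if is_terminus and not caps[0]:
        caps[0] = "C"

    # Apply caps: replace dummies by carbon or delete them (implicit H fills in).
    for idx, cap in sorted(zip(attach, caps), reverse=True):
        if cap == "C":
            atom = rw.GetAtomWithIdx(idx)
            atom.SetAtomicNum(6)
            atom.SetAtomMapNum(0)
            atom.SetNoImplicit(False)
            atom.SetNumExplicitHs(0)
        else:
            rw.RemoveAtom(idx)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception as exc:  # pragma: no cover - malformed valence input
        raise ChemistryError(f"cannot cap {repeat_unit!r}: {exc}") from exc
    if rdmolops.GetFormalCharge(out) != 0:
        raise ChemistryError(f"capped structure of {repeat_unit!r} carries net charge")
    return out


@dataclass(frozen=True)
class MonomerSpec:
    """A repeat unit or chain terminus with its capped-molecule counterpart."""

    name: str
    role: str  # "A" | "B" | "terminus_start" | "terminus_end"
    repeat_unit: str  # attachment-marked SMILES
    capped_smiles: str = ""
    mw_repeat: float = 0.0

    def __post_init__(self):
        if self.role not in ("A", "B", "terminus_start", "terminus_end"):
            raise ValueError(f"unknown monomer role {self.role!r}")
        if not self.capped_smiles:
            capped = build_capped_monomer(self.repeat_unit, self.role)
            object.__setattr__(self, "capped_smiles", Chem.MolToSmiles(capped))
        if self.mw_repeat <= 0.0:
            capped_mass = Descriptors.MolWt(Chem.MolFromSmiles(self.capped_smiles))
            if self.role in ("terminus_start", "terminus_end"):
                # capped terminus = fragment + CH3
                mw = capped_mass - (_CH4_MASS - _H_MASS)
            else:
                # capped repeat = fragment + CH3 + H
                mw = capped_mass - _CH4_MASS
            object.__setattr__(self, "mw_repeat", mw)
        if self.mw_repeat <= 0.0:
            raise ValueError(f"non-positive repeat-unit mass for {self.name}")

    @property
    def capped_mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.capped_smiles)


@dataclass(frozen=True)
class PolymerSpec:
    """An ABA triblock: two hydrophilic A blocks flanking a hydrophobic B block."""

    a_monomer: MonomerSpec
    b_monomer: MonomerSpec
    block_lengths: Tuple[int, int, int]
    termini: Tuple[MonomerSpec, MonomerSpec]
    mw_polymer: float = 0.0

    def __post_init__(self):
        nA1, nB, nA2 = self.block_lengths
        if min(nA1, nB, nA2) < 1:
            raise ValueError("block lengths must be >= 1")
        expected = (
            (nA1 + nA2) * self.a_monomer.mw_repeat
            + nB * self.b_monomer.mw_repeat
            + self.termini[0].mw_repeat
            + self.termini[1].mw_repeat
        )
        if self.mw_polymer <= 0.0:
            object.__setattr__(self, "mw_polymer", expected)
        elif abs(self.mw_polymer - expected) > 0.1:
            raise ValueError(
                f"mw_polymer {self.mw_polymer:.2f} inconsistent with blocks ({expected:.2f})"
            )

    @property
    def name(self) -> str:
        return f"A-{self.b_monomer.name}-A"


@dataclass(frozen=True)
class DrugSpec:
    name: str
    structure: str  # SMILES
    mw_drug: float = 0.0

    def __post_init__(self):
        mol = Chem.MolFromSmiles(self.structure)
        if mol is None:
            raise StructureError(f"unparsable drug SMILES for {self.name!r}")
        if len(rdmolops.GetMolFrags(mol)) != 1:
            raise StructureError(f"drug {self.name!r} is not a single connected molecule")
        if self.mw_drug <= 0.0:
            object.__setattr__(self, "mw_drug", Descriptors.MolWt(mol))

    @property
    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.structure)


@dataclass(frozen=True)
class Formulation:
    """One solubilization experiment: polymer + 1-2 drugs + feeds + time point."""

    polymer: PolymerSpec
    drug_feeds: Tuple[Tuple[DrugSpec, float], ...]
    m_polymer_feed: float
    t_measure: float = 0.0
    m_solubilized: Optional[Tuple[Optional[float], ...]] = None
    settings: Dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not 1 <= len(self.drug_feeds) <= 2:
            raise ValueError("formulation must contain 1 or 2 drugs")
        # canonical drug order (by name) so coformulation features and
        # predictions are invariant to input ordering
        order = sorted(range(len(self.drug_feeds)),
                       key=lambda i: self.drug_feeds[i][0].name)
        if order != list(range(len(self.drug_feeds))):
            object.__setattr__(self, "drug_feeds",
                               tuple(self.drug_feeds[i] for i in order))
            if self.m_solubilized is not None and len(self.m_solubilized) == len(order):
                object.__setattr__(self, "m_solubilized",
                                   tuple(self.m_solubilized[i] for i in order))
        if self.m_polymer_feed <= 0:
            raise ValueError("polymer feed must be positive")
        if any(feed < 0 for _, feed in self.drug_feeds):
            raise ValueError("drug feeds must be nonnegative")
        if self.t_measure < 0:
            raise ValueError("measurement time must be >= 0")
        if self.m_solubilized is not None:
            if len(self.m_solubilized) != len(self.drug_feeds):
                raise ValueError("one solubilized mass per drug required")
            for (drug, feed), sol in zip(self.drug_feeds, self.m_solubilized):
                if sol is not None and not (-1e-9 <= sol <= feed + 1e-9):
                    raise ValueError(
                        f"solubilized mass {sol} of {drug.name} exceeds feed {feed}"
                    )

    @property
    def group_key(self) -> Tuple[str, str, Tuple[str, ...]]:
        """Mixture identity for mixtures-out splitting: A, B, sorted drug names."""
        return (
            self.polymer.a_monomer.name,
            self.polymer.b_monomer.name,
            tuple(sorted(d.name for d, _ in self.drug_feeds)),
        )

    @property
    def total_drug_feed(self) -> float:
        return sum(feed for _, feed in self.drug_feeds)


@dataclass(frozen=True)
class Stoichiometry:
    """Counts and molar fractions of every micellar component per polymer chain."""

    counts: Dict[str, float]
    fractions: Dict[str, float]

    @property
    def n_total(self) -> float:
        return sum(self.counts.values())


def drugs_per_chain(formulation: Formulation) -> Dict[str, float]:
    """Number of drug molecules per polymer chain, from feed mass ratio.

    ``N_drug = (m_added / m_polymer_feed) * (MW_polymer / MW_drug)``; kept
    fractional (the molar-fraction weighting downstream needs continuity).
    """
    if formulation.m_polymer_feed <= 0:
        raise ValueError("polymer feed must be positive")
    mw_p = formulation.polymer.mw_polymer
    return {
        drug.name: (feed / formulation.m_polymer_feed) * (mw_p / drug.mw_drug)
        for drug, feed in formulation.drug_feeds
    }


def molar_fractions(formulation: Formulation) -> Stoichiometry:
    """Molar fraction of each component type per chain.

    N_total counts the A and B repeat units, the two termini, and the
    (fractional) number of drug molecules per chain.
    """
    nA1, nB, nA2 = formulation.polymer.block_lengths
    counts: Dict[str, float] = {
        "T1": 1.0,
        "A": float(nA1 + nA2),
        "B": float(nB),
        "T2": 1.0,
    }
    for name, n in drugs_per_chain(formulation).items():
        counts[f"drug:{name}"] = n
    total = sum(counts.values())
    fractions = {k: v / total for k, v in counts.items()}
    return Stoichiometry(counts=counts, fractions=fractions)


def loading_metrics(
    formulation: Formulation, total_cargo: bool = False
) -> List[Tuple[str, float, float]]:
    """Per-drug (LC %, LE %).

    ``LC = 100 * m_sol / (m_sol + m_polymer_feed)`` (complete polymer
    dissolution assumed) and ``LE = 100 * m_sol / m_added``.  For
    coformulations the default uses each drug's own solubilized mass in the
    LC drug term; ``total_cargo=True`` uses the summed solubilized mass.
    """
    if formulation.m_solubilized is None:
        raise ValueError("no measured solubilization on this formulation")
    sols = formulation.m_solubilized
    if any(s is None for s in sols):
        raise ValueError("solubilized mass missing for at least one drug")
    total_sol = sum(sols)  # type: ignore[arg-type]
    out = []
    for (drug, feed), m_sol in zip(formulation.drug_feeds, sols):
        if feed <= 0:
            raise ValueError(f"zero drug feed for {drug.name}")
        assert m_sol is not None
        cargo = total_sol if total_cargo else m_sol
        lc = 100.0 * m_sol / (cargo + formulation.m_polymer_feed)
        le = 100.0 * m_sol / feed
        out.append((drug.name, lc, le))
    return out


def _connect(a_mol: Chem.Mol, a_attach: int, b_mol: Chem.Mol, b_attach: int) -> Tuple[Chem.Mol, List[int]]:
    """Join two fragments by bonding the neighbors of two dummy atoms."""
    combo = Chem.RWMol(Chem.CombineMols(a_mol, b_mol))
    offset = a_mol.GetNumAtoms()
    ia, ib = a_attach, b_attach + offset
    na = combo.GetAtomWithIdx(ia).GetNeighbors()[0].GetIdx()
    nb = combo.GetAtomWithIdx(ib).GetNeighbors()[0].GetIdx()
    combo.AddBond(na, nb, Chem.BondType.SINGLE)
    for idx in sorted((ia, ib), reverse=True):
        combo.RemoveAtom(idx)
    return combo.GetMol(), []


def build_pseudotrimer(polymer: PolymerSpec) -> Chem.Mol:
    """Single linear molecule T1-A-B-A-T2, each building block once.

    Used only as the simplex-descriptor (SiRMS) input for the polymer; the
    actual monomer ratios enter through the molar-fraction weighting, so the
    pseudotrimer implicitly assumes roughly 2:1 A/B stoichiometry.
    """
    t1 = Chem.MolFromSmiles(polymer.termini[0].repeat_unit)
    t2 = Chem.MolFromSmiles(polymer.termini[1].repeat_unit)
    a = Chem.MolFromSmiles(polymer.a_monomer.repeat_unit)
    b = Chem.MolFromSmiles(polymer.b_monomer.repeat_unit)
    for m, label in ((t1, "T1"), (t2, "T2"), (a, "A"), (b, "B")):
        if m is None:
            raise StructureError(f"unparsable {label} unit")

    def attach_points(m: Chem.Mol) -> List[int]:
        return _attachment_atoms(m)

    # chain order: T1 - A - B - A - T2, bonding tail-to-head (map2 -> map1)
    chain = t1
    for unit in (a, b, a, t2):
        left = attach_points(chain)[-1]
        right = attach_points(unit)[0]
        chain, _ = _connect(chain, left, unit, right)
    if _attachment_atoms(chain):
        raise StructureError("pseudotrimer retains open attachment points")
    try:
        Chem.SanitizeMol(chain)
    except Exception as exc:
        raise StructureError(f"cannot assemble pseudotrimer: {exc}") from exc
    if len(rdmolops.GetMolFrags(chain)) != 1:
        raise StructureError("pseudotrimer is not a single connected molecule")
    return chain


# ---------------------------------------------------------------------------
# monomer registry

def load_monomer_registry(path: Optional[str] = None) -> Dict[str, MonomerSpec]:
    """Load the named monomer registry (JSON: name -> role, SMILES, overrides)."""
    if path is None:
        text = resources.files("poxload.data").joinpath("monomers.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    registry = {}
    for name, entry in raw.items():
        registry[name] = MonomerSpec(
            name=name,
            role=entry["role"],
            repeat_unit=entry["smiles"],
            capped_smiles=entry.get("capped_smiles", ""),
            mw_repeat=float(entry.get("mw_repeat", 0.0)),
        )
    return registry


def make_polymer(
    b_name: str,
    a_name: str = "MeOx",
    block_lengths: Sequence[int] = (35, 20, 35),
    termini: Tuple[str, str] = ("Me", "Pip"),
    registry: Optional[Dict[str, MonomerSpec]] = None,
) -> PolymerSpec:
    """Convenience constructor for registry polymers like ``A-nPrOzi-A``.

    The default 35/20/35 block lengths and methyl/piperidine termini are the
    nominal composition of the pMeOx-b-pB-b-pMeOx triblocks used in the
    underlying solubilization studies.
    """
    reg = registry if registry is not None else load_monomer_registry()
    if b_name.startswith("A-") and b_name.endswith("-A"):
        b_name = b_name[2:-2]
    return PolymerSpec(
        a_monomer=reg[a_name],
        b_monomer=reg[b_name],
        block_lengths=tuple(int(x) for x in block_lengths),  # type: ignore[arg-type]
        termini=(reg[termini[0]], reg[termini[1]]),
    )
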