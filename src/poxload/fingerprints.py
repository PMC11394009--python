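"""Count fingerprints for micellar components and their mixture combination.

Per-component substructure counts (Morgan/ECFP, RDKit path, Avalon, MACCS)
are combined into mixture fingerprints by multiplying every bit count with
the component's copy number per polymer chain (monomer block lengths, two
termini, fractional drugs-per-chain) and summing:
``FP_MIX[b] = sum_i N_i * FP_i[b]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Tuple, Union

from rdkit import Chem
from rdkit.Avalon import pyAvalonTools
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

__all__ = ["CountFingerprint", "FingerprintBackend", "mix_count_fingerprints", "FP_FAMILIES"]

FP_FAMILIES = ("ecfp4", "ecfp6", "rdk5", "rdk7", "avalon", "maccs")
_DEFAULT_WIDTH = 16384  # enlarged over the usual 2048 to limit bit collisions


@dataclass(frozen=True)
class CountFingerprint:
    counts: Dict[int, float]
    family: str
    width: int

    def __post_init__(self):
        for idx, c in self.counts.items():
            if c < 0:
                raise ValueError("negative fingerprint count")
            if not 0 <= idx < self.width:
                raise ValueError(f"bit index {idx} outside width {self.width}")


class FingerprintBackend:
    """Hashed count-fingerprint generators with a shared width."""

    def __init__(self, width: int = _DEFAULT_WIDTH):
        self.width = width
        self._gens = {
            "ecfp4": rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=width),
            "ecfp6": rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=width),
            "rdk5": rdFingerprintGenerator.GetRDKitFPGenerator(maxPath=5, fpSize=width),
            "rdk7": rdFingerprintGenerator.GetRDKitFPGenerator(maxPath=7, fpSize=width),
        }
        self._cache: Dict[Tuple[str, str], CountFingerprint] = {}

    def compute(self, structure: Union[str, Chem.Mol], family: str) -> CountFingerprint:
        if family not in FP_FAMILIES:
            raise ValueError(f"unknown fingerprint family {family!r}")
        mol = Chem.MolFromSmiles(structure) if isinstance(structure, str) else structure
        if mol is None:
            raise ValueError(f"unparsable SMILES: {structure!r}")
        key = (Chem.MolToSmiles(mol), family)
        if key in self._cache:
            return self._cache[key]
        if family in self._gens:
            fp = self._gens[family].GetCountFingerprint(mol)
            counts = {int(i): float(c) for i, c in fp.GetNonzeroElements().items()}
            width = self.width
        elif family == "avalon":
            fp = pyAvalonTools.GetAvalonCountFP(mol, nBits=self.width)
            counts = {int(i): float(c) for i, c in fp.GetNonzeroElements().items()}
            width = self.width
        else:  # maccs: 167 keys, binary counts
            bv = MACCSkeys.GenMACCSKeys(mol)
            counts = {int(i): 1.0 for i in bv.GetOnBits()}
            width = 167
        out = CountFingerprint(counts=counts, family=family, width=width)
        self._cache[key] = out
        return out


def mix_count_fingerprints(
    components: Mapping[str, CountFingerprint],
    multipliers: Mapping[str, float],
) -> CountFingerprint:
    """Copy-number-weighted sum of component count fingerprints.

    Drug multipliers may be fractional (drugs-per-chain is a continuous
    feed-derived quantity); monomer multipliers are the block lengths.
    """
    family = None
    width = None
    mixed: Dict[int, float] = {}
    for key, fp in components.items():
        if family is None:
            family, width = fp.family, fp.width
        elif fp.family != family or fp.width != width:
            raise ValueError(f"fingerprint family/width mismatch at component {key!r}")
        mult = float(multipliers.get(key, 0.0))
        if mult == 0.0:
            continue
        for idx, c in fp.counts.items():
            mixed[idx] = mixed.get(idx, 0.0) + mult * c
    if family is None:
        raise ValueError("no components to mix")
    return CountFingerprint(counts=mixed, family=family, width=width)
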