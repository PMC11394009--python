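"""Physicochemical descriptor backend and molar-fraction mixture weighting.

Each micellar component (capped monomer, terminus, drug) gets a vector of
2D/3D molecular descriptors; formulation-level features are the
molar-fraction-weighted sums ``DESC_MIX[d] = sum_i n_i * DESC_i[d]``.

The backend is built on RDKit and provides, besides RDKit's standard 2D
descriptor set:

* Kier-Hall molecular connectivity (Chi) indices for path, chain, cluster and
  path/cluster subgraphs up to order 7, with sigma (``d``) and valence
  (``dv``) vertex weighting — named in the mordred style (``Xp-7dv`` is the
  order-7 valence-weighted path index);
* Moreau-Broto autocorrelations ``ATS``/``ATSC`` over atomic number, mass,
  van der Waals volume and Gasteiger charge;
* 3D-MoRSE scattering descriptors (``Mor01`` .. ``Mor32`` per weighting) from
  a seeded ETKDG conformer relaxed with MMFF94s;
* the spectral mean absolute deviation of the detour (longest-path) matrix
  (``SpMAD_Dt``);
* an ESOL-style group-contribution aqueous solubility estimate (``LogS``)
  plus rotatable-bond counts (``nRot``, ``RotRatio``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import networkx as nx
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, rdMolDescriptors

__all__ = [
    "DescriptorVector",
    "RDKitDescriptorBackend",
    "ConfigurationError",
    "chi_indices",
    "mix_descriptors",
    "submixture",
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class DescriptorVector:
    """Named numeric descriptors with a provenance tag for the engine config."""

    values: Dict[str, float]
    backend_id: str

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Kier-Hall connectivity (Chi) indices

_PT = Chem.GetPeriodicTable()


def _sigma_delta(atom: Chem.Atom) -> float:
    return float(atom.GetDegree())


def _valence_delta(atom: Chem.Atom) -> float:
    z = atom.GetAtomicNum()
    zv = _PT.GetNOuterElecs(z)
    h = atom.GetTotalNumHs()
    if z <= 10:
        return float(zv - h)
    return (zv - h) / (z - zv - 1.0)


def _classify_subgraph(n_atoms: int, n_edges: int, degrees: Sequence[int]) -> str:
    if n_edges - n_atoms + 1 >= 1:
        return "ch"  # contains a ring -> chain type
    if max(degrees) <= 2:
        return "p"
    if 2 in degrees:
        return "pc"
    return "c"


def chi_indices(mol: Chem.Mol, max_order: int = 7) -> Dict[str, float]:
    """Chi connectivity indices, mordred-style names (Xp-3dv, Xch-6d, ...).

    Sum over connected subgraphs of each Kier-Hall type of
    ``prod(delta_i) ** -0.5`` over the atoms of the subgraph; ``d`` uses the
    sigma-electron (vertex degree) delta, ``dv`` the valence-electron delta.
    """
    sigma = [_sigma_delta(a) for a in mol.GetAtoms()]
    valence = [_valence_delta(a) for a in mol.GetAtoms()]

    out: Dict[str, float] = {}
    for kind, orders in (("p", range(0, max_order + 1)), ("ch", range(3, max_order + 1)),
                         ("c", range(3, 7)), ("pc", range(4, 7))):
        for n in orders:
            out[f"X{kind}-{n}d"] = 0.0
            out[f"X{kind}-{n}dv"] = 0.0

    def weight(atom_ids: Iterable[int], deltas: List[float]) -> float:
        prod = 1.0
        for i in atom_ids:
            d = deltas[i]
            if d <= 0:
                return 0.0
            prod *= d
        return prod ** -0.5

    # order 0: atoms
    for i in range(mol.GetNumAtoms()):
        if sigma[i] > 0:
            out["Xp-0d"] += sigma[i] ** -0.5
        if valence[i] > 0:
            out["Xp-0dv"] += valence[i] ** -0.5

    for n in range(1, max_order + 1):
        for bond_ids in Chem.FindAllSubgraphsOfLengthN(mol, n):
            atoms: Dict[int, int] = {}
            for bidx in bond_ids:
                b = mol.GetBondWithIdx(bidx)
                for a in (b.GetBeginAtomIdx(), b.GetEndAtomIdx()):
                    atoms[a] = atoms.get(a, 0) + 1
            kind = _classify_subgraph(len(atoms), len(bond_ids), list(atoms.values()))
            key = f"X{kind}-{n}"
            if f"{key}d" not in out:
                continue
            out[f"{key}d"] += weight(atoms.keys(), sigma)
            out[f"{key}dv"] += weight(atoms.keys(), valence)
    return out


# ---------------------------------------------------------------------------
# Moreau-Broto autocorrelation

_ATS_MAX_LAG = 7


def _atom_properties(mol: Chem.Mol) -> Dict[str, np.ndarray]:
    zs = np.array([a.GetAtomicNum() for a in mol.GetAtoms()], dtype=float)
    ms = np.array([a.GetMass() for a in mol.GetAtoms()], dtype=float)
    vdw = np.array([_PT.GetRvdw(a.GetAtomicNum()) ** 3 * 4.0 / 3.0 * math.pi
                    for a in mol.GetAtoms()])
    work = Chem.Mol(mol)
    AllChem.ComputeGasteigerCharges(work)
    chg = np.array([float(a.GetProp("_GasteigerCharge")) for a in work.GetAtoms()])
    if not np.all(np.isfinite(chg)):
        chg = np.full(len(zs), np.nan)
    return {"Z": zs, "m": ms, "v": vdw, "c": chg}


def autocorrelations(mol: Chem.Mol) -> Dict[str, float]:
    """ATS / centered ATSC Moreau-Broto autocorrelations, lags 0..7."""
    n = mol.GetNumAtoms()
    out: Dict[str, float] = {}
    props = _atom_properties(mol)
    dmat = Chem.GetDistanceMatrix(mol) if n > 1 else np.zeros((1, 1))
    for tag, w in props.items():
        for centered in (False, True):
            ww = w - np.nanmean(w) if centered else w
            prefix = "ATSC" if centered else "ATS"
            for lag in range(_ATS_MAX_LAG + 1):
                if lag == 0:
                    val = float(np.sum(ww * ww))
                else:
                    mask = dmat == lag
                    val = float(np.sum(np.outer(ww, ww)[mask]) / 2.0)
                out[f"{prefix}{lag}{tag}"] = val
    return out


# ---------------------------------------------------------------------------
# detour matrix

def _block_detour(sub: nx.Graph) -> Dict[Tuple[int, int], int]:
    """Longest simple path lengths between all vertex pairs of one
    biconnected block (exhaustive DFS; molecular blocks are small)."""
    nodes = list(sub.nodes)
    best: Dict[Tuple[int, int], int] = {}

    def dfs(start: int, current: int, visited: set, length: int):
        key = (start, current) if start <= current else (current, start)
        if length > best.get(key, 0):
            best[key] = length
        for nbr in sub.neighbors(current):
            if nbr not in visited:
                visited.add(nbr)
                dfs(start, nbr, visited, length + 1)
                visited.remove(nbr)

    for s in nodes:
        dfs(s, s, {s}, 0)
    return best


def detour_matrix(mol: Chem.Mol) -> np.ndarray:
    """Detour (maximum path length) matrix via biconnected-block composition.

    The longest simple path between two atoms decomposes additively over the
    biconnected blocks along the (unique) block-cut-tree route between them.
    """
    n = mol.GetNumAtoms()
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for b in mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    dt = np.zeros((n, n))
    blocks = [frozenset(b) for b in nx.biconnected_components(g)]
    cuts = set(nx.articulation_points(g))
    block_of: Dict[int, List[int]] = {}
    for i, b in enumerate(blocks):
        for v in b:
            block_of.setdefault(v, []).append(i)
    block_detours = [_block_detour(g.subgraph(b)) for b in blocks]

    # block-cut tree
    bct = nx.Graph()
    for i, b in enumerate(blocks):
        bct.add_node(("b", i))
        for v in b & cuts:
            bct.add_edge(("b", i), ("c", v))

    def home(v: int):
        return ("c", v) if v in cuts else ("b", block_of[v][0])

    def block_dist(bi: int, u: int, v: int) -> int:
        if u == v:
            return 0
        key = (u, v) if u <= v else (v, u)
        return block_detours[bi][key]

    for u, v in combinations(range(n), 2):
        if not nx.has_path(g, u, v):
            continue  # disconnected: leave 0 (components handled separately)
        common = set(block_of[u]) & set(block_of[v])
        if common:
            dt[u, v] = dt[v, u] = block_dist(next(iter(common)), u, v)
            continue
        tree_path = nx.shortest_path(bct, home(u), home(v))
        cur, total = u, 0
        for node in tree_path:
            if node[0] != "b":
                continue
            bi = node[1]
            idx = tree_path.index(node)
            nxt = v if idx + 1 >= len(tree_path) else tree_path[idx + 1][1]
            total += block_dist(bi, cur, nxt)
            cur = nxt
        dt[u, v] = dt[v, u] = total
    return dt


def spmad_detour(mol: Chem.Mol) -> float:
    """Spectral mean absolute deviation of the detour matrix eigenvalues."""
    if mol.GetNumAtoms() < 2:
        return 0.0
    eig = np.linalg.eigvalsh(detour_matrix(mol))
    return float(np.mean(np.abs(eig - eig.mean())))


# ---------------------------------------------------------------------------
# solubility / flexibility

def esol_logs(mol: Chem.Mol) -> float:
    """ESOL estimate of log10 aqueous solubility (mol/L) from cLogP, MW,
    rotatable bonds and aromatic proportion."""
    heavy = mol.GetNumHeavyAtoms()
    ap = sum(a.GetIsAromatic() for a in mol.GetAtoms()) / heavy if heavy else 0.0
    return (0.16
            - 0.63 * Crippen.MolLogP(mol)
            - 0.0062 * Descriptors.MolWt(mol)
            + 0.066 * rdMolDescriptors.CalcNumRotatableBonds(mol)
            - 0.74 * ap)


# ---------------------------------------------------------------------------
# 3D

_MORSE_SUFFIXES = ("", "m", "v", "se", "p", "i", "s")


def embed_conformer(mol: Chem.Mol, seed: int = 1853) -> Optional[Chem.Mol]:
    """Deterministic single conformer: ETKDGv3 embed + MMFF94s relaxation."""
    m3 = Chem.AddHs(Chem.Mol(mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(m3, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(m3, params) != 0:
            return None
    try:
        AllChem.MMFFOptimizeMolecule(m3, mmffVariant="MMFF94s", maxIters=2000)
    except Exception:
        pass
    return m3


def morse_descriptors(mol3d: Chem.Mol) -> Dict[str, float]:
    vals = rdMolDescriptors.CalcMORSE(mol3d)
    per = 32
    out = {}
    for bi, suffix in enumerate(_MORSE_SUFFIXES):
        block = vals[bi * per:(bi + 1) * per]
        for j, v in enumerate(block, start=1):
            out[f"Mor{j:02d}{suffix}"] = float(v)
    return out


# ---------------------------------------------------------------------------
# backend

class RDKitDescriptorBackend:
    """Deterministic descriptor engine for capped building blocks and drugs."""

    def __init__(self, include_3d: bool = True, conformer_seed: int = 1853):
        self.include_3d = include_3d
        self.conformer_seed = conformer_seed
        self._cache: Dict[str, DescriptorVector] = {}

    @property
    def backend_id(self) -> str:
        import rdkit
        return (f"rdkit-{rdkit.__version__};chi=kier-hall<=7;ats<=7;spmad-dt;esol;"
                f"3d={'etkdg3:seed%d+mmff94s' % self.conformer_seed if self.include_3d else 'off'}")

    def compute(self, structure: Union[str, Chem.Mol]) -> DescriptorVector:
        if isinstance(structure, Chem.Mol):
            mol = structure
        else:
            mol = Chem.MolFromSmiles(structure)
            if mol is None:
                raise ValueError(f"unparsable SMILES: {structure!r}")
        smiles = Chem.MolToSmiles(mol)
        if smiles in self._cache:
            return self._cache[smiles]

        values: Dict[str, float] = {}
        for name, val in Descriptors.CalcMolDescriptors(mol).items():
            try:
                values[name] = float(val)
            except (TypeError, ValueError):
                values[name] = float("nan")
        values.update(chi_indices(mol))
        values.update(autocorrelations(mol))
        values["SpMAD_Dt"] = spmad_detour(mol)
        values["LogS"] = esol_logs(mol)
        values["nRot"] = float(rdMolDescriptors.CalcNumRotatableBonds(mol))
        nbonds = mol.GetNumBonds()
        values["RotRatio"] = values["nRot"] / nbonds if nbonds else 0.0

        if self.include_3d:
            m3 = embed_conformer(mol, self.conformer_seed)
            if m3 is not None:
                values.update(morse_descriptors(m3))
            else:
                for bi, suffix in enumerate(_MORSE_SUFFIXES):
                    for j in range(1, 33):
                        values[f"Mor{j:02d}{suffix}"] = float("nan")

        vec = DescriptorVector(values=values, backend_id=self.backend_id)
        self._cache[smiles] = vec
        return vec


# ---------------------------------------------------------------------------
# mixture weighting (linear molar-fraction combination)

def mix_descriptors(
    components: Mapping[str, DescriptorVector],
    fractions: Mapping[str, float],
) -> DescriptorVector:
    """Molar-fraction-weighted mixture descriptors.

    ``DESC_MIX[d] = sum_i n_i * DESC_i[d]`` over the given components; all
    component vectors must share one descriptor name set.
    """
    if not components:
        raise ConfigurationError("no components to mix")
    names = None
    backend = None
    for key, vec in components.items():
        if names is None:
            names = set(vec.values)
            backend = vec.backend_id
        elif set(vec.values) != names:
            raise ConfigurationError(f"descriptor name set mismatch for component {key!r}")
    total = 0.0
    mixed = {n: 0.0 for n in names}  # type: ignore[arg-type]
    for key, vec in components.items():
        n_i = float(fractions.get(key, 0.0))
        total += n_i
        for name, val in vec.values.items():
            mixed[name] += n_i * val
    return DescriptorVector(values=mixed, backend_id=f"{backend};mix=linear;ntotal={total:.6g}")


def submixture(
    components: Mapping[str, DescriptorVector],
    fractions: Mapping[str, float],
    keys: Sequence[str],
) -> DescriptorVector:
    """Mixture over a component subset with renormalized molar fractions."""
    sub = {k: components[k] for k in keys if k in components}
    subfrac = {k: fractions.get(k, 0.0) for k in sub}
    z = sum(subfrac.values())
    if z <= 0:
        raise ConfigurationError(f"zero total fraction for sub-mixture {list(keys)!r}")
    return mix_descriptors(sub, {k: v / z for k, v in subfrac.items()})
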