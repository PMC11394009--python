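"""Simplex (tetraatomic fragment) descriptors for polymer-drug mixtures.

Every 4-atom subset of a molecule is a *simplex*, keyed by the multiset of
its atom labels and the isomorphism class of its induced bond topology.
Connected subsets are *bound* simplexes; disconnected ones are *unbound*
(their key is the multiset of connected fragments).  Atom labels come from
binned atomic properties (Crippen logp/mr by default) or from the element +
hybridization state (a benzene carbon is ``6>sp2``).

For a formulation, simplexes of single molecules (SiRMS-S; the polymer is
represented by its T1-A-B-A-T2 pseudotrimer) are weighted by the component's
molar fraction.  Mixture simplexes (SiRMS-M) combine 1-3-atom connected
fragments from 2-3 distinct components (up to three unbound fragments in
total) and are weighted by twice the smallest molar fraction among the
involved components.

Single-molecule enumeration is exact without visiting all C(n,4) subsets:
connected 2/3/4-subgraphs are enumerated directly, the (3+1), (2+2) and
(2+1+1) unbound patterns are counted with adjacency-complement tallies, and
the fully scattered (1+1+1+1) pattern is obtained as the label-multiset
remainder of C(n,4) — so total counts are conserved by construction.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

__all__ = [
    "PropertyBinScheme",
    "SimplexVector",
    "MixtureComponent",
    "DEFAULT_BIN_SCHEMES",
    "bin_atomic_property",
    "label_atoms",
    "enumerate_simplexes",
    "mixture_simplexes",
    "sirms_feature_dict",
]

_LABELS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class PropertyBinScheme:
    """Three ascending cutpoints mapping a numeric atomic property to A-D.

    Bins use inclusive upper bounds: for logp cutpoints (-0.5, 0, 0.5),
    A <= -0.5 < B <= 0 < C <= 0.5 < D.
    """

    property_id: str
    cutpoints: Tuple[float, float, float]

    def __post_init__(self):
        c = self.cutpoints
        if not (c[0] < c[1] < c[2]):
            raise ValueError("cutpoints must be strictly ascending")


DEFAULT_BIN_SCHEMES: Dict[str, PropertyBinScheme] = {
    "logp": PropertyBinScheme("logp", (-0.5, 0.0, 0.5)),
    "mr": PropertyBinScheme("mr", (1.5, 3.0, 8.0)),
    # external-backend schemes (per-atom values must be supplied by caller)
    "eeq": PropertyBinScheme("eeq", (-0.28, 0.0, 0.28)),
    "alp": PropertyBinScheme("alp", (6.0, 9.0, 12.0)),
    "sa": PropertyBinScheme("sa", (0.5, 0.75, 1.0)),
    "sdx": PropertyBinScheme("sdx", (0.5, 0.75, 1.0)),
    "sdc": PropertyBinScheme("sdc", (0.5, 0.75, 1.0)),
}

DEFAULT_SCHEME_IDS = ("atom_hyb", "logp", "mr")


def bin_atomic_property(value: float, scheme: PropertyBinScheme) -> str:
    if math.isnan(value):
        raise ValueError("cannot bin NaN atomic property")
    for cut, label in zip(scheme.cutpoints, _LABELS):
        if value <= cut:
            return label
    return _LABELS[-1]


_HYB_NAMES = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
    Chem.HybridizationType.SP3D: "sp3d",
    Chem.HybridizationType.SP3D2: "sp3d2",
    Chem.HybridizationType.S: "s",
}


def label_atoms(
    mol: Chem.Mol,
    scheme_id: str,
    external_values: Optional[Sequence[float]] = None,
) -> List[str]:
    """One label per atom under the requested scheme.

    ``atom_hyb`` labels are categorical (``6>sp2``); numeric schemes bin
    Crippen atomic logp/mr contributions, or externally supplied per-atom
    values for the eeq/alp/sa/sdx/sdc schemes.
    """
    if scheme_id == "atom_hyb":
        return [
            f"{a.GetAtomicNum()}>{_HYB_NAMES.get(a.GetHybridization(), 'other')}"
            for a in mol.GetAtoms()
        ]
    scheme = DEFAULT_BIN_SCHEMES.get(scheme_id)
    if scheme is None:
        raise ValueError(f"unknown labeling scheme {scheme_id!r}")
    if scheme_id in ("logp", "mr"):
        contribs = rdMolDescriptors._CalcCrippenContribs(mol)
        idx = 0 if scheme_id == "logp" else 1
        values = [c[idx] for c in contribs]
    else:
        if external_values is None:
            raise ValueError(
                f"scheme {scheme_id!r} needs externally computed per-atom values"
            )
        values = list(external_values)
    if len(values) != mol.GetNumAtoms():
        raise ValueError("one property value per atom required")
    return [bin_atomic_property(v, scheme) for v in values]


@dataclass
class SimplexVector:
    """Sparse map from simplex key string to (weighted) count."""

    counts: Dict[str, float]
    variant: str = "noH"  # "H" when explicit hydrogens were enumerated

    def __post_init__(self):
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("simplex counts must be nonnegative")

    @property
    def total(self) -> float:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# canonical fragment / simplex keys

def _frag1(label: str) -> str:
    return f"({label})"


def _frag2(l1: str, l2: str) -> str:
    a, b = sorted((l1, l2))
    return f"({a}~{b})"


def _frag3_path(mid: str, ends: Sequence[str]) -> str:
    a, b = sorted(ends)
    return f"({a}-{mid}-{b})"


def _frag3_tri(labels: Sequence[str]) -> str:
    return "(t:" + ",".join(sorted(labels)) + ")"


def _canon_connected(labels: Sequence[str], edges: Iterable[Tuple[int, int]]) -> str:
    """Canonical string for a connected labeled graph on <= 4 vertices."""
    n = len(labels)
    edges = [tuple(sorted(e)) for e in edges]
    if n == 1:
        return _frag1(labels[0])
    if n == 2:
        return _frag2(labels[0], labels[1])
    if n == 3:
        if len(edges) == 3:
            return _frag3_tri(labels)
        deg = Counter()
        for i, j in edges:
            deg[i] += 1
            deg[j] += 1
        mid = next(v for v in range(3) if deg[v] == 2)
        return _frag3_path(labels[mid], [labels[v] for v in range(3) if v != mid])
    best = None
    for perm in permutations(range(n)):
        inv = {orig: new for new, orig in enumerate(perm)}
        lab = tuple(labels[orig] for orig in perm)
        e = tuple(sorted(tuple(sorted((inv[i], inv[j]))) for i, j in edges))
        cand = (lab, e)
        if best is None or cand < best:
            best = cand
    lab, e = best  # type: ignore[misc]
    estr = ".".join(f"{i}{j}" for i, j in e)
    return "[" + ",".join(lab) + ";" + estr + "]"


def _unbound_key(fragments: Sequence[str]) -> str:
    return "+".join(sorted(fragments))


# ---------------------------------------------------------------------------
# single-molecule enumeration

def _adjacency(mol: Chem.Mol) -> List[set]:
    adj = [set() for _ in range(mol.GetNumAtoms())]
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        adj[i].add(j)
        adj[j].add(i)
    return adj


def _connected_subsets(adj: List[set], size: int) -> List[frozenset]:
    """All vertex subsets of the given size inducing a connected subgraph."""
    frontier = {frozenset((v,)) for v in range(len(adj))}
    for _ in range(size - 1):
        grown = set()
        for s in frontier:
            for v in s:
                for u in adj[v]:
                    if u not in s:
                        grown.add(s | {u})
        frontier = grown
    return list(frontier)


def _induced_edges(subset: Iterable[int], adj: List[set]) -> List[Tuple[int, int]]:
    nodes = list(subset)
    return [(i, j) for i, j in combinations(nodes, 2) if j in adj[i]]


def _closed_neighborhood(nodes: Iterable[int], adj: List[set]) -> set:
    out = set(nodes)
    for v in list(nodes):
        out |= adj[v]
    return out


def enumerate_simplexes(
    mol: Chem.Mol,
    labels: Sequence[str],
    explicit_h: bool = False,
    connected_only: bool = False,
) -> SimplexVector:
    """Count every 4-atom subset of one molecule, keyed by labeled topology.

    Returns an empty vector for molecules with fewer than 4 atoms.  The sum
    of all counts equals C(n_atoms, 4).  ``connected_only=True`` restricts to
    bound simplexes (an ablation switch; disconnected intramolecular subsets
    are counted by default).
    """
    if len(labels) != mol.GetNumAtoms():
        raise ValueError("one label per atom required")
    n = mol.GetNumAtoms()
    counts: Dict[str, float] = {}
    variant = "H" if explicit_h else "noH"
    if n < 4:
        return SimplexVector(counts=counts, variant=variant)

    adj = _adjacency(mol)
    label_tally = Counter(labels)

    def add(key: str, c: float):
        if c:
            counts[key] = counts.get(key, 0.0) + c

    by_multiset: Dict[Tuple[str, ...], float] = {}

    def add_with_multiset(key: str, multiset: Tuple[str, ...], c: float):
        add(key, c)
        if c:
            by_multiset[multiset] = by_multiset.get(multiset, 0.0) + c

    # bound simplexes: connected induced 4-subsets
    for sub in _connected_subsets(adj, 4):
        nodes = sorted(sub)
        key = _canon_connected([labels[v] for v in nodes],
                               [(nodes.index(i), nodes.index(j))
                                for i, j in _induced_edges(nodes, adj)])
        add_with_multiset(key, tuple(sorted(labels[v] for v in nodes)), 1.0)
    if connected_only:
        return SimplexVector(counts=counts, variant=variant)

    # 3+1: connected triple + one non-adjacent atom
    triples = _connected_subsets(adj, 3)
    frag3_cache: Dict[frozenset, str] = {}
    for sub in triples:
        nodes = sorted(sub)
        e = _induced_edges(nodes, adj)
        key3 = _canon_connected([labels[v] for v in nodes],
                                [(nodes.index(i), nodes.index(j)) for i, j in e])
        frag3_cache[sub] = key3
        forbidden = Counter(labels[v] for v in _closed_neighborhood(sub, adj))
        for lab, tot in label_tally.items():
            free = tot - forbidden.get(lab, 0)
            if free > 0:
                add_with_multiset(
                    _unbound_key([key3, _frag1(lab)]),
                    tuple(sorted([labels[v] for v in nodes] + [lab])),
                    float(free),
                )

    # edge bookkeeping for 2+2 and 2+1+1
    bonds = [tuple(sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))) for b in mol.GetBonds()]

    def edge_far(e: Tuple[int, int], f: Tuple[int, int]) -> bool:
        """disjoint and non-adjacent edge pair"""
        es, fs = set(e), set(f)
        if es & fs:
            return False
        return not any(v in adj[u] for u in es for v in fs)

    # 2+2
    for (e, f) in combinations(bonds, 2):
        if edge_far(e, f):
            key = _unbound_key([_frag2(labels[e[0]], labels[e[1]]),
                                _frag2(labels[f[0]], labels[f[1]])])
            add_with_multiset(key, tuple(sorted(labels[v] for v in (*e, *f))), 1.0)

    # 2+1+1: edge + two mutually non-adjacent atoms outside its neighborhood
    for e in bonds:
        hood = _closed_neighborhood(e, adj)
        far_atoms = [v for v in range(n) if v not in hood]
        far_tally = Counter(labels[v] for v in far_atoms)
        pair_tally: Dict[Tuple[str, str], float] = {}
        for la, lb in combinations(sorted(far_tally), 2):
            pair_tally[(la, lb)] = float(far_tally[la] * far_tally[lb])
        for la in far_tally:
            cnt = far_tally[la]
            pair_tally[(la, la)] = cnt * (cnt - 1) / 2.0
        for f in bonds:
            if edge_far(e, f):
                lf = tuple(sorted((labels[f[0]], labels[f[1]])))
                pair_tally[lf] -= 1.0
        ekey = _frag2(labels[e[0]], labels[e[1]])
        for (la, lb), cnt in pair_tally.items():
            if cnt > 0:
                key = _unbound_key([ekey, _frag1(la), _frag1(lb)])
                add_with_multiset(
                    key, tuple(sorted((labels[e[0]], labels[e[1]], la, lb))), cnt)

    # 1+1+1+1: remainder of C(n, 4) per label multiset
    for multiset in _multisets(sorted(label_tally), 4):
        total = _count_subsets(label_tally, multiset)
        rest = total - by_multiset.get(multiset, 0.0)
        if rest > 0.5:  # counts are integers; guard float fuzz
            add(_unbound_key([_frag1(l) for l in multiset]), round(rest))
    return SimplexVector(counts=counts, variant=variant)


def _multisets(labels: Sequence[str], k: int) -> List[Tuple[str, ...]]:
    from itertools import combinations_with_replacement
    return list(combinations_with_replacement(labels, k))


def _count_subsets(tally: Counter, multiset: Tuple[str, ...]) -> float:
    mult = Counter(multiset)
    total = 1.0
    for lab, m in mult.items():
        total *= math.comb(tally.get(lab, 0), m)
    return total


# ---------------------------------------------------------------------------
# mixtures

@dataclass
class MixtureComponent:
    """A labeled structure with its mixture origin and molar fraction."""

    origin: str  # "polymer" | "drug1" | "drug2"
    mol: Chem.Mol
    labels: Sequence[str]
    fraction: float

    def __post_init__(self):
        if self.fraction < 0:
            raise ValueError("molar fraction must be nonnegative")


def _fragment_tallies(comp: MixtureComponent):
    """Connected fragment counts of sizes 1-3 and disjoint-pair tallies."""
    mol, labels = comp.mol, comp.labels
    adj = _adjacency(mol)
    n = mol.GetNumAtoms()
    singles = Counter(_frag1(l) for l in labels)
    bonds = [tuple(sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))) for b in mol.GetBonds()]
    pairs = Counter(_frag2(labels[i], labels[j]) for i, j in bonds)
    triples: Counter = Counter()
    for sub in _connected_subsets(adj, 3):
        nodes = sorted(sub)
        e = _induced_edges(nodes, adj)
        triples[_canon_connected([labels[v] for v in nodes],
                                 [(nodes.index(i), nodes.index(j)) for i, j in e])] += 1

    # unordered pairs of two mutually non-adjacent single atoms
    tally = Counter(labels)
    pair11: Counter = Counter()
    for la, lb in combinations(sorted(tally), 2):
        pair11[_unbound_key([_frag1(la), _frag1(lb)])] = tally[la] * tally[lb]
    for la in tally:
        pair11[_unbound_key([_frag1(la), _frag1(la)])] = tally[la] * (tally[la] - 1) // 2
    for i, j in bonds:
        pair11[_unbound_key([_frag1(labels[i]), _frag1(labels[j])])] -= 1
    pair11 = Counter({k: v for k, v in pair11.items() if v > 0})

    # (edge, far atom) pairs
    pair21: Counter = Counter()
    for e in bonds:
        hood = _closed_neighborhood(e, adj)
        ekey = _frag2(labels[e[0]], labels[e[1]])
        for v in range(n):
            if v not in hood:
                pair21[_unbound_key([ekey, _frag1(labels[v])])] += 1
    return {"1": singles, "2": pairs, "3": triples, "11": pair11, "21": pair21}


def mixture_simplexes(
    components: Sequence[MixtureComponent],
    max_fragments: int = 3,
) -> SimplexVector:
    """SiRMS-S and SiRMS-M weighted simplex counts for a mixture.

    Single-molecule simplexes are weighted by the component's molar fraction;
    cross-component simplexes (2-3 distinct origins, at most ``max_fragments``
    unbound fragments) by twice the smallest involved molar fraction.  Keys
    carry the origin signature (``@polymer``/``@drug1``/...; SiRMS-S keys are
    prefixed with their single origin).
    """
    if len(components) > 3:
        raise ValueError("at most three mixture components supported")
    if len({c.origin for c in components}) != len(components):
        raise ValueError("component origins must be distinct")
    counts: Dict[str, float] = {}

    def add(key: str, c: float):
        if c:
            counts[key] = counts.get(key, 0.0) + c

    variant = "noH"
    # SiRMS-S
    for comp in components:
        single = enumerate_simplexes(comp.mol, comp.labels)
        variant = single.variant
        for key, c in single.counts.items():
            add(f"S@{comp.origin}:{key}", comp.fraction * c)

    tallies = {c.origin: _fragment_tallies(c) for c in components}
    fractions = {c.origin: c.fraction for c in components}

    def weight(origins: Iterable[str]) -> float:
        return 2.0 * min(fractions[o] for o in set(origins))

    def emit(parts: List[Tuple[str, str]], count: float):
        """parts: list of (origin, fragment-or-multifragment key)"""
        frag_strs = []
        for origin, key in parts:
            for frag in key.split("+"):
                frag_strs.append(f"{frag}@{origin}")
        origins = [o for o, _ in parts]
        add("M:" + _unbound_key(frag_strs), count * weight(origins))

    # two-component partitions: 3+1, 2+2, and three-fragment 2+1+1 via (21|11)+(...)
    for c1, c2 in permutations(components, 2):
        t1, t2 = tallies[c1.origin], tallies[c2.origin]
        # 3 (from c1) + 1 (from c2)
        for k3, n3 in t1["3"].items():
            for k1, n1 in t2["1"].items():
                emit([(c1.origin, k3), (c2.origin, k1)], n3 * n1)
        if max_fragments >= 3:
            # {2,1} from c1 + 1 from c2 ; {1,1} from c1 + 2 from c2
            for k21, n21 in t1["21"].items():
                for k1, n1 in t2["1"].items():
                    emit([(c1.origin, k21), (c2.origin, k1)], n21 * n1)
            for k11, n11 in t1["11"].items():
                for k2, n2 in t2["2"].items():
                    emit([(c1.origin, k11), (c2.origin, k2)], n11 * n2)
    for c1, c2 in combinations(components, 2):
        t1, t2 = tallies[c1.origin], tallies[c2.origin]
        for k2a, n2a in t1["2"].items():
            for k2b, n2b in t2["2"].items():
                emit([(c1.origin, k2a), (c2.origin, k2b)], n2a * n2b)

    # three-component 2+1+1
    if len(components) == 3 and max_fragments >= 3:
        for c_pair in permutations(components, 3):
            c1, c2, c3 = c_pair
            if c2.origin > c3.origin:
                continue  # unordered single-atom contributors
            t1, t2, t3 = tallies[c1.origin], tallies[c2.origin], tallies[c3.origin]
            for k2, n2 in t1["2"].items():
                for k1a, n1a in t2["1"].items():
                    for k1b, n1b in t3["1"].items():
                        emit([(c1.origin, k2), (c2.origin, k1a), (c3.origin, k1b)],
                             n2 * n1a * n1b)
    return SimplexVector(counts=counts, variant=variant)


def sirms_feature_dict(
    polymer_pseudotrimer: Chem.Mol,
    drugs: Sequence[Chem.Mol],
    fractions: Mapping[str, float],
    scheme_ids: Sequence[str] = DEFAULT_SCHEME_IDS,
    explicit_h: bool = False,
) -> Dict[str, float]:
    """Formulation-level simplex features over the requested label schemes.

    ``fractions`` maps "polymer"/"drug1"/"drug2" to molar fractions (the
    polymer fraction aggregates monomers and termini).  Returns a flat
    feature dict named ``SIRMS[<scheme>|<variant>]:<key>``.
    """
    out: Dict[str, float] = {}
    structures: List[Tuple[str, Chem.Mol]] = [("polymer", polymer_pseudotrimer)]
    structures += [(f"drug{i+1}", m) for i, m in enumerate(drugs)]
    variant = "H" if explicit_h else "noH"
    for scheme in scheme_ids:
        comps = []
        for origin, mol in structures:
            m = Chem.AddHs(mol) if explicit_h else mol
            comps.append(MixtureComponent(
                origin=origin,
                mol=m,
                labels=label_atoms(m, scheme),
                fraction=float(fractions.get(origin, 0.0)),
            ))
        vec = mixture_simplexes(comps)
        for key, c in vec.counts.items():
            out[f"SIRMS[{scheme}|{variant}]:{key}"] = c
    return out
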