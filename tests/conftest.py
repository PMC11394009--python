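import math
from collections import Counter
from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from rdkit import Chem

import poxload as px


@pytest.fixture(scope="session")
def registry():
    return px.load_monomer_registry()


@pytest.fixture(scope="session")
def drug_pool():
    return px.load_drug_pool()


@pytest.fixture(scope="session")
def small_table():
    """120-row synthetic formulation table (default study conditions)."""
    return px.generate_formulation_dataset(
        px.GeneratorConfig(n_formulations=120, seed=11))


@pytest.fixture(scope="session")
def factory_2d():
    """Feature factory without 3D descriptors (fast subsets for tests)."""
    from poxload.mixtures import FeatureFactory
    return FeatureFactory(include_3d=False)


def brute_force_simplexes(mol: Chem.Mol, labels):
    """Independent O(C(n,4)) enumeration of all 4-atom subset patterns."""
    from poxload.sirms import _canon_connected, _unbound_key

    adj = [set() for _ in range(mol.GetNumAtoms())]
    for b in mol.GetBonds():
        adj[b.GetBeginAtomIdx()].add(b.GetEndAtomIdx())
        adj[b.GetEndAtomIdx()].add(b.GetBeginAtomIdx())
    out = Counter()
    for sub in combinations(range(mol.GetNumAtoms()), 4):
        g = nx.Graph()
        g.add_nodes_from(sub)
        for i, j in combinations(sub, 2):
            if j in adj[i]:
                g.add_edge(i, j)
        frags = []
        for comp in nx.connected_components(g):
            nodes = sorted(comp)
            edges = [(nodes.index(i), nodes.index(j)) for i, j in g.edges()
                     if i in comp and j in comp]
            frags.append(_canon_connected([labels[v] for v in nodes], edges))
        out[_unbound_key(frags)] += 1
    return out
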