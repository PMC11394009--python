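"""Descriptor backend: Chi indices, autocorrelations, detour matrix, mixing."""

import itertools
import math

import numpy as np
import pytest
from rdkit import Chem

import poxload as px
from poxload.descriptors import (ConfigurationError, DescriptorVector,
                                 autocorrelations, detour_matrix, esol_logs,
                                 spmad_detour, _valence_delta)


def brute_chi_path(mol, order, valence=True):
    """Independent path-chi: enumerate simple paths with networkx."""
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(mol.GetNumAtoms()))
    for b in mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    deltas = [(_valence_delta(a) if valence else a.GetDegree())
              for a in mol.GetAtoms()]
    if order == 0:
        return sum(d ** -0.5 for d in deltas if d > 0)
    total = 0.0
    seen = set()
    for u in g.nodes:
        stack = [(u, [u])]
        while stack:
            node, path = stack.pop()
            if len(path) == order + 1:
                key = frozenset(path)
                akey = tuple(path) if tuple(path) < tuple(reversed(path)) else tuple(reversed(path))
                if akey not in seen:
                    seen.add(akey)
                    prod = math.prod(deltas[v] for v in path)
                    if prod > 0:
                        total += prod ** -0.5
                continue
            for nbr in g.neighbors(node):
                if nbr not in path:
                    stack.append((nbr, path + [nbr]))
    return total


CHI_MOLS = ["CCO", "CC(C)CC", "c1ccccc1O", "CC(=O)Nc1ccc(O)cc1",
            "C1CCC2(CC1)CCCCC2"]


class TestChi:
    @pytest.mark.parametrize("smiles", CHI_MOLS)
    @pytest.mark.parametrize("order", [0, 1, 2, 3, 5, 7])
    def test_path_chi_matches_independent_enumeration(self, smiles, order):
        mol = Chem.MolFromSmiles(smiles)
        chis = px.chi_indices(mol)
        assert chis[f"Xp-{order}dv"] == pytest.approx(
            brute_chi_path(mol, order, valence=True), abs=1e-10)
        assert chis[f"Xp-{order}d"] == pytest.approx(
            brute_chi_path(mol, order, valence=False), abs=1e-10)

    def test_low_order_valence_chi_matches_rdkit(self):
        # RDKit implements Kier-Hall Chi0v/Chi1v directly
        from rdkit.Chem import GraphDescriptors
        for smiles in CHI_MOLS:
            mol = Chem.MolFromSmiles(smiles)
            chis = px.chi_indices(mol)
            assert chis["Xp-0dv"] == pytest.approx(GraphDescriptors.Chi0v(mol), abs=1e-8)
            assert chis["Xp-1dv"] == pytest.approx(GraphDescriptors.Chi1v(mol), abs=1e-8)

    def test_chain_chi_counts_rings(self):
        benzene = Chem.MolFromSmiles("c1ccccc1")
        chis = px.chi_indices(benzene)
        # exactly one 6-edge ring subgraph; all aromatic CH have delta_v = 3
        assert chis["Xch-6dv"] == pytest.approx(3.0 ** -3.0)
        assert chis["Xch-5dv"] == 0.0

    def test_structural_isomer_monomers_share_order7_path_chi(self, registry):
        # nBuOx and nPrOzi are isomeric repeat units; their capped molecules
        # contain one identical 7-bond path each
        chi_buox = px.chi_indices(registry["nBuOx"].capped_mol)["Xp-7dv"]
        chi_przi = px.chi_indices(registry["nPrOzi"].capped_mol)["Xp-7dv"]
        assert chi_buox == pytest.approx(chi_przi, abs=1e-12)
        assert chi_buox == pytest.approx(320.0 ** -0.5, abs=1e-12)


class TestDetour:
    def test_tree_detour_equals_topological_distance(self):
        mol = Chem.MolFromSmiles("CCC(C)CC")
        assert np.allclose(detour_matrix(mol), Chem.GetDistanceMatrix(mol))

    def test_benzene_detour_by_hand(self):
        mol = Chem.MolFromSmiles("c1ccccc1")
        dt = detour_matrix(mol)
        d = Chem.GetDistanceMatrix(mol)
        # in a 6-ring the longest path between atoms at shortest distance k
        # is 6 - k edges
        for i, j in itertools.combinations(range(6), 2):
            assert dt[i, j] == 6 - d[i, j]

    def test_fused_ring_plus_tail(self):
        # cyclopropane with a one-atom tail: detour(tail, opposite ring atom)
        mol = Chem.MolFromSmiles("CC1CC1")
        dt = detour_matrix(mol)
        # tail(0)-C1(1): 1; around the ring from 1 to 2/3 is 2 edges
        assert dt[0, 1] == 1 and dt[0, 2] == 3 and dt[1, 2] == 2
        assert spmad_detour(mol) > 0


class TestAutocorrelation:
    def test_ethane_by_hand(self):
        mol = Chem.MolFromSmiles("CC")
        ats = autocorrelations(mol)
        assert ats["ATS0Z"] == pytest.approx(36.0 + 36.0)
        assert ats["ATS1Z"] == pytest.approx(36.0)
        assert ats["ATSC0Z"] == pytest.approx(0.0, abs=1e-12)  # centered, equal atoms

    def test_heteroatom_centering(self):
        mol = Chem.MolFromSmiles("CO")
        ats = autocorrelations(mol)
        # weights 6, 8 -> centered -1, +1 -> lag1 product = -1
        assert ats["ATSC1Z"] == pytest.approx(-1.0)


class TestBackend:
    def test_deterministic_across_instances(self):
        a = px.RDKitDescriptorBackend(include_3d=True, conformer_seed=7)
        b = px.RDKitDescriptorBackend(include_3d=True, conformer_seed=7)
        va = a.compute("CC(C)Cc1ccc(C(C)C(=O)O)cc1").values
        vb = b.compute("CC(C)Cc1ccc(C(C)C(=O)O)cc1").values
        assert set(va) == set(vb)
        for k in va:
            if not (isinstance(va[k], float) and math.isnan(va[k])):
                assert va[k] == vb[k], k

    def test_required_descriptor_families_present(self):
        backend = px.RDKitDescriptorBackend(include_3d=True, conformer_seed=1)
        vals = backend.compute("c1ccccc1CCO").values
        for name in ("Xp-7dv", "Xc-4dv", "ATS0Z", "ATSC1v", "Mor03p",
                     "SpMAD_Dt", "LogS", "nRot", "RotRatio"):
            assert name in vals

    def test_methane_has_no_rotatable_bonds(self):
        backend = px.RDKitDescriptorBackend(include_3d=False)
        assert backend.compute("C").values["nRot"] == 0.0


class TestMixing:
    def _vec(self, **kv):
        return DescriptorVector(values=dict(kv), backend_id="test")

    def test_identical_components_reproduce_vector(self):
        v = self._vec(a=2.0, b=-1.0)
        mixed = px.mix_descriptors({"x": v, "y": v, "z": v},
                                   {"x": 0.2, "y": 0.3, "z": 0.5})
        assert mixed.values == pytest.approx({"a": 2.0, "b": -1.0})

    def test_two_component_weighting(self):
        mixed = px.mix_descriptors(
            {"u": self._vec(d=1.0), "v": self._vec(d=3.0)},
            {"u": 0.75, "v": 0.25})
        assert mixed.values["d"] == pytest.approx(1.5)

    def test_zero_fraction_component_is_inert(self):
        with_z = px.mix_descriptors(
            {"u": self._vec(d=1.0), "v": self._vec(d=3.0), "w": self._vec(d=99.0)},
            {"u": 0.75, "v": 0.25, "w": 0.0})
        assert with_z.values["d"] == pytest.approx(1.5)

    def test_renormalization_linearity(self):
        comps = {"u": self._vec(d=1.0, e=5.0), "v": self._vec(d=3.0, e=-2.0)}
        sub = px.submixture(comps, {"u": 0.3, "v": 0.1}, ["u", "v"])
        direct = px.mix_descriptors(comps, {"u": 0.75, "v": 0.25})
        assert sub.values == pytest.approx(direct.values)

    def test_name_mismatch_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            px.mix_descriptors({"u": self._vec(d=1.0), "v": self._vec(e=1.0)},
                               {"u": 0.5, "v": 0.5})


class TestFingerprints:
    def test_single_component_scaling(self):
        fp = px.CountFingerprint(counts={3: 2.0, 9: 1.0}, family="ecfp4", width=16)
        mixed = px.mix_count_fingerprints({"A": fp}, {"A": 35.0})
        assert mixed.counts == {3: 70.0, 9: 35.0}

    def test_disjoint_components_union(self):
        a = px.CountFingerprint(counts={1: 1.0}, family="rdk5", width=8)
        b = px.CountFingerprint(counts={5: 2.0}, family="rdk5", width=8)
        mixed = px.mix_count_fingerprints({"a": a, "b": b}, {"a": 2.0, "b": 0.5})
        assert mixed.counts == {1: 2.0, 5: 1.0}

    def test_permutation_invariance(self):
        a = px.CountFingerprint(counts={1: 1.0, 2: 2.0}, family="ecfp6", width=8)
        b = px.CountFingerprint(counts={2: 3.0}, family="ecfp6", width=8)
        m1 = px.mix_count_fingerprints({"a": a, "b": b}, {"a": 1.5, "b": 2.0})
        m2 = px.mix_count_fingerprints({"b": b, "a": a}, {"b": 2.0, "a": 1.5})
        assert m1.counts == m2.counts

    def test_family_mismatch_rejected(self):
        a = px.CountFingerprint(counts={1: 1.0}, family="ecfp4", width=8)
        b = px.CountFingerprint(counts={1: 1.0}, family="rdk5", width=8)
        with pytest.raises(ValueError):
            px.mix_count_fingerprints({"a": a, "b": b}, {"a": 1.0, "b": 1.0})

    def test_fractional_drug_multiplier_allowed(self):
        a = px.CountFingerprint(counts={4: 3.0}, family="ecfp4", width=8)
        mixed = px.mix_count_fingerprints({"drug1": a}, {"drug1": 2.34})
        assert mixed.counts[4] == pytest.approx(7.02)

    def test_backend_counts_are_counts(self, drug_pool):
        backend = px.FingerprintBackend(width=2048)
        fp = backend.compute(drug_pool["ibuprofen"], "ecfp4")
        assert fp.width == 2048
        assert all(c > 0 and c == int(c) for c in fp.counts.values())
        maccs = backend.compute(drug_pool["ibuprofen"], "maccs")
        assert maccs.width == 167
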