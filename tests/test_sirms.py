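"""Simplex descriptors: binning, labeling, enumeration, mixture weighting."""

import math

import pytest
from rdkit import Chem

import poxload as px
from poxload.sirms import (DEFAULT_BIN_SCHEMES, MixtureComponent,
                           enumerate_simplexes, label_atoms, mixture_simplexes)
from conftest import brute_force_simplexes


class TestBinning:
    @pytest.mark.parametrize("value,expected", [
        (-0.7, "A"), (-0.5, "A"), (-0.2, "B"), (0.0, "B"),
        (0.3, "C"), (0.5, "C"), (0.6, "D")])
    def test_logp_boundaries_inclusive_upper(self, value, expected):
        assert px.bin_atomic_property(value, DEFAULT_BIN_SCHEMES["logp"]) == expected

    def test_eeq_zero_is_b(self):
        assert px.bin_atomic_property(0.0, DEFAULT_BIN_SCHEMES["eeq"]) == "B"

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            px.bin_atomic_property(float("nan"), DEFAULT_BIN_SCHEMES["logp"])

    def test_cutpoints_must_ascend(self):
        with pytest.raises(ValueError):
            px.PropertyBinScheme("bad", (1.0, 1.0, 2.0))


class TestLabeling:
    def test_benzene_is_sp2_carbon_everywhere(self):
        mol = Chem.MolFromSmiles("c1ccccc1")
        assert label_atoms(mol, "atom_hyb") == ["6>sp2"] * 6

    def test_label_count_equals_atom_count(self, drug_pool):
        for name in ("curcumin", "celecoxib"):
            mol = Chem.MolFromSmiles(drug_pool[name])
            for scheme in ("atom_hyb", "logp", "mr"):
                assert len(label_atoms(mol, scheme)) == mol.GetNumAtoms()

    def test_ethanol_crippen_logp_labels_by_hand(self):
        # Wildman-Crippen atomic contributions: CH3 (C1, +0.1441) -> C;
        # CH2 bonded to O (C3, -0.2035) -> B; alcohol O (O2, -0.2893) -> B
        mol = Chem.MolFromSmiles("CCO")
        assert label_atoms(mol, "logp") == ["C", "B", "B"]

    def test_external_scheme_requires_values(self):
        mol = Chem.MolFromSmiles("CCO")
        with pytest.raises(ValueError):
            label_atoms(mol, "eeq")
        labels = label_atoms(mol, "eeq", external_values=[-0.3, 0.1, 0.5])
        assert labels == ["A", "C", "D"]


class TestEnumeration:
    def test_butane_single_bound_simplex(self):
        mol = Chem.MolFromSmiles("CCCC")
        vec = enumerate_simplexes(mol, ["X"] * 4)
        assert vec.total == 1
        (key, count), = vec.counts.items()
        assert count == 1 and key.startswith("[")  # connected pattern

    def test_pentane_five_subsets(self):
        mol = Chem.MolFromSmiles("CCCCC")
        vec = enumerate_simplexes(mol, ["X"] * 5)
        assert vec.total == 5
        bound = sum(c for k, c in vec.counts.items() if k.startswith("["))
        assert bound == 2  # two connected 4-paths; three disconnected patterns
        assert sum(c for k, c in vec.counts.items() if "+" in k) == 3

    @pytest.mark.parametrize("smiles", [
        "CCCCC", "c1ccccc1O", "CC(C)C(=O)O", "C1CC1CCl", "CCOCC",
        "CC1=CC(=O)CC1", "c1ccc2ccccc2c1"])
    def test_agrees_with_brute_force(self, smiles):
        mol = Chem.MolFromSmiles(smiles)
        labels = label_atoms(mol, "logp")
        mine = enumerate_simplexes(mol, labels).counts
        ref = brute_force_simplexes(mol, labels)
        assert set(mine) == set(ref)
        for k, v in ref.items():
            assert mine[k] == pytest.approx(v)

    @pytest.mark.parametrize("name", ["curcumin", "ibuprofen", "diazepam"])
    def test_total_count_conservation_on_drugs(self, drug_pool, name):
        mol = Chem.MolFromSmiles(drug_pool[name])
        labels = label_atoms(mol, "atom_hyb")
        vec = enumerate_simplexes(mol, labels)
        assert vec.total == pytest.approx(math.comb(mol.GetNumAtoms(), 4))

    def test_small_molecule_yields_empty_vector(self):
        mol = Chem.MolFromSmiles("CCO")
        assert enumerate_simplexes(mol, ["X"] * 3).counts == {}

    def test_noh_equals_h_variant_restricted_to_heavy_keys(self):
        mol = Chem.MolFromSmiles("CCCC")
        noh = enumerate_simplexes(mol, label_atoms(mol, "atom_hyb"))
        molh = Chem.AddHs(mol)
        withh = enumerate_simplexes(molh, label_atoms(molh, "atom_hyb"),
                                    explicit_h=True)
        heavy_only = {k: v for k, v in withh.counts.items() if "1>" not in k}
        assert heavy_only == noh.counts


class TestMixtures:
    def _comp(self, origin, smiles, fraction):
        mol = Chem.MolFromSmiles(smiles)
        return MixtureComponent(origin=origin, mol=mol,
                                labels=label_atoms(mol, "atom_hyb"),
                                fraction=fraction)

    def test_equimolar_binary_weight_is_one(self):
        vec = mixture_simplexes([self._comp("polymer", "CCC", 0.5),
                                 self._comp("drug1", "CO", 0.5)])
        m_keys = {k: v for k, v in vec.counts.items() if k.startswith("M:")}
        assert m_keys
        # 3+1 partition: one connected propane triple x each single of CO
        # base count 1 x weight 2*min(0.5, 0.5) = 1.0
        triple_keys = [k for k in m_keys if "(6>sp3-6>sp3-6>sp3)@polymer" in k]
        assert triple_keys and all(m_keys[k] == pytest.approx(1.0 * 1.0)
                                   for k in triple_keys)

    def test_doubled_minor_fraction_weighting(self):
        vec_ab = mixture_simplexes([self._comp("polymer", "CCC", 0.9),
                                    self._comp("drug1", "CO", 0.1)])
        m = {k: v for k, v in vec_ab.counts.items() if k.startswith("M:")}
        base = mixture_simplexes([self._comp("polymer", "CCC", 0.5),
                                  self._comp("drug1", "CO", 0.5)])
        base_m = {k: v for k, v in base.counts.items() if k.startswith("M:")}
        for k, v in m.items():
            assert v == pytest.approx(base_m[k] * 0.2)
        # single-molecule simplexes keep their own fraction: propane has no
        # 4-atom subset, so check S entries on a bigger polymer stand-in
        vec = mixture_simplexes([self._comp("polymer", "CCCCC", 0.9),
                                 self._comp("drug1", "CO", 0.1)])
        s_total = sum(v for k, v in vec.counts.items() if k.startswith("S@polymer"))
        assert s_total == pytest.approx(0.9 * 5)  # C(5,4) subsets x fraction

    def test_ternary_simplex_carries_three_origins(self):
        vec = mixture_simplexes([self._comp("polymer", "CCC", 0.8),
                                 self._comp("drug1", "CO", 0.15),
                                 self._comp("drug2", "CCl", 0.05)])
        three_origin = [k for k in vec.counts
                        if "@polymer" in k and "@drug1" in k and "@drug2" in k]
        assert three_origin
        # weight = 2 * min fraction of the involved components
        key = next(k for k in three_origin if "(6>sp3~6>sp3)@polymer" in k)
        # base count: 2 eligible (edge, single, single) combos per label choice
        assert vec.counts[key] > 0
        assert vec.counts[key] == pytest.approx(
            round(vec.counts[key] / (2 * 0.05)) * 2 * 0.05)

    def test_uniform_fraction_scaling_preserves_relative_s_weights(self):
        comps = [self._comp("polymer", "CCCCC", 0.6),
                 self._comp("drug1", "CCOCC", 0.4)]
        scaled = [self._comp("polymer", "CCCCC", 0.3),
                  self._comp("drug1", "CCOCC", 0.2)]
        v1 = mixture_simplexes(comps)
        v2 = mixture_simplexes(scaled)
        s1 = {k: v for k, v in v1.counts.items() if k.startswith("S@")}
        s2 = {k: v for k, v in v2.counts.items() if k.startswith("S@")}
        assert set(s1) == set(s2)
        ratios = {k: s1[k] / s2[k] for k in s1}
        assert all(r == pytest.approx(2.0) for r in ratios.values())

    def test_more_than_three_components_unsupported(self):
        comps = [self._comp(o, "CC", 0.25)
                 for o in ("polymer", "drug1", "drug2", "drug3")]
        with pytest.raises(ValueError):
            mixture_simplexes(comps)

    def test_mixture_counts_match_brute_force_cross_enumeration(self):
        """Cross-component 4-atom combos, counted by exhaustive pairing."""
        import itertools
        from collections import Counter
        from poxload.sirms import _canon_connected, _unbound_key

        c1 = self._comp("polymer", "CCO", 1.0)   # fractions 1 -> weight 2
        c2 = self._comp("drug1", "CC", 1.0)
        vec = mixture_simplexes([c1, c2])
        got = {k[2:]: v / 2.0 for k, v in vec.counts.items() if k.startswith("M:")}

        def frags(comp, size):
            """all connected fragments of given size with canonical keys"""
            mol, labels = comp.mol, comp.labels
            adj = [set() for _ in range(mol.GetNumAtoms())]
            for b in mol.GetBonds():
                adj[b.GetBeginAtomIdx()].add(b.GetEndAtomIdx())
                adj[b.GetEndAtomIdx()].add(b.GetBeginAtomIdx())
            out = []
            for sub in itertools.combinations(range(mol.GetNumAtoms()), size):
                edges = [(i, j) for i, j in itertools.combinations(sub, 2)
                         if j in adj[i]]
                # connected?
                import networkx as nx
                g = nx.Graph()
                g.add_nodes_from(sub)
                g.add_edges_from(edges)
                if nx.is_connected(g):
                    nodes = sorted(sub)
                    out.append((_canon_connected(
                        [labels[v] for v in nodes],
                        [(nodes.index(i), nodes.index(j)) for i, j in edges]), sub))
            return out

        expected = Counter()
        # partitions 3+1 and 1+3 and 2+2 (single fragment per component)
        for (k3, _), (k1, _) in itertools.product(frags(c1, 3), frags(c2, 1)):
            expected[_unbound_key([f"{k3}@polymer", f"{k1}@drug1"])] += 1
        for (k1, _), (k3, _) in itertools.product(frags(c1, 1), frags(c2, 3)):
            expected[_unbound_key([f"{k1}@polymer", f"{k3}@drug1"])] += 1
        for (k2a, _), (k2b, _) in itertools.product(frags(c1, 2), frags(c2, 2)):
            expected[_unbound_key([f"{k2a}@polymer", f"{k2b}@drug1"])] += 1
        # 2+1+1 with two single atoms from one molecule (disjoint, non-adjacent)
        def far_pairs(comp):
            mol, labels = comp.mol, comp.labels
            adj = [set() for _ in range(mol.GetNumAtoms())]
            for b in mol.GetBonds():
                adj[b.GetBeginAtomIdx()].add(b.GetEndAtomIdx())
                adj[b.GetEndAtomIdx()].add(b.GetBeginAtomIdx())
            return [(i, j) for i, j in
                    itertools.combinations(range(mol.GetNumAtoms()), 2)
                    if j not in adj[i]]

        for (k2, _), (i, j) in itertools.product(frags(c1, 2), far_pairs(c2)):
            expected[_unbound_key([f"{k2}@polymer",
                                   f"({c2.labels[i]})@drug1",
                                   f"({c2.labels[j]})@drug1"])] += 1
        for (k2, _), (i, j) in itertools.product(frags(c2, 2), far_pairs(c1)):
            expected[_unbound_key([f"{k2}@drug1",
                                   f"({c1.labels[i]})@polymer",
                                   f"({c1.labels[j]})@polymer"])] += 1
        # edge + one far single within the same molecule + single from other
        def edge_far_single(comp):
            mol, labels = comp.mol, comp.labels
            adj = [set() for _ in range(mol.GetNumAtoms())]
            for b in mol.GetBonds():
                adj[b.GetBeginAtomIdx()].add(b.GetEndAtomIdx())
                adj[b.GetEndAtomIdx()].add(b.GetBeginAtomIdx())
            out = []
            for b in mol.GetBonds():
                e = (b.GetBeginAtomIdx(), b.GetEndAtomIdx())
                hood = set(e) | adj[e[0]] | adj[e[1]]
                for v in range(mol.GetNumAtoms()):
                    if v not in hood:
                        out.append((e, v))
            return out

        for (e, v) in edge_far_single(c1):
            for (k1, _) in frags(c2, 1):
                expected[_unbound_key([
                    f"({'~'.join(sorted((c1.labels[e[0]], c1.labels[e[1]])))})@polymer",
                    f"({c1.labels[v]})@polymer", f"{k1}@drug1"])] += 1
        for (e, v) in edge_far_single(c2):
            for (k1, _) in frags(c1, 1):
                expected[_unbound_key([
                    f"({'~'.join(sorted((c2.labels[e[0]], c2.labels[e[1]])))})@drug1",
                    f"({c2.labels[v]})@drug1", f"{k1}@polymer"])] += 1

        assert got == {k: float(v) for k, v in expected.items()}


class TestConnectedOnly:
    def test_restriction_keeps_exactly_the_bound_simplexes(self):
        mol = Chem.MolFromSmiles("CCCCCO")
        labels = label_atoms(mol, "atom_hyb")
        full = enumerate_simplexes(mol, labels)
        bound = enumerate_simplexes(mol, labels, connected_only=True)
        assert bound.counts == {k: v for k, v in full.counts.items()
                                if k.startswith("[")}
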