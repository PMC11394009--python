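"""Assembly of formulation-level feature rows and matrices.

A feature row combines one of the structural descriptor subsets —
physicochemical mixture descriptors, a mixed count-fingerprint family, or
simplex (SiRMS) descriptors — with the experimental features that are always
present: drug and polymer feeds (g/L), the measurement time point (days),
block lengths, molar fractions of every micellar component and drugs per
polymer chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem

from .descriptors import (ConfigurationError, DescriptorVector,
                          RDKitDescriptorBackend, mix_descriptors, submixture)
from .fingerprints import FingerprintBackend, mix_count_fingerprints, FP_FAMILIES
from .polymer import Formulation, build_pseudotrimer, drugs_per_chain, molar_fractions
from .sirms import DEFAULT_SCHEME_IDS, sirms_feature_dict

__all__ = ["MixtureFeatureVector", "FeatureFactory", "SUBSETS"]

SUBSETS = ("mordred",) + FP_FAMILIES + ("sirms", "sirms-noH")


@dataclass
class MixtureFeatureVector:
    """Named numeric features for one formulation plus its split group key."""

    features: Dict[str, float]
    group_key: Tuple[str, str, Tuple[str, ...]]
    subset: str
    backend_id: str = ""


class FeatureFactory:
    """Computes per-component descriptors once and assembles feature rows.

    Component-level results are cached by canonical SMILES, so large tables
    with few unique drugs/monomers assemble quickly.
    """

    def __init__(
        self,
        include_3d: bool = True,
        conformer_seed: int = 1853,
        fp_width: int = 16384,
        round_drug_count: bool = False,
        sirms_schemes: Sequence[str] = DEFAULT_SCHEME_IDS,
    ):
        self.descriptor_backend = RDKitDescriptorBackend(
            include_3d=include_3d, conformer_seed=conformer_seed)
        self.fp_backend = FingerprintBackend(width=fp_width)
        self.round_drug_count = round_drug_count
        self.sirms_schemes = tuple(sirms_schemes)
        self._trimer_cache: Dict[str, Chem.Mol] = {}
        self._sirms_cache: Dict[Tuple, Dict[str, float]] = {}

    # ------------------------------------------------------------------
    def experimental_features(self, formulation: Formulation) -> Dict[str, float]:
        nA1, nB, nA2 = formulation.polymer.block_lengths
        stoich = molar_fractions(formulation)
        per_chain = drugs_per_chain(formulation)
        drugs = list(formulation.drug_feeds)
        feats: Dict[str, float] = {
            "DF": formulation.total_drug_feed,
            "polymer_feed": formulation.m_polymer_feed,
            "t_measure": formulation.t_measure,
            "n_block_A1": float(nA1),
            "n_block_B": float(nB),
            "n_block_A2": float(nA2),
            "frac_T1": stoich.fractions["T1"],
            "frac_A": stoich.fractions["A"],
            "frac_B": stoich.fractions["B"],
            "frac_T2": stoich.fractions["T2"],
        }
        for i in range(2):
            if i < len(drugs):
                drug, feed = drugs[i]
                feats[f"DF_drug{i+1}"] = feed
                feats[f"frac_drug{i+1}"] = stoich.fractions[f"drug:{drug.name}"]
                feats[f"per_chain_drug{i+1}"] = per_chain[drug.name]
            else:
                feats[f"DF_drug{i+1}"] = 0.0
                feats[f"frac_drug{i+1}"] = 0.0
                feats[f"per_chain_drug{i+1}"] = 0.0
        return feats

    # ------------------------------------------------------------------
    def _component_structures(self, formulation: Formulation) -> Dict[str, Chem.Mol]:
        pol = formulation.polymer
        comps = {
            "T1": pol.termini[0].capped_mol,
            "A": pol.a_monomer.capped_mol,
            "B": pol.b_monomer.capped_mol,
            "T2": pol.termini[1].capped_mol,
        }
        for i, (drug, _) in enumerate(formulation.drug_feeds):
            comps[f"drug{i+1}"] = drug.mol
        return comps

    def _fraction_map(self, formulation: Formulation) -> Dict[str, float]:
        stoich = molar_fractions(formulation)
        out = {k: v for k, v in stoich.fractions.items() if not k.startswith("drug:")}
        for i, (drug, _) in enumerate(formulation.drug_feeds):
            out[f"drug{i+1}"] = stoich.fractions[f"drug:{drug.name}"]
        return out

    def descriptor_features(self, formulation: Formulation) -> Dict[str, float]:
        comps = self._component_structures(formulation)
        vecs = {k: self.descriptor_backend.compute(m) for k, m in comps.items()}
        fracs = self._fraction_map(formulation)
        mixed = mix_descriptors(vecs, fracs)
        out = {f"MIX:{k}": v for k, v in mixed.values.items()}
        ablock = submixture(vecs, fracs, ["T1", "A", "T2"])
        bblock = submixture(vecs, fracs, ["B"])
        drug_keys = [k for k in vecs if k.startswith("drug")]
        drugmix = submixture(vecs, fracs, drug_keys)
        for prefix, vec in (("ABLOCK", ablock), ("BBLOCK", bblock), ("DRUG", drugmix)):
            out.update({f"{prefix}:{k}": v for k, v in vec.values.items()})
        return out

    def fingerprint_features(self, formulation: Formulation, family: str) -> Dict[str, float]:
        comps = self._component_structures(formulation)
        fps = {k: self.fp_backend.compute(m, family) for k, m in comps.items()}
        stoich = molar_fractions(formulation)
        mult = {k: stoich.counts[k] for k in ("T1", "A", "B", "T2")}
        for i, (drug, _) in enumerate(formulation.drug_feeds):
            n = stoich.counts[f"drug:{drug.name}"]
            mult[f"drug{i+1}"] = round(n) if self.round_drug_count else n
        mixed = mix_count_fingerprints(fps, mult)
        out = {f"MIX:{family}_{b}": c for b, c in mixed.counts.items()}
        drug_fps = {k: v for k, v in fps.items() if k.startswith("drug")}
        if drug_fps:
            dmix = mix_count_fingerprints(drug_fps, mult)
            out.update({f"DRUG:{family}_{b}": c for b, c in dmix.counts.items()})
        return out

    def sirms_features(self, formulation: Formulation, explicit_h: bool) -> Dict[str, float]:
        pol = formulation.polymer
        pol_key = "|".join((pol.a_monomer.name, pol.b_monomer.name,
                            pol.termini[0].name, pol.termini[1].name))
        if pol_key not in self._trimer_cache:
            self._trimer_cache[pol_key] = build_pseudotrimer(pol)
        trimer = self._trimer_cache[pol_key]
        stoich = molar_fractions(formulation)
        fracs = {"polymer": sum(v for k, v in stoich.fractions.items()
                                if not k.startswith("drug:"))}
        drugs = []
        for i, (drug, _) in enumerate(formulation.drug_feeds):
            fracs[f"drug{i+1}"] = stoich.fractions[f"drug:{drug.name}"]
            drugs.append(drug.mol)
        return sirms_feature_dict(trimer, drugs, fracs,
                                  scheme_ids=self.sirms_schemes, explicit_h=explicit_h)

    # ------------------------------------------------------------------
    def assemble_feature_row(self, formulation: Formulation, subset: str) -> MixtureFeatureVector:
        """One named feature row for the requested descriptor subset."""
        if subset not in SUBSETS:
            raise ConfigurationError(
                f"unknown subset {subset!r}; choose one of {SUBSETS}")
        feats = self.experimental_features(formulation)
        if subset == "mordred":
            feats.update(self.descriptor_features(formulation))
            backend_id = self.descriptor_backend.backend_id
        elif subset in FP_FAMILIES:
            feats.update(self.fingerprint_features(formulation, subset))
            backend_id = f"fp:{subset}:w{self.fp_backend.width}"
        else:
            explicit_h = subset == "sirms"
            feats.update(self.sirms_features(formulation, explicit_h))
            backend_id = f"sirms:{','.join(self.sirms_schemes)}:{'H' if explicit_h else 'noH'}"
        return MixtureFeatureVector(
            features=feats,
            group_key=formulation.group_key,
            subset=subset,
            backend_id=backend_id,
        )

    def assemble_feature_table(
        self, formulations: Sequence[Formulation], subset: str
    ) -> Tuple[pd.DataFrame, List[Tuple[str, str, Tuple[str, ...]]]]:
        """Feature matrix (rows aligned with input order) and group keys.

        Sparse structural features (fingerprint bits, simplex counts) absent
        from a row are true zero counts; physicochemical descriptors missing
        for a component stay NaN and are removed by the preprocessing filter.
        """
        rows = [self.assemble_feature_row(f, subset) for f in formulations]
        frame = pd.DataFrame([r.features for r in rows])
        if subset != "mordred":
            structural = [c for c in frame.columns if ":" in c]
            frame[structural] = frame[structural].fillna(0.0)
        return frame, [r.group_key for r in rows]
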