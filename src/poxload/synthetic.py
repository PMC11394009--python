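"""Synthetic formulation tables with a planted structure-loading relationship.

The generator emulates the schema of a real solubilization database — ABA
triblock polymers crossed with hydrophobic drugs at varying drug feeds and
measurement times — and plants an additive-logistic rule for the solubilized
fraction so that every pipeline stage has a known ground truth:

``logit(LE/100) = b0 + b_hbd*min(HBD,4) + b_logp*exp(-((logP-3.5)/2)^2)
+ b_block*(nB-20)/10 - b_df*(DF-5)/3``, attenuated by ``exp(-decay*t)``
for storage-time decay, plus Gaussian noise.  Higher drug feeds therefore
lower LE (the sign structure of real data), polar-group-bearing drugs in a
mid-logP window load better, and longer hydrophobic blocks help.

The drug pool is a curated list of ~30 real, poorly water-soluble drugs
(SMILES shipped with the package), so descriptor pipelines run on realistic
chemistry without any download.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, rdMolDescriptors

from .dataset import FormulationTable
from .polymer import (DrugSpec, Formulation, PolymerSpec, load_monomer_registry,
                      make_polymer)

__all__ = ["GeneratorConfig", "generate_formulation_dataset", "load_drug_pool",
           "make_worked_example", "make_tabular_planted"]


def load_drug_pool() -> Dict[str, str]:
    text = resources.files("poxload.data").joinpath("drug_pool.json").read_text()
    return json.loads(text)


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic tables.

    The planted coefficients act on interpretable drug/polymer properties so
    feature-importance checks have a known answer; noise_sd and decay set the
    measurement noise and the long-term storage decay rate (per day).
    """

    n_formulations: int = 500
    seed: int = 42
    drug_names: Optional[Sequence[str]] = None  # default: whole shipped pool
    b_monomers: Sequence[str] = ("nPrOx", "nPrOzi", "nBuOx", "nBuOzi", "BzOx", "PentOx")
    a_monomers: Sequence[str] = ("MeOx", "EtOx")
    a_weights: Sequence[float] = (0.9, 0.1)
    block_choices: Sequence[Tuple[int, int, int]] = (
        (35, 20, 35), (25, 15, 25), (30, 25, 30), (20, 10, 20))
    df_choices: Sequence[float] = tuple(float(v) for v in range(2, 13))
    polymer_feed: float = 10.0
    t_choices: Sequence[float] = (0.0, 1.0, 7.0, 30.0, 180.0)
    t_weights: Sequence[float] = (0.5, 0.1, 0.2, 0.1, 0.1)
    coformulation_rate: float = 0.1
    # planted rule
    b0: float = -1.0
    b_hbd: float = 0.8
    b_logp: float = 1.5
    b_block: float = 0.6
    b_df: float = 0.8
    noise_sd: float = 0.05
    decay: float = 0.004


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _drug_props(smiles: str) -> Tuple[int, float]:
    mol = Chem.MolFromSmiles(smiles)
    return rdMolDescriptors.CalcNumHBD(mol), Crippen.MolLogP(mol)


def planted_le_fraction(hbd: int, logp: float, n_block: int, df: float,
                        t: float, config: GeneratorConfig) -> float:
    """Noise-free solubilized fraction under the planted rule."""
    x = (config.b0
         + config.b_hbd * min(hbd, 4)
         + config.b_logp * math.exp(-(((logp - 3.5) / 2.0) ** 2))
         + config.b_block * (n_block - 20) / 10.0
         - config.b_df * (df - 5.0) / 3.0)
    return _sigmoid(x) * math.exp(-config.decay * t)


def generate_formulation_dataset(config: Optional[GeneratorConfig] = None
                                 ) -> FormulationTable:
    """Seeded synthetic formulation table passing all loader validation."""
    cfg = config or GeneratorConfig()
    pool = load_drug_pool()
    names = sorted(pool) if cfg.drug_names is None else list(cfg.drug_names)
    if not names or not cfg.b_monomers:
        raise ValueError("drug and polymer pools must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    registry = load_monomer_registry()
    props = {n: _drug_props(pool[n]) for n in names}
    drugs = {n: DrugSpec(n, pool[n]) for n in names}

    rows: List[Formulation] = []
    for _ in range(cfg.n_formulations):
        a = str(rng.choice(list(cfg.a_monomers), p=list(cfg.a_weights)))
        b = str(rng.choice(list(cfg.b_monomers)))
        blocks = cfg.block_choices[int(rng.integers(len(cfg.block_choices)))]
        polymer = make_polymer(b, a_name=a, block_lengths=blocks, registry=registry)
        df_total = float(rng.choice(list(cfg.df_choices)))
        t = float(rng.choice(list(cfg.t_choices), p=list(cfg.t_weights)))
        n_drugs = 2 if rng.random() < cfg.coformulation_rate else 1
        chosen = list(rng.choice(names, size=n_drugs, replace=False))
        feed_each = df_total / n_drugs
        feeds, sols = [], []
        for dn in chosen:
            hbd, logp = props[dn]
            le = planted_le_fraction(hbd, logp, blocks[1], df_total, t, cfg)
            le = le + float(rng.normal(0.0, cfg.noise_sd))
            le = min(max(le, 0.0), 1.0)
            feeds.append((drugs[dn], feed_each))
            sols.append(round(le * feed_each, 6))
        rows.append(Formulation(
            polymer=polymer,
            drug_feeds=tuple(feeds),
            m_polymer_feed=cfg.polymer_feed,
            t_measure=t,
            m_solubilized=tuple(sols),
            settings={"organic_solvent": "EtOH", "aqueous_solvent": "Diwater"},
        ))
    return FormulationTable(rows=rows, provenance=f"synthetic(seed={cfg.seed})")


def make_worked_example() -> Formulation:
    """Paclitaxel in A-nPrOzi-A micelles at a 10/2 polymer/drug feed ratio."""
    pool = load_drug_pool()
    polymer = make_polymer("nPrOzi")
    drug = DrugSpec("paclitaxel", pool["paclitaxel"])
    return Formulation(polymer=polymer, drug_feeds=((drug, 2.0),),
                       m_polymer_feed=10.0, t_measure=0.0)


def make_tabular_planted(n: int = 300, n_informative: int = 5, n_noise: int = 50,
                         seed: int = 0, flip: float = 0.0, margin: float = 0.0
                         ) -> Tuple[pd.DataFrame, np.ndarray, List[str]]:
    """Plain tabular planted-signal data for selector/classifier checks.

    Returns (X, y, informative feature names); y is a thresholded linear
    combination of the informative features with optional label flips.
    ``margin > 0`` removes rows within that many score standard deviations of
    the class boundary, yielding cleanly separable classes.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_informative + n_noise))
    cols = [f"inf_{i}" for i in range(n_informative)] + \
           [f"noise_{i}" for i in range(n_noise)]
    w = rng.uniform(1.0, 2.0, size=n_informative)
    score = X[:, :n_informative] @ w
    boundary = np.median(score)
    y = (score > boundary).astype(int)
    if margin > 0:
        keep = np.abs(score - boundary) > margin * score.std()
        X, y = X[keep], y[keep]
    if flip > 0:
        flips = rng.random(len(y)) < flip
        y[flips] = 1 - y[flips]
    return pd.DataFrame(X, columns=cols), y, cols[:n_informative]
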