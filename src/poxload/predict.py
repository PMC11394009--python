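"""End-user prediction: threshold ensemble, solubilization estimates, screening.

Eight threshold classifiers (LC >= 10/20/30/40 %, LE >= 20/40/60/80 %) are
applied to a candidate formulation; predictions outside a model's
applicability domain count as negative.  Each ladder (LC and LE) is walked in
ascending order until two consecutive rungs fail; the percentage estimate is
one point below the rung following the last passed threshold (39 % when
passing LE20 but not LE40), the threshold value itself (a lower bound) when
the top rung passes, and 0 when nothing passes.  Percentage estimates are
converted to solubilized masses: ``m_LE = LE/100 * DF`` and ``m_LC`` solves
``LC = 100 * m / (m + polymer_feed)``; the combined estimate is their mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dataset import LC_THRESHOLDS, LE_THRESHOLDS
from .mixtures import FeatureFactory
from .pipeline import PipelineError, ThresholdModelBundle
from .polymer import DrugSpec, Formulation, PolymerSpec

__all__ = [
    "ThresholdCall",
    "PredictionReport",
    "SolubilizationEnsemble",
    "ladder_estimate",
    "estimate_solubilized",
]

LADDERS: Dict[str, Tuple[float, ...]] = {"LC": LC_THRESHOLDS, "LE": LE_THRESHOLDS}
THRESHOLD_IDS = tuple(f"{kind}{int(t)}" for kind in ("LC", "LE") for t in LADDERS[kind])


@dataclass(frozen=True)
class ThresholdCall:
    threshold_id: str
    raw_positive: bool
    in_ad: bool
    distance: Optional[float]

    @property
    def passed(self) -> bool:
        """Out-of-domain predictions are treated as negative."""
        return self.raw_positive and self.in_ad


@dataclass
class PredictionReport:
    polymer: str
    drugs: Tuple[str, ...]
    df: float
    polymer_feed: float
    t_measure: float
    calls: Dict[str, ThresholdCall]
    lc_estimate_pct: float
    le_estimate_pct: float
    lc_lower_bound: bool
    le_lower_bound: bool
    m_lc: float
    m_le: float
    m_combined: float

    @property
    def n_passed(self) -> int:
        return sum(c.passed for c in self.calls.values())


def ladder_estimate(passes: Sequence[bool], thresholds: Sequence[float]
                    ) -> Tuple[float, bool]:
    """(percentage estimate, top-rung lower-bound flag) from a pass ladder.

    Walk ascending thresholds, stopping after two consecutive failures; the
    estimate is one point below the rung above the last pass, the top
    threshold itself when it passed (flagged as a ">=" lower bound), and 0
    when no rung passed.
    """
    if len(passes) != len(thresholds):
        raise ValueError("one pass flag per threshold required")
    last_passed = -1
    consecutive_fails = 0
    for i, ok in enumerate(passes):
        if ok:
            last_passed = i
            consecutive_fails = 0
        else:
            consecutive_fails += 1
            if consecutive_fails >= 2:
                break
    if last_passed < 0:
        return 0.0, False
    if last_passed == len(thresholds) - 1:
        return float(thresholds[-1]), True
    return float(thresholds[last_passed + 1]) - 1.0, False


def estimate_solubilized(lc_pct: float, le_pct: float, polymer_feed: float,
                         df: float) -> Tuple[float, float, float]:
    """(m_LC, m_LE, combined mean) solubilized masses in g/L."""
    m_le = le_pct / 100.0 * df
    if lc_pct >= 100.0:
        raise ValueError("LC estimate of 100 % cannot be inverted")
    m_lc = (lc_pct / 100.0) * polymer_feed / (1.0 - lc_pct / 100.0)
    return m_lc, m_le, 0.5 * (m_lc + m_le)


class SolubilizationEnsemble:
    """Eight fitted threshold bundles + a feature factory = a screening tool."""

    def __init__(self, bundles: Mapping[str, ThresholdModelBundle],
                 factory: Optional[FeatureFactory] = None):
        missing = [t for t in THRESHOLD_IDS if t not in bundles]
        if missing:
            raise PipelineError(f"missing threshold bundles: {missing}")
        self.bundles = dict(bundles)
        self.factory = factory or FeatureFactory()

    # ------------------------------------------------------------------
    def predict_thresholds(self, formulation: Formulation) -> Dict[str, ThresholdCall]:
        calls: Dict[str, ThresholdCall] = {}
        frames: Dict[str, pd.DataFrame] = {}
        for tid in THRESHOLD_IDS:
            bundle = self.bundles[tid]
            if bundle.subset not in frames:
                frame, _ = self.factory.assemble_feature_table([formulation], bundle.subset)
                frames[bundle.subset] = frame
            frame = frames[bundle.subset]
            raw = bool(bundle.decision(frame)[0])
            if bundle.ad_model is not None:
                dist = float(bundle.ad_distances(frame)[0])
                inside = dist <= bundle.ad_model.cutoff
            else:
                dist, inside = None, True
            calls[tid] = ThresholdCall(threshold_id=tid, raw_positive=raw,
                                       in_ad=inside, distance=dist)
        return calls

    def predict_report(self, formulation: Formulation) -> PredictionReport:
        calls = self.predict_thresholds(formulation)
        lc_pct, lc_lb = ladder_estimate(
            [calls[f"LC{int(t)}"].passed for t in LADDERS["LC"]], LADDERS["LC"])
        le_pct, le_lb = ladder_estimate(
            [calls[f"LE{int(t)}"].passed for t in LADDERS["LE"]], LADDERS["LE"])
        m_lc, m_le, m_comb = estimate_solubilized(
            lc_pct, le_pct, formulation.m_polymer_feed, formulation.total_drug_feed)
        return PredictionReport(
            polymer=formulation.polymer.name,
            drugs=tuple(d.name for d, _ in formulation.drug_feeds),
            df=formulation.total_drug_feed,
            polymer_feed=formulation.m_polymer_feed,
            t_measure=formulation.t_measure,
            calls=calls,
            lc_estimate_pct=lc_pct, le_estimate_pct=le_pct,
            lc_lower_bound=lc_lb, le_lower_bound=le_lb,
            m_lc=m_lc, m_le=m_le, m_combined=m_comb)

    # ------------------------------------------------------------------
    def predict_df_grid(self, polymer: PolymerSpec, drugs: Sequence[DrugSpec],
                        polymer_feed: float = 10.0,
                        df_grid: Sequence[float] = tuple(range(2, 11)),
                        t_measure: float = 0.0) -> List[PredictionReport]:
        """Formulation report over a drug-feed grid (default 2-10 g/L)."""
        out = []
        for df in df_grid:
            share = df / len(drugs)
            form = Formulation(polymer=polymer,
                               drug_feeds=tuple((d, share) for d in drugs),
                               m_polymer_feed=polymer_feed, t_measure=t_measure)
            out.append(self.predict_report(form))
        return out

    def screen_library(
        self,
        drugs: Sequence[DrugSpec],
        polymers: Sequence[PolymerSpec],
        polymer_feed: float = 10.0,
        df: float = 6.0,
        t_measure: float = 0.0,
        logs_filter: Optional[float] = None,
    ) -> pd.DataFrame:
        """One ranked row per drug x polymer at the given conditions.

        Default conditions: 10 g/L polymer feed, 6 g/L drug feed, immediate
        (0-day) measurement.  ``logs_filter`` drops drugs whose estimated
        aqueous solubility exceeds the given g/L value (poorly soluble drugs
        are the use case); the estimate is the descriptor backend's ESOL logS.
        """
        from rdkit import Chem
        from .descriptors import esol_logs

        rows = []
        for drug in drugs:
            if logs_filter is not None:
                mol = drug.mol
                sol_gl = 10.0 ** esol_logs(mol) * drug.mw_drug
                if sol_gl >= logs_filter:
                    continue
            for pol in polymers:
                form = Formulation(polymer=pol, drug_feeds=((drug, df),),
                                   m_polymer_feed=polymer_feed, t_measure=t_measure)
                rep = self.predict_report(form)
                row = {
                    "drug": drug.name, "polymer": pol.name,
                    "df": df, "polymer_feed": polymer_feed,
                    "n_passed": rep.n_passed,
                    "lc_estimate_pct": rep.lc_estimate_pct,
                    "le_estimate_pct": rep.le_estimate_pct,
                    "m_combined": rep.m_combined,
                }
                for tid, call in rep.calls.items():
                    row[f"{tid}_pass"] = call.passed
                    row[f"{tid}_in_ad"] = call.in_ad
                rows.append(row)
        frame = pd.DataFrame(rows)
        if len(frame):
            frame = frame.sort_values(
                ["n_passed", "m_combined", "drug", "polymer"],
                ascending=[False, False, True, True]).reset_index(drop=True)
        return frame
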