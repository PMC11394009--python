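"""Threshold-classifier training pipeline and evaluation metrics.

The modeling core follows a Model/Results layout: a
:class:`ThresholdClassifier` is constructed from a feature matrix and binary
labels (metric >= threshold); :meth:`ThresholdClassifier.fit` runs

1. preprocessing fitted on the training set only — drop features with any
   missing value, (near-)zero variance, or pairwise correlation above 0.9,
   then center/scale with a Yeo-Johnson power transform;
2. Boruta feature selection (shadow-feature random-forest importances);
3. repeated stratified k-fold cross-validation with majority-class
   downsampling inside every training fold and a grid search optimized on
   ROC AUC;
4. a refit on the (downsampled) full training set with the best
   hyperparameters,

and returns a :class:`ThresholdClassifierResults` carrying the fitted
pipeline, CV metrics, selected features and an optional applicability-domain
model.  Regression uses the same scaffolding with RMSE as the objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import (RandomForestClassifier, RandomForestRegressor)
from sklearn.gaussian_process import (GaussianProcessClassifier,
                                      GaussianProcessRegressor)
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, RepeatedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import PowerTransformer
from sklearn.svm import SVC, SVR
from xgboost import XGBClassifier, XGBRegressor

from .domain import ADModel, fit_ad

__all__ = [
    "PreprocessSpec",
    "Preprocessor",
    "MetricsSet",
    "ThresholdModelBundle",
    "ThresholdClassifier",
    "ThresholdClassifierResults",
    "ThresholdRegressor",
    "classification_metrics",
    "boruta_select",
    "y_randomize",
    "PipelineError",
    "CLASSIFIER_FAMILIES",
    "REGRESSOR_FAMILIES",
]


class PipelineError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# preprocessing

@dataclass
class PreprocessSpec:
    dropped_missing: List[str]
    dropped_nzv: List[str]
    dropped_correlated: List[str]
    retained: List[str]

    @property
    def dropped_features(self) -> List[str]:
        return self.dropped_missing + self.dropped_nzv + self.dropped_correlated


class Preprocessor:
    """Missing/NZV/correlation filters + Yeo-Johnson scaling, fit on TS only."""

    def __init__(self, corr_limit: float = 0.9, nzv_freq_ratio: float = 19.0,
                 nzv_unique_frac: float = 0.1):
        self.corr_limit = corr_limit
        self.nzv_freq_ratio = nzv_freq_ratio
        self.nzv_unique_frac = nzv_unique_frac
        self.spec: Optional[PreprocessSpec] = None
        self._transform: Optional[PowerTransformer] = None

    def fit(self, frame: pd.DataFrame) -> "Preprocessor":
        cols = list(frame.columns)
        missing = [c for c in cols if frame[c].isna().any()]
        work = frame.drop(columns=missing)

        nzv = []
        n = len(work)
        for c in work.columns:
            vals = work[c].to_numpy()
            uniq, counts = np.unique(vals, return_counts=True)
            if len(uniq) < 2 or float(np.var(vals)) < 1e-12:
                nzv.append(c)
                continue
            counts = np.sort(counts)[::-1]
            freq_ratio = counts[0] / counts[1]
            if freq_ratio > self.nzv_freq_ratio and len(uniq) / n < self.nzv_unique_frac:
                nzv.append(c)
        work = work.drop(columns=nzv)

        corr_dropped: List[str] = []
        if work.shape[1] > 1:
            corr = np.abs(np.corrcoef(work.to_numpy(), rowvar=False))
            names = list(work.columns)
            # connected components of the |r| > limit graph; keep the
            # lexicographically first member of each component
            parent = list(range(len(names)))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            hi, hj = np.where(np.triu(corr, 1) > self.corr_limit)
            for i, j in zip(hi, hj):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
            clusters: Dict[int, List[str]] = {}
            for i, name in enumerate(names):
                clusters.setdefault(find(i), []).append(name)
            for members in clusters.values():
                if len(members) > 1:
                    keep = min(members)
                    corr_dropped.extend(m for m in members if m != keep)
            work = work.drop(columns=corr_dropped)

        if work.shape[1] == 0:
            raise PipelineError("preprocessing dropped every feature")
        self.spec = PreprocessSpec(
            dropped_missing=missing, dropped_nzv=nzv,
            dropped_correlated=sorted(corr_dropped), retained=list(work.columns))
        self._transform = PowerTransformer(method="yeo-johnson", standardize=True)
        self._transform.fit(work.to_numpy())
        return self

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        if self.spec is None or self._transform is None:
            raise PipelineError("preprocessor not fitted")
        # sparse count features (fingerprint bits, simplex keys) absent from a
        # query are true zeros; queries sharing no fitted feature are rejected
        present = [c for c in self.spec.retained if c in frame.columns]
        if not present:
            raise PipelineError("query shares no feature with the fitted matrix")
        aligned = frame.reindex(columns=self.spec.retained, fill_value=0.0)
        data = self._transform.transform(aligned.to_numpy())
        return pd.DataFrame(data, columns=self.spec.retained, index=frame.index)


# ---------------------------------------------------------------------------
# Boruta (shadow-feature random-forest selection)

def boruta_select(
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    max_iter: int = 40,
    alpha: float = 0.01,
    task: str = "classification",
    keep_tentative: bool = True,
    n_estimators: int = 300,
) -> List[str]:
    """Boruta: compare real-feature importances against permuted shadows.

    Each round, every feature is duplicated and shuffled; a random forest is
    fitted on [real | shadow] and a feature scores a *hit* when its
    importance exceeds the best shadow importance.  A two-sided binomial
    test (Bonferroni-corrected) confirms or rejects features; undecided
    (tentative) features are kept by default.
    """
    y = np.asarray(y)
    if task == "classification" and len(np.unique(y)) < 2:
        raise PipelineError("degenerate labels: only one class present")
    rng = np.random.default_rng(seed)
    names = list(X.columns)
    active = list(names)
    hits = {n: 0 for n in names}
    trials = 0
    confirmed: List[str] = []
    rejected: List[str] = []

    for _ in range(max_iter):
        if not active:
            break
        data = X[active].to_numpy()
        shadow = data.copy()
        for j in range(shadow.shape[1]):
            rng.shuffle(shadow[:, j])
        both = np.hstack([data, shadow])
        est_seed = int(rng.integers(0, 2**31 - 1))
        if task == "classification":
            forest = RandomForestClassifier(
                n_estimators=n_estimators, random_state=est_seed, n_jobs=1)
        else:
            forest = RandomForestRegressor(
                n_estimators=n_estimators, random_state=est_seed, n_jobs=1)
        forest.fit(both, y)
        imp = forest.feature_importances_
        best_shadow = imp[len(active):].max()
        for i, name in enumerate(active):
            if imp[i] > best_shadow:
                hits[name] += 1
        trials += 1

        # binomial decisions (Bonferroni over the initial feature count)
        thresh = alpha / len(names)
        still = []
        for name in active:
            p_hi = stats.binomtest(hits[name], trials, 0.5, alternative="greater").pvalue
            p_lo = stats.binomtest(hits[name], trials, 0.5, alternative="less").pvalue
            if p_hi < thresh:
                confirmed.append(name)
            elif p_lo < thresh:
                rejected.append(name)
            else:
                still.append(name)
        active = still

    tentative = active
    selected = confirmed + (tentative if keep_tentative else [])
    if not selected:
        # Boruta may reject everything on pure noise; fall back to the single
        # best-scoring feature so downstream fitting remains possible.
        selected = [max(hits, key=lambda n: hits[n])]
    return sorted(selected, key=names.index)


# ---------------------------------------------------------------------------
# metrics

@dataclass
class MetricsSet:
    """Confusion-matrix statistics; undefined ratios stay None (not zero)."""

    TP: float
    TN: float
    FP: float
    FN: float
    Sens: Optional[float] = None
    Spec: Optional[float] = None
    PPV: Optional[float] = None
    NPV: Optional[float] = None
    Acc: Optional[float] = None
    F1: Optional[float] = None
    nMCC: Optional[float] = None
    AUC: Optional[float] = None


def classification_metrics(tp: float, tn: float, fp: float, fn: float,
                           auc: Optional[float] = None) -> MetricsSet:
    """Sens/Spec/PPV/NPV, balanced accuracy, F1 and normalized MCC.

    Balanced accuracy is (Sens + Spec)/2; nMCC = (MCC + 1)/2 rescales the
    Matthews correlation coefficient to [0, 1].
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    total = tp + tn + fp + fn
    if total <= 0:
        raise ValueError("empty confusion matrix")

    def ratio(num, den):
        return num / den if den > 0 else None

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    acc = (sens + spec) / 2.0 if sens is not None and spec is not None else None
    f1 = None
    if ppv is not None and sens is not None and (ppv + sens) > 0:
        f1 = 2.0 * ppv * sens / (ppv + sens)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    nmcc = ((tp * tn - fp * fn) / mcc_den + 1.0) / 2.0 if mcc_den > 0 else None
    return MetricsSet(TP=tp, TN=tn, FP=fp, FN=fn, Sens=sens, Spec=spec,
                      PPV=ppv, NPV=npv, Acc=acc, F1=f1, nMCC=nmcc, AUC=auc)


def _mean_metrics(folds: List[MetricsSet]) -> MetricsSet:
    def mean_of(attr):
        vals = [getattr(m, attr) for m in folds if getattr(m, attr) is not None]
        return float(np.mean(vals)) if vals else None

    return MetricsSet(
        TP=float(np.mean([m.TP for m in folds])),
        TN=float(np.mean([m.TN for m in folds])),
        FP=float(np.mean([m.FP for m in folds])),
        FN=float(np.mean([m.FN for m in folds])),
        Sens=mean_of("Sens"), Spec=mean_of("Spec"), PPV=mean_of("PPV"),
        NPV=mean_of("NPV"), Acc=mean_of("Acc"), F1=mean_of("F1"),
        nMCC=mean_of("nMCC"), AUC=mean_of("AUC"))


# ---------------------------------------------------------------------------
# model families and hyperparameter grids

def _geomspace(lo, hi, n):
    return list(np.geomspace(lo, hi, num=max(2, n)))


def _classifier_grid(family: str, tune_length: int, n_features: int, seed: int):
    """caret-like default grids of the requested tune length."""
    tl = max(1, tune_length)
    if family == "RF":
        mtry = sorted({max(1, int(round(v)))
                       for v in np.linspace(1, max(1, n_features), num=tl)})
        return [{"max_features": m} for m in mtry]
    if family == "XGB":
        depths = [2, 3, 4, 5, 6][:tl]
        return [{"max_depth": d, "n_estimators": 150, "learning_rate": 0.3}
                for d in depths]
    if family == "SVC":
        return [{"C": c} for c in _geomspace(0.25, 2.0 ** max(1, tl - 1), tl)]
    if family == "GPC":
        return [{"kernel_scale": s} for s in _geomspace(0.1, 10.0, min(tl, 5))]
    if family == "kNN":
        ks = sorted({int(round(k)) // 2 * 2 + 1
                     for k in np.linspace(5, 5 + 2 * (tl - 1), num=tl)})
        return [{"n_neighbors": k} for k in ks]
    if family == "LR":
        return [{"C": c} for c in _geomspace(1e-3, 1e3, tl)]
    raise ValueError(f"unknown classifier family {family!r}")


def _make_classifier(family: str, params: Dict, seed: int, n_estimators: int = 300):
    if family == "RF":
        return RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                      n_jobs=1, **params)
    if family == "XGB":
        return XGBClassifier(random_state=seed, n_jobs=1, eval_metric="logloss",
                             verbosity=0, **params)
    if family == "SVC":
        return SVC(kernel="rbf", gamma="scale", random_state=seed, **params)
    if family == "GPC":
        scale = params.get("kernel_scale", 1.0)
        return GaussianProcessClassifier(
            kernel=ConstantKernel(1.0) * RBF(length_scale=scale),
            random_state=seed)
    if family == "kNN":
        return KNeighborsClassifier(**params)
    if family == "LR":
        return LogisticRegression(max_iter=2000, **params)
    raise ValueError(f"unknown classifier family {family!r}")


def _regressor_grid(family: str, tune_length: int, n_features: int):
    tl = max(1, tune_length)
    if family == "PLS":
        comps = sorted({max(1, int(round(v)))
                        for v in np.linspace(1, min(n_features, 1 + tl), num=tl)})
        return [{"n_components": c} for c in comps]
    if family == "RF":
        mtry = sorted({max(1, int(round(v)))
                       for v in np.linspace(1, max(1, n_features), num=tl)})
        return [{"max_features": m} for m in mtry]
    if family == "XGB":
        return [{"max_depth": d, "n_estimators": 150, "learning_rate": 0.3}
                for d in [2, 3, 4, 5, 6][:tl]]
    if family == "linear":
        return [{}]
    if family == "SVR":
        return [{"C": c} for c in _geomspace(0.25, 2.0 ** max(1, tl - 1), tl)]
    if family == "GPR":
        return [{"kernel_scale": s} for s in _geomspace(0.1, 10.0, min(tl, 5))]
    raise ValueError(f"unknown regressor family {family!r}")


def _make_regressor(family: str, params: Dict, seed: int, n_estimators: int = 300):
    if family == "PLS":
        return PLSRegression(**params)
    if family == "RF":
        return RandomForestRegressor(n_estimators=n_estimators, random_state=seed,
                                     n_jobs=1, **params)
    if family == "XGB":
        return XGBRegressor(random_state=seed, n_jobs=1, verbosity=0, **params)
    if family == "linear":
        return LinearRegression()
    if family == "SVR":
        return SVR(kernel="rbf", gamma="scale", **params)
    if family == "GPR":
        scale = params.get("kernel_scale", 1.0)
        return GaussianProcessRegressor(
            kernel=ConstantKernel(1.0) * RBF(length_scale=scale),
            alpha=1e-6, random_state=seed, normalize_y=True)
    raise ValueError(f"unknown regressor family {family!r}")


CLASSIFIER_FAMILIES = ("RF", "XGB", "SVC", "GPC", "kNN", "LR")
REGRESSOR_FAMILIES = ("PLS", "RF", "XGB", "linear", "SVR", "GPR")


def _downsample(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Drop majority-class rows to an exact 1:1 class ratio."""
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == len(neg):
        return X, y
    major, minor = (pos, neg) if len(pos) > len(neg) else (neg, pos)
    keep = rng.choice(major, size=len(minor), replace=False)
    idx = np.sort(np.concatenate([keep, minor]))
    return X[idx], y[idx]


def _scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


# ---------------------------------------------------------------------------
# training configuration

@dataclass
class TrainConfig:
    """Knobs of the repeated-CV grid search.

    Defaults follow the reference workflow (5-fold CV with 20 repeats and a
    tune length of 20, reduced to 5 for gradient-boosted trees; regression
    halves repeats and tune length); scale them down for quick runs.
    """

    n_folds: int = 5
    n_repeats: int = 20
    tune_length: int = 20
    xgb_tune_length: int = 5
    downsample: bool = True
    n_estimators: int = 300

    @classmethod
    def quick(cls) -> "TrainConfig":
        return cls(n_folds=5, n_repeats=2, tune_length=3, xgb_tune_length=2,
                   n_estimators=150)


@dataclass
class ThresholdModelBundle:
    """Everything needed to apply one threshold model to new formulations."""

    threshold_id: str  # e.g. "LC40"
    family: str
    subset: str
    preprocessor: Preprocessor
    selected_features: List[str]
    model: object
    cv_metrics: MetricsSet
    best_params: Dict
    ad_model: Optional[ADModel] = None
    seed: int = 0

    def decision(self, frame: pd.DataFrame) -> np.ndarray:
        """Preprocess -> select -> classify; returns boolean predictions."""
        Xp = self.preprocessor.transform(frame)[self.selected_features].to_numpy()
        return np.asarray(self.model.predict(Xp)).astype(bool)

    def ad_distances(self, frame: pd.DataFrame) -> np.ndarray:
        if self.ad_model is None:
            raise PipelineError("bundle has no applicability-domain model")
        from .domain import knn_distances
        Xp = self.preprocessor.transform(frame)[self.selected_features].to_numpy()
        return knn_distances(Xp, self.ad_model)

    # persistence: model binary (joblib) + human-readable JSON metadata
    def save(self, directory) -> None:
        import json
        import os
        import joblib
        os.makedirs(directory, exist_ok=True)
        joblib.dump({"model": self.model, "preprocessor": self.preprocessor,
                     "ad_model": self.ad_model}, os.path.join(directory, "model.joblib"))
        meta = {
            "threshold_id": self.threshold_id,
            "family": self.family,
            "subset": self.subset,
            "selected_features": self.selected_features,
            "best_params": self.best_params,
            "seed": self.seed,
            "dropped_features": self.preprocessor.spec.dropped_features,
            "cv_metrics": {k: getattr(self.cv_metrics, k)
                           for k in ("AUC", "nMCC", "Acc", "Sens", "Spec",
                                     "F1", "PPV", "NPV")},
            "ad": None if self.ad_model is None else {
                "k": self.ad_model.k, "z": self.ad_model.z,
                "mean_distance": self.ad_model.mean_distance,
                "sd": self.ad_model.sd, "cutoff": self.ad_model.cutoff},
        }
        with open(os.path.join(directory, "metadata.json"), "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, directory) -> "ThresholdModelBundle":
        import json
        import os
        import joblib
        blob = joblib.load(os.path.join(directory, "model.joblib"))
        with open(os.path.join(directory, "metadata.json")) as fh:
            meta = json.load(fh)
        metrics = classification_metrics(1, 1, 0, 0)  # placeholder shape
        for k, v in meta["cv_metrics"].items():
            setattr(metrics, k, v)
        return cls(threshold_id=meta["threshold_id"], family=meta["family"],
                   subset=meta["subset"], preprocessor=blob["preprocessor"],
                   selected_features=meta["selected_features"], model=blob["model"],
                   cv_metrics=metrics, best_params=meta["best_params"],
                   ad_model=blob["ad_model"], seed=meta["seed"])


@dataclass
class ThresholdClassifierResults:
    """Fit result: bundle + diagnostics, statsmodels-style summary()."""

    bundle: ThresholdModelBundle
    cv_metrics: MetricsSet
    grid_results: List[Tuple[Dict, float]]
    n_obs: int
    n_features_in: int

    def summary(self) -> str:
        b = self.bundle
        m = self.cv_metrics
        lines = [
            f"Threshold classifier {b.threshold_id} [{b.family}, subset={b.subset}]",
            f"  observations: {self.n_obs}   features in: {self.n_features_in}"
            f" -> retained: {len(b.preprocessor.spec.retained)}"
            f" -> selected: {len(b.selected_features)}",
            f"  best params: {b.best_params}",
            "  repeated-CV metrics (mean over folds):",
        ]
        for attr in ("AUC", "nMCC", "Acc", "Sens", "Spec", "F1", "PPV", "NPV"):
            v = getattr(m, attr)
            lines.append(f"    {attr:>5s}: {'  --' if v is None else f'{v:0.3f}'}")
        return "\n".join(lines)

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        return self.bundle.decision(frame)


class ThresholdClassifier:
    """Binary threshold model (e.g. LC >= 40 %) over mixture features."""

    def __init__(self, X: pd.DataFrame, y: Sequence[bool], family: str = "RF",
                 threshold_id: str = "LC10", subset: str = "",
                 config: Optional[TrainConfig] = None):
        if family not in CLASSIFIER_FAMILIES:
            raise ValueError(f"unknown classifier family {family!r}")
        self.X = X.reset_index(drop=True)
        self.y = np.asarray(y, dtype=int)
        if set(np.unique(self.y)) != {0, 1}:
            raise PipelineError("labels must contain both classes")
        self.family = family
        self.threshold_id = threshold_id
        self.subset = subset
        self.config = config or TrainConfig()

    def fit(self, seed: int = 0, run_boruta: bool = True,
            fit_ad_model: bool = True, ad_k: int = 5, ad_z: float = 0.5
            ) -> ThresholdClassifierResults:
        cfg = self.config
        pre = Preprocessor().fit(self.X)
        Xp = pre.transform(self.X)
        if run_boruta:
            selected = boruta_select(Xp, self.y, seed=seed, task="classification",
                                     n_estimators=min(cfg.n_estimators, 300))
        else:
            selected = list(Xp.columns)
        Xs = Xp[selected].to_numpy()
        y = self.y

        n_min = min(np.bincount(y))
        folds = cfg.n_folds
        if n_min < folds:
            folds = max(2, n_min)

        tl = cfg.xgb_tune_length if self.family == "XGB" else cfg.tune_length
        grid = _classifier_grid(self.family, tl, Xs.shape[1], seed)
        splitter = RepeatedStratifiedKFold(
            n_splits=folds, n_repeats=cfg.n_repeats, random_state=seed)
        split_list = list(splitter.split(Xs, y))

        grid_results: List[Tuple[Dict, float]] = []
        best: Tuple[Optional[Dict], float, List[MetricsSet]] = (None, -np.inf, [])
        for params in grid:
            fold_metrics: List[MetricsSet] = []
            aucs: List[float] = []
            for fold_i, (tr, te) in enumerate(split_list):
                rng = np.random.default_rng((seed, fold_i, 17))
                Xtr, ytr = Xs[tr], y[tr]
                if cfg.downsample:
                    Xtr, ytr = _downsample(Xtr, ytr, rng)
                model = _make_classifier(self.family, params, seed,
                                         n_estimators=cfg.n_estimators)
                model.fit(Xtr, ytr)
                pred = np.asarray(model.predict(Xs[te])).astype(int)
                yt = y[te]
                tp = int(np.sum((pred == 1) & (yt == 1)))
                tn = int(np.sum((pred == 0) & (yt == 0)))
                fp = int(np.sum((pred == 1) & (yt == 0)))
                fn = int(np.sum((pred == 0) & (yt == 1)))
                auc = None
                if len(np.unique(yt)) == 2:
                    auc = float(roc_auc_score(yt, _scores(model, Xs[te])))
                    aucs.append(auc)
                fold_metrics.append(classification_metrics(tp, tn, fp, fn, auc=auc))
            mean_auc = float(np.mean(aucs)) if aucs else -np.inf
            grid_results.append((params, mean_auc))
            if mean_auc > best[1]:
                best = (params, mean_auc, fold_metrics)

        best_params, _, best_folds = best
        if best_params is None:
            raise PipelineError("grid search failed to score any configuration")
        cv_metrics = _mean_metrics(best_folds)

        rng = np.random.default_rng((seed, 10_007))
        Xfit, yfit = (Xs, y)
        if cfg.downsample:
            Xfit, yfit = _downsample(Xs, y, rng)
        final = _make_classifier(self.family, best_params, seed,
                                 n_estimators=cfg.n_estimators)
        final.fit(Xfit, yfit)

        ad = None
        if fit_ad_model and Xs.shape[0] > ad_k:
            ad = fit_ad(Xs, k=ad_k, z=ad_z)

        bundle = ThresholdModelBundle(
            threshold_id=self.threshold_id, family=self.family, subset=self.subset,
            preprocessor=pre, selected_features=selected, model=final,
            cv_metrics=cv_metrics, best_params=best_params, ad_model=ad, seed=seed)
        return ThresholdClassifierResults(
            bundle=bundle, cv_metrics=cv_metrics, grid_results=grid_results,
            n_obs=len(y), n_features_in=self.X.shape[1])


@dataclass
class RegressionResults:
    model: object
    preprocessor: Preprocessor
    selected_features: List[str]
    best_params: Dict
    cv_rmse: float
    cv_mae: float
    cv_r2: float
    grid_results: List[Tuple[Dict, float]]

    def summary(self) -> str:
        return (f"Regression [{type(self.model).__name__}] "
                f"RMSE_CV={self.cv_rmse:0.4f} MAE_CV={self.cv_mae:0.4f} "
                f"R2_CV={self.cv_r2:0.4f} params={self.best_params}")

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        Xp = self.preprocessor.transform(frame)[self.selected_features].to_numpy()
        return np.asarray(self.model.predict(Xp)).ravel()


class ThresholdRegressor:
    """Continuous LC/LE regression with the same preprocessing scaffolding."""

    def __init__(self, X: pd.DataFrame, y: Sequence[float], family: str = "RF",
                 config: Optional[TrainConfig] = None):
        if family not in REGRESSOR_FAMILIES:
            raise ValueError(f"unknown regressor family {family!r}")
        self.X = X.reset_index(drop=True)
        self.y = np.asarray(y, dtype=float)
        cfg = config or TrainConfig(n_repeats=10, tune_length=10, xgb_tune_length=3,
                                    downsample=False)
        cfg.downsample = False
        self.family = family
        self.config = cfg

    def fit(self, seed: int = 0, run_boruta: bool = False) -> RegressionResults:
        cfg = self.config
        pre = Preprocessor().fit(self.X)
        Xp = pre.transform(self.X)
        if run_boruta:
            selected = boruta_select(Xp, self.y, seed=seed, task="regression",
                                     n_estimators=min(cfg.n_estimators, 300))
        else:
            selected = list(Xp.columns)
        Xs = Xp[selected].to_numpy()
        y = self.y
        grid = _regressor_grid(self.family, cfg.tune_length, Xs.shape[1])
        splitter = RepeatedKFold(n_splits=cfg.n_folds, n_repeats=cfg.n_repeats,
                                 random_state=seed)
        split_list = list(splitter.split(Xs))
        results = []
        best = (None, np.inf, None)
        for params in grid:
            sq, ab, preds_all, y_all = [], [], [], []
            for tr, te in split_list:
                model = _make_regressor(self.family, params, seed,
                                        n_estimators=cfg.n_estimators)
                model.fit(Xs[tr], y[tr])
                pred = np.asarray(model.predict(Xs[te])).ravel()
                sq.extend((pred - y[te]) ** 2)
                ab.extend(np.abs(pred - y[te]))
                preds_all.extend(pred)
                y_all.extend(y[te])
            rmse = float(np.sqrt(np.mean(sq)))
            results.append((params, rmse))
            if rmse < best[1]:
                ss_res = float(np.sum((np.array(y_all) - np.array(preds_all)) ** 2))
                ss_tot = float(np.sum((np.array(y_all) - np.mean(y_all)) ** 2))
                r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
                best = (params, rmse, (float(np.mean(ab)), r2))
        params, rmse, (mae, r2) = best  # type: ignore[misc]
        final = _make_regressor(self.family, params, seed,
                                n_estimators=cfg.n_estimators)
        final.fit(Xs, y)
        return RegressionResults(model=final, preprocessor=pre,
                                 selected_features=selected, best_params=params,
                                 cv_rmse=rmse, cv_mae=mae, cv_r2=r2,
                                 grid_results=results)


# ---------------------------------------------------------------------------
# Y-randomization

def y_randomize(
    X: pd.DataFrame,
    y: Sequence[bool],
    family: str = "RF",
    config: Optional[TrainConfig] = None,
    n_rounds: int = 10,
    seed: int = 0,
    run_boruta: bool = False,
) -> List[MetricsSet]:
    """Refit the whole pipeline on label permutations (chance baseline)."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=int)
    out: List[MetricsSet] = []
    for r in range(n_rounds):
        yperm = rng.permutation(y)
        if len(np.unique(yperm)) < 2:
            continue
        model = ThresholdClassifier(X, yperm, family=family,
                                    threshold_id="Yrand", config=config)
        res = model.fit(seed=int(rng.integers(0, 2**31 - 1)), run_boruta=run_boruta,
                        fit_ad_model=False)
        out.append(res.cv_metrics)
    return out
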