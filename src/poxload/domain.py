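"""Distance-based applicability domain in the scaled descriptor space.

A query is inside the domain when its mean Euclidean distance to the k
nearest training rows is at most ``D_cutoff = <D> + z * s``, where ``<D>``
and ``s`` are the mean and standard deviation of the same k-NN statistic over
the training rows themselves (self excluded).  Membership is inclusive at
the cutoff.  Defaults k=5, z=0.5 are the conventional choices in the
nearest-neighbor AD literature; both are stored with the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["ADModel", "fit_ad", "in_domain", "knn_distances"]


@dataclass
class ADModel:
    reference: np.ndarray  # scaled TS feature rows
    k: int
    z: float
    mean_distance: float
    sd: float
    cutoff: float

    def __post_init__(self):
        if self.reference.ndim != 2:
            raise ValueError("reference matrix must be 2-D")


def fit_ad(ts_matrix: np.ndarray, k: int = 5, z: float = 0.5) -> ADModel:
    """Fit the k-NN distance cutoff on the (scaled) training matrix."""
    X = np.asarray(ts_matrix, dtype=float)
    n = X.shape[0]
    if k < 1 or k >= n:
        raise ValueError(f"k must satisfy 1 <= k < n_rows ({k} vs {n})")
    tree = cKDTree(X)
    # k+1 because the closest hit of a training row is itself
    dists, _ = tree.query(X, k=k + 1)
    mean_knn = dists[:, 1:].mean(axis=1)
    mean_d = float(mean_knn.mean())
    sd = float(mean_knn.std(ddof=1)) if n > 1 else 0.0
    return ADModel(reference=X, k=k, z=z, mean_distance=mean_d, sd=sd,
                   cutoff=mean_d + z * sd)


def knn_distances(queries: np.ndarray, ad: ADModel) -> np.ndarray:
    """Mean k-NN distance of each query row to the AD reference set."""
    Q = np.atleast_2d(np.asarray(queries, dtype=float))
    if Q.shape[1] != ad.reference.shape[1]:
        raise ValueError("query dimension does not match the AD reference")
    tree = cKDTree(ad.reference)
    dists, _ = tree.query(Q, k=ad.k)
    return np.atleast_2d(dists).reshape(Q.shape[0], ad.k).mean(axis=1)


def in_domain(query: np.ndarray, ad: ADModel) -> Tuple[bool, float]:
    """(inside?, mean k-NN distance) for one preprocessed query row."""
    dist = float(knn_distances(np.asarray(query, dtype=float).reshape(1, -1), ad)[0])
    return dist <= ad.cutoff, dist
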