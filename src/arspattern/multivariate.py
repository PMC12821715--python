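"""Sample-structure analysis: PCA and K-means in principal-component space.

Samples are the observations and proteins the variables, so PCA score plots
show replicates as points — PC1/PC2 separations then reflect treatment and
strain structure. Protein columns are re-centered across the sample subset
before the SVD (a no-op when the full autoscaled matrix is used, but
necessary when analysing a subset of samples).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from arspattern.normalization import NormalizedMatrix


@dataclass
class PcaResult:
    """Scores (sample × PC), loadings (protein × PC), variance fractions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.variance_fraction)


@dataclass
class ClusterAssignment:
    """K-means result on PCA scores."""

    k: int
    labels: pd.Series  # indexed by sample id, values in [0, k)
    inertia: float
    seed: int
    n_restarts: int


def run_pca(
    normalized: NormalizedMatrix | pd.DataFrame,
    sample_subset: Sequence[str] | None = None,
) -> PcaResult:
    """PCA of sample profiles via SVD of the centered sample × protein matrix.

    All components up to the matrix rank bound, min(n_samples − 1,
    n_proteins), are retained so variance fractions sum to 1. Component
    signs are fixed by convention: the largest-magnitude loading of each
    component is made positive, so results are deterministic.
    """
    df = normalized.data if isinstance(normalized, NormalizedMatrix) else normalized
    cols = list(df.columns) if sample_subset is None else list(sample_subset)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"samples not in matrix: {missing}")
    if len(cols) < 2:
        raise ValueError("PCA requires at least 2 samples")

    x = df[cols].to_numpy(dtype=float).T  # samples × proteins
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    n_comp = min(len(cols) - 1, df.shape[0])
    u, s, vt = u[:, :n_comp], s[:n_comp], vt[:n_comp]

    # sign convention: largest-magnitude loading positive
    for i in range(n_comp):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1

    scores = u * s
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    pc_names = [f"PC{i + 1}" for i in range(n_comp)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=cols, columns=pc_names),
        loadings=pd.DataFrame(vt.T, index=df.index, columns=pc_names),
        variance_fraction=frac,
    )


def kmeans_cluster(
    scores: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
    n_components: int | None = None,
) -> ClusterAssignment:
    """Lloyd's K-means with k-means++ seeding, best of ``n_restarts``.

    Runs on the full score matrix by default; set ``n_components=2`` to
    cluster in the PC1/PC2 plane shown in score plots.
    """
    if k < 1:
        raise ValueError("k must be ≥ 1")
    if k > scores.shape[0]:
        raise ValueError(f"k={k} exceeds n_samples={scores.shape[0]}")
    x = scores.to_numpy(dtype=float)
    if n_components is not None:
        x = x[:, :n_components]
    if not np.all(np.isfinite(x)):
        raise ValueError("scores must be finite")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(x)
    return ClusterAssignment(
        k=k,
        labels=pd.Series(labels, index=scores.index, name="cluster"),
        inertia=float(km.inertia_),
        seed=seed,
        n_restarts=n_restarts,
    )


def silhouette_scan(
    scores: pd.DataFrame,
    ks: Sequence[int] = range(2, 7),
    seed: int = 0,
    n_restarts: int = 10,
) -> pd.DataFrame:
    """Mean silhouette width for each candidate k (diagnostic only)."""
    rows = []
    x = scores.to_numpy(dtype=float)
    for k in ks:
        if k >= scores.shape[0]:
            continue
        assign = kmeans_cluster(scores, k=k, seed=seed, n_restarts=n_restarts)
        rows.append(
            {
                "k": k,
                "silhouette": float(silhouette_score(x, assign.labels.to_numpy())),
                "inertia": assign.inertia,
            }
        )
    return pd.DataFrame(rows)
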