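"""Archetype clustering and the continuous vulnerability score.

Neurons are described by ten features (variance-tuning parameters, tuning
statistics and response dynamics), z-scored, reduced to two principal
components and split with K-means (k=2).  The cluster whose centroid has the
larger mean ``b_theta_max`` (tuned up to higher input variance) is labeled
*resilient*, the other *vulnerable*.

A continuous vulnerability score recombines seven of the variables, each
min-max normalized over the population and oriented so that larger means
"more resilient", weighted by the mean absolute PC-1/PC-2 loading of the
corresponding feature.  The weighted resilience sum is subtracted from 1 and
affinely rescaled so the score runs from 0 (most resilient) to 1 (most
vulnerable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "FEATURE_COLUMNS",
    "SCORE_VARIABLES",
    "FeatureMatrix",
    "ClusterModel",
    "assemble_features",
    "cluster",
    "vulnerability_score",
]

#: Fixed feature column order ("low"/"high" = lowest / highest grid b_theta).
FEATURE_COLUMNS = [
    "log_n", "b_theta50", "f0", "b_theta_max", "cv_low", "cv_high",
    "early_late_low", "early_late_high", "delay_low", "delay_high",
]

#: Score variables -> (feature column for the PCA weight, sign of the
#: resilience direction: +1 if larger values mean more resilient).
SCORE_VARIABLES = {
    "b_theta50": ("b_theta50", +1),
    "log_n": ("log_n", -1),
    "f0": ("f0", -1),
    "b_theta_max": ("b_theta_max", +1),
    "cv": ("cv_low", -1),
    "early_late_ratio": ("early_late_low", +1),
    "delay": ("delay_low", +1),
}


@dataclass
class FeatureMatrix:
    raw: pd.DataFrame  # imputed, original units
    z: pd.DataFrame  # standardized copy
    columns: list = field(default_factory=lambda: list(FEATURE_COLUMNS))


@dataclass
class ClusterModel:
    loadings: np.ndarray  # (2, n_features)
    explained_variance: np.ndarray  # fractions, (2,)
    pc_scores: np.ndarray  # (n_neurons, 2)
    centroids: np.ndarray  # (2, 2) in PC space
    labels: np.ndarray  # "vulnerable" | "resilient" per neuron
    wcss: np.ndarray  # within-cluster sum of squares, k = 1..8
    weights: dict  # score-variable weights, sum to 1
    columns: list


def assemble_features(summary_table: pd.DataFrame,
                      max_missing_frac: float = 0.2) -> FeatureMatrix:
    """Build the standardized feature matrix from a neuron summary table.

    Missing (flagged-undefined) entries are imputed with the column median;
    any column with more than ``max_missing_frac`` missing raises.  Constant
    columns z-score to 0 with a warning.
    """
    missing = [c for c in FEATURE_COLUMNS if c not in summary_table.columns]
    if missing:
        raise ValueError(f"summary table lacks feature columns: {missing}")
    raw = summary_table[FEATURE_COLUMNS].astype(float).copy()
    frac = raw.isna().mean()
    bad = frac[frac > max_missing_frac]
    if len(bad):
        raise ValueError(
            "too many missing values in columns: "
            + ", ".join(f"{c} ({f:.0%})" for c, f in bad.items()))
    raw = raw.fillna(raw.median())
    sd = raw.std(ddof=0)
    const = sd[sd == 0].index.tolist()
    if const:
        warnings.warn(f"constant feature columns z-scored to 0: {const}")
    z = (raw - raw.mean()) / sd.replace(0.0, 1.0)
    return FeatureMatrix(raw=raw, z=z)


def cluster(features: FeatureMatrix, k: int = 2, seed: int = 0,
            n_init: int = 50, k_range=range(1, 9)) -> ClusterModel:
    """PCA (2 components) -> K-means split with a deterministic label rule."""
    X = features.z.to_numpy()
    if X.shape[0] < 2 * k:
        raise ValueError("need at least 2k neurons")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("degenerate feature matrix: all neurons identical")
    pca = PCA(n_components=2, random_state=seed)
    scores = pca.fit_transform(X)

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(scores)
    wcss = np.array([
        KMeans(n_clusters=kk, n_init=n_init, random_state=seed)
        .fit(scores).inertia_
        for kk in k_range])

    # label identity: centroid with larger mean b_theta_max -> resilient
    bmax = features.raw["b_theta_max"].to_numpy()
    means = [bmax[km.labels_ == c].mean() for c in range(k)]
    resilient_cluster = int(np.argmax(means))
    labels = np.where(km.labels_ == resilient_cluster, "resilient",
                      "vulnerable")

    loadings = pca.components_
    weights = {}
    for var, (col, _sign) in SCORE_VARIABLES.items():
        j = FEATURE_COLUMNS.index(col)
        weights[var] = float(np.mean(np.abs(loadings[:, j])))
    total = sum(weights.values())
    weights = {v: w / total for v, w in weights.items()}

    return ClusterModel(
        loadings=loadings,
        explained_variance=pca.explained_variance_ratio_,
        pc_scores=scores, centroids=km.cluster_centers_, labels=labels,
        wcss=wcss, weights=weights, columns=list(features.columns))


def vulnerability_score(features: FeatureMatrix,
                        weights: dict | None = None,
                        model: ClusterModel | None = None) -> np.ndarray:
    """Continuous score in [0, 1]: 0 most resilient, 1 most vulnerable.

    Each score variable is min-max normalized over the population and
    oriented toward resilience; the weighted sum is subtracted from 1 and
    affinely rescaled to [0, 1].  Min-max normalization makes the score
    invariant to affine rescaling of any input column.
    """
    if weights is None:
        if model is None:
            raise ValueError("provide weights or a fitted ClusterModel")
        weights = model.weights
    raw = features.raw
    resilience = np.zeros(len(raw))
    for var, (col, sign) in SCORE_VARIABLES.items():
        x = raw[col].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"score undefined: missing values in {col}")
        rng = x.max() - x.min()
        xn = (x - x.min()) / rng if rng > 0 else np.zeros_like(x)
        term = xn if sign > 0 else 1.0 - xn
        resilience = resilience + weights[var] * term
    score = 1.0 - resilience
    lo, hi = score.min(), score.max()
    return (score - lo) / (hi - lo) if hi > lo else np.zeros_like(score)
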