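"""PCA + k-means segregation of firing phenotypes.

The nine per-neuron features are median-imputed, z-scored, projected with
PCA (deterministic sign convention), clustered into k = 8 groups with
restarted k-means, and each group is mapped to a low / intermediate / high
firing (LF/IF/HF) class from its median burst count and inter-burst
interval: HF groups burst ≥ 40 times per recording or have IBI ≤ 16 s, LF
groups burst ≤ 7 times or have IBI > 40 s, the rest are IF.  Per-feature
contributions to a principal component are the squared loadings of that
component, normalized to 100%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .burst_features import FEATURE_NAMES, GroupSummary, FeatureVector, summarize_group
from .errors import InputError, ParameterError

__all__ = [
    "PCAModel",
    "ClusterAssignment",
    "PhenotypeReport",
    "ClassThresholds",
    "impute_median",
    "fit_pca",
    "pc_contributions",
    "kmeans_cluster",
    "classify_groups",
]


@dataclass(frozen=True)
class PCAModel:
    """Fitted PCA basis: centering/scaling, loadings and explained variance."""

    mean: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # (n_features, n_components), columns orthonormal
    explained_variance_ratio: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, x: np.ndarray) -> np.ndarray:
        return ((np.asarray(x, float) - self.mean) / self.scale) @ self.loadings

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        """Back to the standardized feature space (all components → exact)."""
        return np.asarray(scores, float) @ self.loadings.T


@dataclass(frozen=True)
class ClusterAssignment:
    """k-means result: 1-based group labels, centroids in PC space, inertia."""

    labels: np.ndarray
    k: int
    centroids: np.ndarray
    inertia: float
    seed: int = 0


@dataclass(frozen=True)
class ClassThresholds:
    """Group→class decision thresholds (bursts per recording; IBI seconds)."""

    hf_min_bursts: float = 40.0
    hf_max_ibi_s: float = 16.0
    lf_max_bursts: float = 7.0
    lf_min_ibi_s: float = 40.0


@dataclass
class PhenotypeReport:
    """Clustered-population report: group stats, group→class map, fractions."""

    assignment: ClusterAssignment
    group_summaries: dict[int, GroupSummary]
    group_class: dict[int, str]
    class_fractions: dict[str, float]
    pca: PCAModel | None = None
    thresholds: ClassThresholds = field(default_factory=ClassThresholds)

    def to_json(self, path=None) -> str:
        payload = {
            "k": self.assignment.k,
            "seed": self.assignment.seed,
            "inertia": self.assignment.inertia,
            "group_class": {str(g): c for g, c in self.group_class.items()},
            "class_fractions": self.class_fractions,
            "group_summaries": {
                str(g): s.table.to_dict(orient="index") for g, s in self.group_summaries.items()
            },
            "thresholds": vars(self.thresholds),
        }
        if self.pca is not None:
            payload["pca"] = {
                "feature_names": list(self.pca.feature_names),
                "loadings": self.pca.loadings.tolist(),
                "explained_variance_ratio": self.pca.explained_variance_ratio.tolist(),
                "pc_contributions_pct": [
                    pc_contributions(self.pca, i).tolist()
                    for i in range(self.pca.n_components)
                ],
            }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def impute_median(x: np.ndarray) -> np.ndarray:
    """Replace NaNs with the per-feature (column) median of the finite values."""
    x = np.array(x, dtype=float, copy=True)
    finite_cols = ~np.all(np.isnan(x), axis=0)
    med = np.zeros(x.shape[1])
    med[finite_cols] = np.nanmedian(x[:, finite_cols], axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    idx = np.where(np.isnan(x))
    x[idx] = np.take(med, idx[1])
    return x


def fit_pca(
    features: np.ndarray | pd.DataFrame,
    standardize: bool = True,
    feature_names: tuple[str, ...] | None = None,
) -> tuple[PCAModel, np.ndarray]:
    """Fit PCA to a (neurons × features) matrix; returns model and scores.

    Missing values must be imputed beforehand (see :func:`impute_median`).
    Data are centered and, by default, z-scored; components are sorted by
    descending eigenvalue with a deterministic sign convention (the
    largest-magnitude loading of each component is positive).  Constant
    features get unit scale; all-constant data is degenerate.
    """
    if isinstance(features, pd.DataFrame):
        feature_names = feature_names or tuple(features.columns)
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        feature_names = feature_names or tuple(f"f{i}" for i in range(x.shape[1]))
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ParameterError("PCA requires at least 2 neurons and 2 features")
    if np.isnan(x).any():
        raise InputError("impute missing values before PCA")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if not np.any(sd > 0):
        raise ParameterError("rank-0 data: every feature is constant")
    scale = np.where(sd > 0, sd, 1.0) if standardize else np.ones_like(sd)
    z = (x - mean) / scale

    n_comp = min(z.shape)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(z)
    loadings = pca.components_.T.copy()  # (features, components)
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    model = PCAModel(
        mean=mean, scale=scale, loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        feature_names=feature_names,
    )
    return model, scores


def pc_contributions(model: PCAModel, pc_index: int) -> np.ndarray:
    """Per-feature contribution (%) to one PC: 100·loadingᵢ²/Σⱼ loadingⱼ²."""
    if not 0 <= pc_index < model.n_components:
        raise IndexError(f"pc_index {pc_index} out of range (0..{model.n_components - 1})")
    col = model.loadings[:, pc_index]
    return 100.0 * col**2 / np.sum(col**2)


def kmeans_cluster(
    scores: np.ndarray, k: int = 8, n_restarts: int = 50, seed: int = 0
) -> ClusterAssignment:
    """Best-of-restarts Lloyd's k-means on PC scores (squared Euclidean).

    Deterministic for a fixed seed; labels are 1-based group ids.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < k:
        raise ParameterError(f"need at least k={k} neurons, got {x.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(x)
    return ClusterAssignment(
        labels=labels + 1, k=k, centroids=km.cluster_centers_.copy(),
        inertia=float(km.inertia_), seed=seed,
    )


def classify_groups(
    assignment: ClusterAssignment,
    features: pd.DataFrame,
    thresholds: ClassThresholds = ClassThresholds(),
    pca: PCAModel | None = None,
) -> PhenotypeReport:
    """Map k-means groups to LF/IF/HF classes and report group statistics.

    Each group's median burst count and median IBI drive the mapping (HF
    first, then LF, else IF).  A group whose members never burst (median
    burst count 0 and no defined IBI) falls back to population spike-count
    tertiles of the group median.  Class fractions are over all clustered
    (active) neurons and sum to 1.
    """
    if len(features) != assignment.labels.size:
        raise InputError("features and assignment must cover the same neurons")
    labels = assignment.labels
    ns_all = features["n_spikes"].to_numpy(dtype=float)
    tertiles = np.percentile(ns_all, [100 / 3, 200 / 3]) if ns_all.size else (0, 0)

    group_summaries: dict[int, GroupSummary] = {}
    group_class: dict[int, str] = {}
    for g in range(1, assignment.k + 1):
        rows = features.iloc[np.flatnonzero(labels == g)]
        if rows.empty:
            continue
        group_summaries[g] = summarize_group(rows[list(FEATURE_NAMES)])
        med_b = float(rows["n_bursts"].median())
        ibi_defined = rows["ibi_s"].dropna()
        med_ibi = float(ibi_defined.median()) if len(ibi_defined) else float("nan")
        if np.isnan(med_ibi) and med_b == 0:
            med_ns = float(rows["n_spikes"].median())
            cls = "LF" if med_ns <= tertiles[0] else ("IF" if med_ns <= tertiles[1] else "HF")
        elif med_b >= thresholds.hf_min_bursts or (
            not np.isnan(med_ibi) and med_ibi <= thresholds.hf_max_ibi_s
        ):
            cls = "HF"
        elif med_b <= thresholds.lf_max_bursts or (
            not np.isnan(med_ibi) and med_ibi > thresholds.lf_min_ibi_s
        ):
            cls = "LF"
        else:
            cls = "IF"
        group_class[g] = cls

    n_total = labels.size
    class_fractions = {
        cls: float(np.sum([np.sum(labels == g) for g, c in group_class.items() if c == cls]))
        / n_total
        for cls in ("LF", "IF", "HF")
    }
    return PhenotypeReport(
        assignment=assignment,
        group_summaries=group_summaries,
        group_class=group_class,
        class_fractions=class_fractions,
        pca=pca,
        thresholds=thresholds,
    )
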