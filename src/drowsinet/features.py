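"""Feature-space diagnostics: PCA views and the KNN-Sigma curve.

Features are the post-activation outputs of the 512-unit dense layer, one
row per frame. Two complementary views of their geometry:

* **PCA projection** (3 components) for visual inspection — drowsy red,
  alert blue;
* **KNN-Sigma**: leave-one-out k-nearest-neighbor classification accuracy
  traced over k expressed as a percentage of the sample size. Accuracy at
  *small* k measures homogeneous concentration (tight same-class
  neighborhoods); accuracy at *large* k measures heterogeneous separation
  (classes still distinguishable when the neighborhood spans most of the
  data). The curve's mean over the grid is reported as a one-number summary.

The neighborhood is the *extended* k-nearest set: all points (excluding the
query) whose Euclidean distance does not exceed the k-th-nearest distance —
distance ties are all included, so the set can hold more than k points.
Majority-vote ties break deterministically toward the lower class index and
are counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .nn import Network

__all__ = [
    "FeatureMatrix",
    "PCAProjection",
    "KNNSigmaCurve",
    "extract_features",
    "pca_project",
    "extended_knn",
    "knn_classify",
    "knn_sigma_curve",
    "plot_feature_cloud",
]

CLASS_COLORS = {"alert": "tab:blue", "drowsy": "tab:red"}


@dataclass
class FeatureMatrix:
    features: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,) strings or ints
    subject_ids: np.ndarray  # (n,)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        n = self.features.shape[0]
        if n < 2 or self.labels.shape[0] != n or self.subject_ids.shape[0] != n:
            raise ValueError("features, labels and subject_ids must align, n >= 2")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")

    def to_frame(self) -> pd.DataFrame:
        d = self.features.shape[1]
        df = pd.DataFrame(self.features, columns=[f"f{i}" for i in range(d)])
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        fcols = [c for c in df.columns if c.startswith("f")]
        return cls(df[fcols].to_numpy(), df["label"].to_numpy(), df["subject_id"].to_numpy())


@dataclass
class PCAProjection:
    components: np.ndarray  # (3, d) orthonormal rows
    projected: np.ndarray  # (n, 3) scores
    eigenvalues: np.ndarray  # (3,) descending explained variances


@dataclass
class KNNSigmaCurve:
    k_percent_grid: np.ndarray  # strictly increasing, in (0, 100]
    accuracy_at_k: np.ndarray  # percent, aligned with the grid
    summary_P: float  # mean of accuracy_at_k over the grid
    n_tie_events: int  # majority-vote ties resolved by the class-index rule

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k_percent": self.k_percent_grid,
                             "accuracy": self.accuracy_at_k})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def extract_features(network: Network, x: np.ndarray, labels, subject_ids,
                     batch_size: int = 64, layer: str = "dense512") -> FeatureMatrix:
    """Per-frame deep features.

    ``layer="dense512"`` (default) takes the 512-unit dense layer's
    post-LeakyReLU activations — the 2-unit logit layer (``layer="logits"``)
    would make a 3-component PCA degenerate, but is available for
    comparison.
    """
    if layer not in ("dense512", "logits"):
        raise ValueError(f"unknown feature layer {layer!r}")
    feats = []
    for i in range(0, x.shape[0], batch_size):
        logits = network.forward(x[i : i + batch_size], training=False)
        if layer == "logits":
            feats.append(logits.copy())
            continue
        if network.fc1_activation is None:
            raise RuntimeError("network exposes no dense-layer activation")
        feats.append(network.fc1_activation.copy())
    return FeatureMatrix(np.concatenate(feats), np.asarray(labels), np.asarray(subject_ids))


def pca_project(features: np.ndarray | FeatureMatrix, n_components: int = 3) -> PCAProjection:
    """Top principal directions of the (mean-centered) features.

    Components are orthonormal; eigenvalues (explained variances) descend.
    """
    x = features.features if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    n, d = x.shape
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    if d < n_components:
        raise ValueError(f"need at least {n_components} feature dimensions, got {d}")
    pca = PCA(n_components=n_components, svd_solver="full")
    projected = pca.fit_transform(x)
    return PCAProjection(
        components=pca.components_,
        projected=projected,
        eigenvalues=pca.explained_variance_,
    )


def _pairwise_distances(x: np.ndarray) -> np.ndarray:
    # plain row-wise norms (not the gram-matrix identity): the extended
    # neighborhood's tie semantics needs exact distance equality for exactly
    # tied point pairs, which the algebraically rearranged form loses
    n = x.shape[0]
    out = np.empty((n, n), dtype=float)
    for i in range(n):
        out[i] = np.linalg.norm(x - x[i], axis=1)
    return out


def extended_knn(query: int, features: np.ndarray, k: int,
                 distances: np.ndarray | None = None) -> np.ndarray:
    """Indices of the extended k-nearest neighborhood of point ``query``.

    All other points whose distance to the query is at most the k-th-nearest
    distance; ties at that threshold are all included, so the result has at
    least ``k`` members. The query itself is excluded (leave-one-out).
    """
    x = np.asarray(features, dtype=float)
    n = x.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    if distances is None:
        d = np.linalg.norm(x - x[query], axis=1)
    else:
        d = distances[query]
    d = d.copy()
    d[query] = np.inf
    eps_k = np.partition(d, k - 1)[k - 1]  # k-th nearest distance
    idx = np.nonzero(d <= eps_k)[0]
    return idx


def knn_classify(neighbor_labels: np.ndarray) -> tuple[int, bool]:
    """Majority vote over integer-coded neighbor labels.

    Returns ``(class, tied)``; an exact tie resolves to the lower class index.
    """
    labels = np.asarray(neighbor_labels)
    if labels.size == 0:
        raise ValueError("neighborhood must be non-empty")
    counts = np.bincount(labels)
    winners = np.nonzero(counts == counts.max())[0]
    return int(winners[0]), len(winners) > 1


def knn_sigma_curve(features: np.ndarray | FeatureMatrix,
                    labels: np.ndarray | None = None,
                    grid_resolution: float = 1.0) -> KNNSigmaCurve:
    """Leave-one-out extended-k-NN accuracy across k percentages.

    The grid runs from ``grid_resolution`` to 100 in steps of
    ``grid_resolution``; each percentage maps to
    ``k = max(1, round(pct/100 * (n-1)))``. ``summary_P`` is the curve mean.
    """
    if isinstance(features, FeatureMatrix):
        labels = features.labels if labels is None else labels
        features = features.features
    x = np.asarray(features, dtype=float)
    n = x.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")
    classes, y = np.unique(np.asarray(labels), return_inverse=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")

    grid = np.arange(grid_resolution, 100.0 + 1e-9, grid_resolution)
    ks = np.maximum(1, np.rint(grid / 100.0 * (n - 1)).astype(int))
    dist = _pairwise_distances(x)
    # per point: neighbor labels sorted by distance, plus tie-aware cutoffs
    order = np.argsort(dist + np.where(np.eye(n, dtype=bool), np.inf, 0.0), axis=1,
                       kind="stable")
    sorted_d = np.take_along_axis(dist, order, axis=1)  # column n-1 is inf-distance self
    acc_by_k: dict[int, float] = {}
    ties = 0
    for k in np.unique(ks):
        correct = 0
        for i in range(n):
            eps_k = sorted_d[i, k - 1]
            # tie-aware cutoff: all points within eps_k (self excluded via inf)
            m = int(np.searchsorted(sorted_d[i, : n - 1], eps_k, side="right"))
            vote, tied = knn_classify(y[order[i, :m]])
            ties += tied
            correct += vote == y[i]
        acc_by_k[k] = 100.0 * correct / n
    accuracy = np.array([acc_by_k[k] for k in ks])
    return KNNSigmaCurve(
        k_percent_grid=grid,
        accuracy_at_k=accuracy,
        summary_P=float(accuracy.mean()),
        n_tie_events=ties,
    )


def plot_feature_cloud(projection: PCAProjection, labels, ax=None):
    """3-D scatter of the projected features, drowsy red / alert blue."""
    import matplotlib.pyplot as plt

    if ax is None:
        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(111, projection="3d")
    labels = np.asarray(labels)
    pts = projection.projected
    for cls in np.unique(labels):
        m = labels == cls
        ax.scatter(pts[m, 0], pts[m, 1], pts[m, 2], s=8,
                   c=CLASS_COLORS.get(str(cls), "gray"), label=str(cls))
    ax.set_xlabel("PC1"); ax.set_ylabel("PC2"); ax.set_zlabel("PC3")
    if labels.size:
        ax.legend()
    return ax.figure
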