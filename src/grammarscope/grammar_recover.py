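"""Reconstructing grammars from saliency profiles.

The central object is the TFBS-by-neuron :class:`~grammarscope.attribution.
SaliencyProfile`.  Reconstruction is unsupervised: k-means clusters the
rows, each cluster is labeled by the majority true grammar of its members,
and accuracy / per-grammar sensitivity quantify the recovery.  Auxiliary
tools: the neuron-by-(TF, grammar) median matrix with hierarchical
clustering for heatmaps, a top-fraction saliency filter for removing
non-grammar sites, 2-D embedding for visualization, and silhouette-based
selection of k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .attribution import SaliencyProfile


@dataclass
class MedianMatrix:
    """Median TFBS saliency per (motif, grammar) column across neurons."""

    values: np.ndarray  # neurons x columns
    columns: list[tuple[str, str]]  # (motif_id, grammar_id)
    scaled: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            columns=[f"{m}@{g}" for m, g in self.columns],
            index=[f"neuron_{i}" for i in range(self.values.shape[0])],
        )


@dataclass
class ClusterResult:
    assignments: np.ndarray
    cluster_to_grammar: dict[int, str]
    predicted: np.ndarray
    true: np.ndarray
    accuracy: float
    sensitivity: dict[str, float]
    params: dict = field(default_factory=dict)


def median_tf_grammar_matrix(profile: SaliencyProfile, scale: bool = True) -> MedianMatrix:
    """Median saliency of each (TF, grammar) pair per neuron.

    With ``scale=True`` columns are z-scored (population sd) so that the
    neurons most responsive to each TF stand out; constant columns map to
    zero.
    """
    df = profile.meta
    keys = list(zip(df["motif_id"], df["grammar_id"]))
    uniq: list[tuple[str, str]] = []
    seen = set()
    for kk in keys:
        if kk not in seen:
            seen.add(kk)
            uniq.append(kk)
    cols = []
    kept = []
    for kk in uniq:
        mask = np.array([k == kk for k in keys])
        if not mask.any():
            warnings.warn(f"(motif, grammar) pair {kk} has no rows; column omitted")
            continue
        cols.append(np.median(profile.values[mask], axis=0))
        kept.append(kk)
    mat = np.stack(cols, axis=1)  # neurons x columns
    if scale:
        mu = mat.mean(axis=0)
        sd = mat.std(axis=0)
        mat = np.where(sd > 0, (mat - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    return MedianMatrix(mat, kept, scaled=scale)


def hierarchical_cluster(
    mat: MedianMatrix, k_rows: int, k_cols: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Ward/Euclidean agglomerative clustering of rows and columns.

    Returns (row_groups, col_groups, row_leaf_order, col_leaf_order); the
    leaf orders are for heatmap rendering.
    """
    if k_rows > mat.values.shape[0] or k_cols > mat.values.shape[1]:
        raise ValueError("k exceeds matrix dimension")
    zr = linkage(mat.values, method="ward")
    zc = linkage(mat.values.T, method="ward")
    row_groups = fcluster(zr, t=k_rows, criterion="maxclust")
    col_groups = fcluster(zc, t=k_cols, criterion="maxclust")
    return row_groups, col_groups, leaves_list(zr), leaves_list(zc)


def filter_top_fraction(profile: SaliencyProfile, q: float) -> tuple[SaliencyProfile, np.ndarray]:
    """Keep the ceil(q*n) rows with the largest row sums of saliency.

    Ties are broken by original row order.  Returns the filtered profile
    and the boolean keep-mask over the original rows.
    """
    if not (0 < q <= 1):
        raise ValueError("q must be in (0, 1]")
    n = len(profile)
    if n == 0:
        raise ValueError("empty profile")
    keep_n = int(np.ceil(q * n))
    sums = profile.values.sum(axis=1)
    order = np.argsort(-sums, kind="stable")
    mask = np.zeros(n, dtype=bool)
    mask[order[:keep_n]] = True
    filtered = SaliencyProfile(
        profile.values[mask], profile.meta.loc[mask].reset_index(drop=True), profile.layer
    )
    return filtered, mask


def kmeans_cluster(profile: SaliencyProfile | np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means with k-means++ initialization and 10 restarts."""
    X = profile.values if isinstance(profile, SaliencyProfile) else np.asarray(profile)
    if len(X) < k:
        raise ValueError(f"fewer rows ({len(X)}) than clusters ({k})")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(X)


def majority_vote(assignments: np.ndarray, true_grammars: np.ndarray) -> tuple[dict[int, str], np.ndarray]:
    """Map each cluster to its modal true grammar (ties: lexicographically
    smallest id) and predict every row via its cluster's grammar."""
    assignments = np.asarray(assignments)
    true_grammars = np.asarray(true_grammars)
    if len(assignments) != len(true_grammars):
        raise ValueError("assignments and truths must align")
    mapping: dict = {}
    for c in np.unique(assignments):
        labels, counts = np.unique(true_grammars[assignments == c], return_counts=True)
        best = counts.max()
        key = int(c) if np.issubdtype(np.asarray(c).dtype, np.integer) else str(c)
        mapping[key] = str(min(labels[counts == best]))

    def _key(c):
        return int(c) if np.issubdtype(np.asarray(c).dtype, np.integer) else str(c)

    predicted = np.array([mapping[_key(c)] for c in assignments])
    return mapping, predicted


def reconstruction_metrics(predicted: np.ndarray, true: np.ndarray) -> tuple[float, dict[str, float]]:
    """Overall accuracy plus per-grammar sensitivity TP/(TP+FN)."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("predicted and true must align")
    accuracy = float((predicted == true).mean())
    sens: dict[str, float] = {}
    for g in np.unique(true):
        mask = true == g
        sens[str(g)] = float((predicted[mask] == g).mean())
    return accuracy, sens


def normalize_profile_rows(values: np.ndarray) -> np.ndarray:
    """Standardize neurons (columns) and L2-normalize each TFBS row.

    Column z-scoring puts neurons on a common scale; row normalization makes
    the clustering compare the *pattern* of neuron responses rather than
    their overall magnitude (which varies with sequence-level activation
    strength).  Constant columns map to zero.
    """
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    z = np.where(sd > 0, (values - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    return z / np.where(norms == 0, 1.0, norms)


def recover_grammars(
    profile: SaliencyProfile,
    k: int = 12,
    seed: int = 0,
    filter_q: float | None = None,
    normalize: bool = True,
) -> ClusterResult:
    """Full reconstruction: optional top-fraction filter, k-means,
    majority-vote labeling, and metrics against the true grammar ids.

    With ``normalize`` (default) the profile is column-standardized and
    row-normalized before clustering (see :func:`normalize_profile_rows`);
    ``normalize=False`` clusters the raw saliency rows.
    """
    params = {"k": k, "seed": seed, "filter_q": filter_q, "normalize": normalize}
    if filter_q is not None:
        profile, _ = filter_top_fraction(profile, filter_q)
    truths = profile.meta["grammar_id"].to_numpy(dtype=object).astype(str)
    X = normalize_profile_rows(profile.values) if normalize else profile.values
    assignments = kmeans_cluster(X, k, seed)
    mapping, predicted = majority_vote(assignments, truths)
    acc, sens = reconstruction_metrics(predicted, truths)
    return ClusterResult(assignments, mapping, predicted, truths, acc, sens, params)


def embed_2d(profile: SaliencyProfile | np.ndarray, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """2-D t-SNE embedding for visualization only."""
    X = profile.values if isinstance(profile, SaliencyProfile) else np.asarray(profile)
    if len(X) < 5:
        raise ValueError("need at least 5 rows to embed")
    perp = min(perplexity, (len(X) - 1) / 3.0)
    if perp < 1:
        raise ValueError(f"too few rows for t-SNE; need > {int(3 * perplexity) + 1} or lower perplexity")
    ts = TSNE(n_components=2, perplexity=perp, random_state=seed, init="pca")
    return ts.fit_transform(X)


def select_k_silhouette(
    profile: SaliencyProfile | np.ndarray,
    k_range=range(2, 13),
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Mean silhouette (Euclidean) per k; best k = argmax, ties to smaller k.

    When all points coincide, every silhouette is 0.
    """
    X = profile.values if isinstance(profile, SaliencyProfile) else np.asarray(profile)
    scores: dict[int, float] = {}
    for k in k_range:
        if not (2 <= k <= len(X) - 1):
            raise ValueError(f"k={k} outside valid range [2, {len(X) - 1}]")
        labels = kmeans_cluster(X, k, seed)
        if len(np.unique(labels)) < 2:
            scores[k] = 0.0
            continue
        scores[k] = float(silhouette_score(X, labels, metric="euclidean"))
    best = min(scores, key=lambda k: (-scores[k], k))
    return best, scores
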