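"""Cluster-quality metrics: silhouette on an embedding and bootstrap
co-assignment probability.

Both metrics take cluster labels as given (clustering itself is a
caller-supplied contract), which makes them usable to compare labelings
produced by different modalities on the same embedding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .types import ContractError

__all__ = [
    "Embedding",
    "CoassignmentMatrix",
    "silhouette_scores",
    "bootstrap_coassignment",
    "nearest_centroid_clusterer",
]


@dataclass
class Embedding:
    """Cells in a low-dimensional Euclidean space (e.g. first 40 PCs)."""

    cell_ids: List[str]
    coordinates: np.ndarray  # cells x dims

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] < 1:
            raise ContractError("embedding must be a cells x dims matrix")
        if self.coordinates.shape[0] != len(self.cell_ids):
            raise ContractError("embedding rows must match cell_ids")
        if not np.isfinite(self.coordinates).all():
            raise ContractError("embedding contains non-finite values")


@dataclass
class CoassignmentMatrix:
    """Mean pairwise bootstrap co-assignment probability between clusters."""

    labels: List[str]
    probabilities: np.ndarray  # symmetric, in [0, 1]
    n_pairs: np.ndarray  # replicate-summed pair counts behind each entry


def silhouette_scores(
    emb: Embedding, labels: Sequence[str]
) -> Tuple[np.ndarray, pd.Series]:
    """Per-cell silhouette coefficient and per-cluster means.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean Euclidean
    distance to the cell's own cluster (excluding itself) and b(i) the
    smallest mean distance to any other cluster.  Members of singleton
    clusters get s = 0 by convention.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != len(emb.cell_ids):
        raise ContractError("labels must cover all cells")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ContractError("silhouette requires at least two clusters")
    d = cdist(emb.coordinates, emb.coordinates)
    n = d.shape[0]
    s = np.zeros(n)
    members = {lab: np.flatnonzero(labels == lab) for lab in uniq}
    for i in range(n):
        own = members[labels[i]]
        if own.size == 1:
            s[i] = 0.0
            continue
        a = d[i, own].sum() / (own.size - 1)
        b = min(d[i, members[lab]].mean() for lab in uniq if lab != labels[i])
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    per_cluster = pd.Series(
        {lab: float(s[members[lab]].mean()) for lab in uniq}, name="mean_silhouette"
    )
    return s, per_cluster


def nearest_centroid_clusterer(
    reference: Embedding, reference_labels: Sequence[str]
) -> Callable[[Embedding], np.ndarray]:
    """Reference clusterer for tests: assign each cell to the nearest
    centroid of the reference labeling (deterministic)."""
    reference_labels = np.asarray(reference_labels)
    uniq = sorted(set(reference_labels.tolist()))
    cents = np.vstack(
        [reference.coordinates[reference_labels == lab].mean(axis=0) for lab in uniq]
    )

    def cluster(emb: Embedding) -> np.ndarray:
        d = cdist(emb.coordinates, cents)
        return np.asarray(uniq, dtype=object)[d.argmin(axis=1)]

    return cluster


def bootstrap_coassignment(
    emb: Embedding,
    labels: Sequence[str],
    cluster_fn: Callable[[Embedding], np.ndarray],
    n_boot: int = 50,
    seed: int = 0,
) -> CoassignmentMatrix:
    """Bootstrap stability of a labeling under reclustering.

    Each replicate resamples cells with replacement (duplicates counted
    once per identity), reclusters the resampled embedding with
    ``cluster_fn``, and records, for every ordered-free pair of original
    clusters, the fraction of co-sampled cell pairs landing in the same
    new cluster; pairs with an absent cell are excluded from the
    replicate's denominator.  Entries average over replicates.
    """
    if n_boot < 1:
        raise ContractError("n_boot must be >= 1")
    labels = np.asarray(labels)
    n = len(emb.cell_ids)
    if labels.shape[0] != n:
        raise ContractError("labels must cover all cells")
    uniq = sorted(set(labels.tolist()))
    k = len(uniq)
    lab_idx = {lab: i for i, lab in enumerate(uniq)}
    rng = np.random.default_rng(seed)

    prob_sum = np.zeros((k, k))
    prob_n = np.zeros((k, k))
    pair_counts = np.zeros((k, k))
    for _ in range(n_boot):
        draw = rng.integers(0, n, size=n)
        present = np.unique(draw)  # each identity once
        sub = Embedding(
            [emb.cell_ids[i] for i in present], emb.coordinates[present]
        )
        new = np.asarray(cluster_fn(sub))
        if new.shape[0] != present.size:
            raise ContractError("cluster_fn returned labels of the wrong length")
        orig_idx = np.array([lab_idx[o] for o in labels[present]])
        new_codes = pd.factorize(new)[0]
        same = np.zeros((k, k))
        total = np.zeros((k, k))
        # accumulate per original-cluster-pair co-assignment over cell pairs
        ia, ib = np.triu_indices(present.size, 1)
        lo = np.minimum(orig_idx[ia], orig_idx[ib])
        hi = np.maximum(orig_idx[ia], orig_idx[ib])
        co = (new_codes[ia] == new_codes[ib]).astype(float)
        np.add.at(total, (lo, hi), 1.0)
        np.add.at(same, (lo, hi), co)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, same / np.maximum(total, 1), np.nan)
        defined = total > 0
        prob_sum[defined] += frac[defined]
        prob_n[defined] += 1
        pair_counts += total

    probs = np.full((k, k), np.nan)
    has = prob_n > 0
    probs[has] = prob_sum[has] / prob_n[has]
    # mirror the upper triangle
    iu = np.triu_indices(k, 1)
    probs[(iu[1], iu[0])] = probs[iu]
    pair_counts[(iu[1], iu[0])] = pair_counts[iu]
    return CoassignmentMatrix(labels=uniq, probabilities=probs, n_pairs=pair_counts)
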