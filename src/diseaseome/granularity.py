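"""Pathway dissection: split broad pathways into co-expressed gene sets.

Pathway databases annotate broad gene lists whose members need not behave
coherently in a given disease. Splitting works on the gene z-score rows of
each cohort:

1. Per dataset, pick k as the smallest number of k-means clusters whose
   between-cluster sum of squares explains at least ``explained_variance``
   percent of the total, then assign the pathway's genes to clusters
   (Euclidean distance; z-scores keep both magnitude and direction, so
   consistently anti-regulated genes separate).
2. Build a genes × datasets matrix of cluster assignments; genes missing
   from a dataset get a dedicated "absent" category.
3. Cluster genes on the one-hot encoding of that assignment matrix
   (co-occurrence clustering) with k = the maximum per-dataset k.
4. Merge clusters smaller than ``min_split_size`` into the nearest cluster
   by Euclidean centroid distance in the encoded space (ties toward the
   larger cluster, then the lower index).
5. Emit one child set per final cluster (ids ``<parent>.s1``, ``.s2``, ...,
   terms inherited, parent recorded); drop children below
   ``min_final_size`` genes.

Pathways smaller than ``min_path_size`` are passed through unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .types import GeneSet, GeneSetCollection, ZScoreMatrix

logger = logging.getLogger(__name__)

_ABSENT = "absent"


@dataclass(frozen=True)
class SplitParams:
    min_path_size: int = 8
    min_split_size: int = 3
    max_splits: Optional[int] = None
    explained_variance: float = 70.0
    min_final_size: int = 3
    n_init: int = 25  # k-means restarts

    def __post_init__(self) -> None:
        if self.min_split_size < 2:
            raise ValueError("min_split_size must be >= 2")
        if not 0 < self.explained_variance <= 100:
            raise ValueError("explained_variance must be in (0, 100]")


def _kmeans(X: np.ndarray, k: int, params: SplitParams, random_state: int) -> KMeans:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate rows trigger convergence noise
        return KMeans(
            n_clusters=k, n_init=params.n_init, random_state=random_state
        ).fit(X)


def choose_k(
    z_sub: np.ndarray, params: SplitParams, random_state: int = 0
) -> int:
    """Smallest k whose between/total sum-of-squares ratio reaches the
    explained-variance target.

    The search is capped at ``max_splits`` (when set) and at
    ``rows - min_split_size + 1``; identical rows (zero total SS) give k=1.
    """
    X = np.asarray(z_sub, dtype=float)
    n = X.shape[0]
    tot = float(((X - X.mean(axis=0)) ** 2).sum())
    if tot <= 0:
        return 1
    cap = n - params.min_split_size + 1
    if params.max_splits is not None:
        cap = min(cap, params.max_splits)
    cap = max(cap, 1)
    target = params.explained_variance / 100.0
    for k in range(1, cap + 1):
        if k == 1:
            ratio = 0.0
        else:
            km = _kmeans(X, k, params, random_state)
            ratio = 1.0 - km.inertia_ / tot
        if ratio >= target:
            return k
    return cap


def _merge_small_clusters(
    X: np.ndarray, labels: np.ndarray, min_size: int
) -> np.ndarray:
    """Fold clusters below ``min_size`` into their nearest neighbour
    (centroid Euclidean distance; ties toward the larger cluster, then the
    lower cluster index)."""
    labels = labels.copy()
    while True:
        ids, counts = np.unique(labels, return_counts=True)
        if len(ids) <= 1:
            break
        small = [(n, c) for c, n in zip(ids, counts) if n < min_size]
        if not small:
            break
        _, cid = min(small)  # smallest cluster first; ties by lower id
        centroids = {c: X[labels == c].mean(axis=0) for c in ids}
        sizes = dict(zip(ids, counts))
        best = None
        for other in ids:
            if other == cid:
                continue
            d = float(np.linalg.norm(centroids[cid] - centroids[other]))
            key = (d, -sizes[other], other)
            if best is None or key < best[0]:
                best = (key, other)
        labels[labels == cid] = best[1]
    return labels


def split_pathway(
    pathway: GeneSet,
    datasets: Sequence[ZScoreMatrix],
    params: SplitParams = SplitParams(),
    seed: int = 0,
) -> list[GeneSet]:
    """Split one pathway into co-expressed gene sets across datasets.

    Returns the pathway unchanged when it is below ``min_path_size``; an
    empty list (with a logged warning) when fewer than ``min_final_size`` of
    its genes are present in any dataset.
    """
    if pathway.size < params.min_path_size:
        return [pathway]

    present = [
        g
        for g in pathway.genes
        if any(g in z.values.index for z in datasets)
    ]
    if len(present) < params.min_final_size:
        logger.warning(
            "pathway %s: only %d genes present across datasets; dropped",
            pathway.set_id,
            len(present),
        )
        return []

    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, _stable_hash(pathway.set_id)])
    states = ss.generate_state(len(datasets) + 1) % (2**31)

    assignments = pd.DataFrame(_ABSENT, index=present, columns=range(len(datasets)))
    ks = []
    for j, z in enumerate(datasets):
        genes_d = [g for g in present if g in z.values.index]
        if len(genes_d) == 0:
            ks.append(1)
            continue
        X = z.values.loc[genes_d].to_numpy()
        if len(genes_d) < 2:
            labels = np.zeros(len(genes_d), dtype=int)
            k = 1
        else:
            k = choose_k(X, params, random_state=int(states[j]))
            if k == 1:
                labels = np.zeros(len(genes_d), dtype=int)
            else:
                labels = _kmeans(X, k, params, random_state=int(states[j])).labels_
        ks.append(k)
        assignments.loc[genes_d, j] = [f"c{c}" for c in labels]

    k_final = min(max(ks), len(present))
    encoded = pd.get_dummies(assignments, dtype=float)
    E = encoded.to_numpy()
    if k_final <= 1:
        labels = np.zeros(len(present), dtype=int)
    else:
        labels = _kmeans(E, k_final, params, random_state=int(states[-1])).labels_
        labels = _merge_small_clusters(E, labels, params.min_split_size)

    # emit clusters ordered by first member occurrence for stable ids
    order: dict[int, int] = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order) + 1
    out: list[GeneSet] = []
    for lab, idx in order.items():
        genes = tuple(g for g, l in zip(present, labels) if l == lab)
        if len(genes) < params.min_final_size:
            continue
        out.append(
            replace(
                pathway,
                set_id=f"{pathway.set_id}.s{idx}",
                genes=genes,
                parent_id=pathway.set_id,
            )
        )
    return out


def dissect_collection(
    collection: GeneSetCollection,
    datasets: Sequence[ZScoreMatrix],
    params: SplitParams = SplitParams(),
    seed: int = 0,
) -> GeneSetCollection:
    """Apply :func:`split_pathway` to every pathway; splits replace their
    parent, and any emitted set below three genes is removed."""
    out: list[GeneSet] = []
    for pathway in collection:
        for s in split_pathway(pathway, datasets, params, seed=seed):
            if s.size >= 3:
                out.append(s)
    return GeneSetCollection(out)


def split_map(collection: GeneSetCollection) -> pd.DataFrame:
    """Child set id → parent pathway id table for audit export."""
    return pd.DataFrame(
        [(s.set_id, s.parent_id or "") for s in collection],
        columns=["set_id", "parent_id"],
    )


def _stable_hash(text: str) -> int:
    h = 2166136261
    for ch in text.encode("utf-8"):
        h = (h ^ ch) * 16777619 % (2**32)
    return h
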