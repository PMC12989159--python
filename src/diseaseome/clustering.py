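"""Two-round consensus clustering of DRG activity profiles and automatic
label generation from annotation terms.

M-score matrices from all cohorts are concatenated column-wise into one
DRG × sample matrix. Round 1 groups DRGs into main functional categories by
k-means consensus clustering: on each of ``permutations`` iterations a
random 80% of the rows is clustered, and the consensus matrix records how
often each pair co-clusters among the iterations where both were sampled.
Final labels come from a complete-linkage hierarchical cut of
(1 − consensus). The number of clusters is chosen by minimizing the
proportion of ambiguous clustering (PAC): the fraction of consensus entries
that are neither clearly together (> 0.9) nor clearly apart (< 0.1). Round 2
repeats the procedure inside each round-1 cluster for finer stratification.

Cluster labels are generated by token mining over the member sets'
annotation terms: terms are lowercased, stripped of punctuation and digits,
tokenized, filtered against a stopword list (common English words plus
generic pathway vocabulary), and the tokens appearing in the most terms
become the label.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .types import DiseaseomeModel, GeneSetCollection, MScoreMatrix

logger = logging.getLogger(__name__)

DEFAULT_STOPWORDS = frozenset(
    """a an and are as at by for from in into of on or the to via with
    within without positive negative up down upregulated downregulated
    pathway pathways process processes regulation signaling signalling
    activity gene genes set sets term""".split()
)


@dataclass(frozen=True)
class ClusteringParams:
    k_min: int = 2
    k_max: int = 15
    permutations: int = 500
    subsample_fraction: float = 0.8
    seed: int = 0
    pac_lower: float = 0.1
    pac_upper: float = 0.9

    def __post_init__(self) -> None:
        if self.permutations < 2:
            raise ValueError("permutations must be >= 2")
        if not 0 < self.subsample_fraction < 1:
            raise ValueError("subsample_fraction must be in (0, 1)")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")


@dataclass
class ClusterAssignment:
    round: int
    labels: dict[str, int]
    consensus: pd.DataFrame

    def members(self, cluster: int) -> list[str]:
        return [sid for sid, c in self.labels.items() if c == cluster]

    @property
    def clusters(self) -> list[int]:
        return sorted(set(self.labels.values()))


def combine_scores(
    mscores: Sequence[MScoreMatrix], drgs: GeneSetCollection
) -> pd.DataFrame:
    """Column-wise concatenation of every dataset's M-scores, rows
    restricted to the DRGs; columns are prefixed with the dataset id."""
    blocks = []
    for m in mscores:
        missing = [
            sid
            for sid in drgs.ids
            if sid not in m.values.index or m.values.loc[sid].isna().all()
        ]
        if missing:
            raise ValueError(
                f"DRGs not scored in dataset {m.dataset_id!r}: {missing}"
            )
        block = m.values.loc[list(drgs.ids)].copy()
        block.columns = [f"{m.dataset_id}:{c}" for c in block.columns]
        blocks.append(block)
    return pd.concat(blocks, axis=1)


def consensus_cluster(
    matrix: pd.DataFrame, k: int, params: ClusteringParams = ClusteringParams()
) -> ClusterAssignment:
    """k-means consensus clustering with a complete-linkage consensus cut."""
    n = matrix.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of rows ({n})")
    X = matrix.to_numpy()
    rng = np.random.default_rng(params.seed)
    m_sub = max(k, int(round(params.subsample_fraction * n)))
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for _ in range(params.permutations):
        idx = rng.choice(n, size=m_sub, replace=False)
        state = int(rng.integers(2**31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels = KMeans(n_clusters=k, n_init=1, random_state=state).fit(
                X[idx]
            ).labels_
        same = (labels[:, None] == labels[None, :]).astype(float)
        together[np.ix_(idx, idx)] += same
        sampled[np.ix_(idx, idx)] += 1.0
    consensus = np.divide(
        together, sampled, out=np.zeros_like(together), where=sampled > 0
    )
    np.fill_diagonal(consensus, 1.0)
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = linkage(squareform(dist, checks=False), method="complete")
    raw = fcluster(Z, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    labels_out: dict[str, int] = {}
    for sid, lab in zip(matrix.index, raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels_out[str(sid)] = remap[lab]
    cons = pd.DataFrame(consensus, index=matrix.index, columns=matrix.index)
    return ClusterAssignment(round=0, labels=labels_out, consensus=cons)


def pac_score(
    consensus: pd.DataFrame, lower: float = 0.1, upper: float = 0.9
) -> float:
    """Proportion of ambiguous clustering: off-diagonal consensus entries in
    the open interval (lower, upper)."""
    c = consensus.to_numpy()
    iu = np.triu_indices_from(c, k=1)
    vals = c[iu]
    return float(((vals > lower) & (vals < upper)).mean())


def select_k(
    matrix: pd.DataFrame, params: ClusteringParams = ClusteringParams()
) -> int:
    """Candidate k minimizing PAC; ties go to the smaller k. Degenerate
    matrices (all rows identical) return ``k_min`` with a warning."""
    n = matrix.shape[0]
    X = matrix.to_numpy()
    if np.allclose(X, X[0]):
        logger.warning("all rows identical; defaulting to k=%d", params.k_min)
        return params.k_min
    k_hi = min(params.k_max, n - 1)
    if k_hi < params.k_min:
        return params.k_min
    best = None
    for k in range(params.k_min, k_hi + 1):
        assign = consensus_cluster(matrix, k, params)
        pac = pac_score(assign.consensus, params.pac_lower, params.pac_upper)
        key = (pac, k)
        if best is None or key < best:
            best = key
    return best[1]


def label_from_terms(
    terms: Sequence[str],
    top_n: int = 3,
    stopwords: frozenset = DEFAULT_STOPWORDS,
) -> str:
    """Token-frequency label for a group of annotation terms.

    Tokens are ranked by the number of terms they occur in (document
    frequency), ties broken by total frequency and then alphabetically; the
    ``top_n`` tokens joined by spaces form the label. If filtering removes
    every token, the most frequent raw term is returned instead.
    """
    if not terms:
        raise ValueError("label_from_terms requires a non-empty term list")
    doc_freq: dict[str, int] = {}
    tot_freq: dict[str, int] = {}
    for term in terms:
        tokens = [
            t
            for t in re.findall(r"[a-z]+", term.lower())
            if len(t) > 1 and t not in stopwords
        ]
        for t in tokens:
            tot_freq[t] = tot_freq.get(t, 0) + 1
        for t in set(tokens):
            doc_freq[t] = doc_freq.get(t, 0) + 1
    if not doc_freq:
        counts: dict[str, int] = {}
        for term in terms:
            counts[term] = counts.get(term, 0) + 1
        return min(counts, key=lambda t: (-counts[t], t))
    ranked = sorted(doc_freq, key=lambda t: (-doc_freq[t], -tot_freq[t], t))
    return " ".join(ranked[:top_n])


def _cluster_terms(drgs: GeneSetCollection, ids: Sequence[str]) -> list[str]:
    return [term for sid in ids for term, _src in drgs[sid].terms]


def two_round_clustering(
    matrix: pd.DataFrame,
    drgs: GeneSetCollection,
    params: ClusteringParams = ClusteringParams(),
    provenance: Mapping | None = None,
) -> DiseaseomeModel:
    """Round-1 consensus clustering of all DRGs, then an independent round-2
    clustering inside each round-1 cluster.

    Round-1 clusters with fewer than ``2 * k_min`` members are kept as a
    single round-2 cluster. Labels are generated from the member sets'
    annotation terms at both rounds.
    """
    n = matrix.shape[0]
    round1_labels: dict[str, str] = {}
    round2_labels: dict[str, str] = {}
    tree: dict[str, dict[str, list[str]]] = {}
    ks: dict[str, int] = {}

    if n < 2 * params.k_min:
        # too small to cluster: one cluster, one subcluster
        ids = [str(i) for i in matrix.index]
        label = label_from_terms(_cluster_terms(drgs, ids)) if ids else ""
        tree["1"] = {"1.1": ids}
        for sid in ids:
            round1_labels[sid] = label
            round2_labels[sid] = label
        ks = {"round1": 1}
    else:
        k1 = select_k(matrix, params)
        assign1 = consensus_cluster(matrix, k1, params)
        ks["round1"] = k1
        for c1 in assign1.clusters:
            members = assign1.members(c1)
            label1 = label_from_terms(_cluster_terms(drgs, members))
            sub = matrix.loc[members]
            r1_id = str(c1)
            tree[r1_id] = {}
            if len(members) >= 2 * params.k_min and not np.allclose(
                sub.to_numpy(), sub.to_numpy()[0]
            ):
                k2 = select_k(sub, params)
                assign2 = consensus_cluster(sub, k2, params)
                ks[f"round2.{r1_id}"] = k2
                groups = {
                    c2: assign2.members(c2) for c2 in assign2.clusters
                }
            else:
                groups = {1: members}
            for c2, mem2 in groups.items():
                r2_id = f"{r1_id}.{c2}"
                tree[r1_id][r2_id] = list(mem2)
                label2 = label_from_terms(_cluster_terms(drgs, mem2))
                for sid in mem2:
                    round1_labels[sid] = label1
                    round2_labels[sid] = label2

    prov = dict(provenance or {})
    prov["clustering"] = {
        "k_min": params.k_min,
        "k_max": params.k_max,
        "permutations": params.permutations,
        "subsample_fraction": params.subsample_fraction,
        "seed": params.seed,
        "chosen_k": ks,
    }
    model = DiseaseomeModel(
        drgs=drgs.subset([str(i) for i in matrix.index]),
        round1_labels=round1_labels,
        round2_labels=round2_labels,
        cluster_tree=tree,
        provenance=prov,
    )
    model.validate()
    return model


def assignments_table(model: DiseaseomeModel) -> pd.DataFrame:
    """Flat TSV-ready table: set_id, round-1/2 cluster ids and labels."""
    rows = []
    for r1, subs in model.cluster_tree.items():
        for r2, members in subs.items():
            for sid in members:
                rows.append(
                    (
                        sid,
                        r1,
                        model.round1_labels[sid],
                        r2,
                        model.round2_labels[sid],
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "set_id",
            "round1_cluster",
            "round1_label",
            "round2_cluster",
            "round2_label",
        ],
    )
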