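"""Redundancy reduction: subset packing with the replacement test, and the
Jaccard similarity graph filter.

Integrating several pathway databases — and splitting pathways — leaves
many near-identical gene sets. Two passes remove them:

**Set packing.** For each gene set G, its proper subsets among the
collection are candidates; a pairwise-disjoint combination maximizing the
number of G's genes covered is selected (exact search up to 15 candidates,
greedy beyond). Whether G or the selected subsets survive is decided from
M-score behaviour: the mean Pearson correlation between G's and each
selected subset's per-patient profiles, and the *information gain* — the
mean over datasets of the difference in the proportion of patients with
significant scores between the best selected subset and G. High correlation
with little gain means the subsets merely mirror G and G is kept; a gain
above the threshold means some subset detects patients G dilutes, and the
subsets replace G. Surviving sets absorb the removed sets' annotation terms
(co-annotation), so no functional information is lost.

**Jaccard graph.** Pairs of sets with Jaccard index above 0.8 (0.75 when
either set has fewer than five genes) are linked; within each connected
component only the largest set survives, re-annotated with the terms of the
others.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Sequence

import networkx as nx
import numpy as np

from .scoring import significant_fraction
from .types import (
    DEFAULT_M_THRESHOLD,
    GeneSet,
    GeneSetCollection,
    MScoreMatrix,
)


class Decision(str, Enum):
    KEEP_PARENT = "KEEP_PARENT"
    KEEP_SPLITS = "KEEP_SPLITS"


@dataclass(frozen=True)
class RedundancyParams:
    corr_threshold: float = 0.75
    gain_threshold: float = 10.0  # percent
    jaccard_threshold: float = 0.8
    jaccard_threshold_small: float = 0.75
    small_set_size: int = 5
    m_threshold: float = DEFAULT_M_THRESHOLD

    def __post_init__(self) -> None:
        for name in ("corr_threshold", "jaccard_threshold", "jaccard_threshold_small"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 < self.gain_threshold <= 100:
            raise ValueError("gain_threshold must be in (0, 100]")


@dataclass(frozen=True)
class RemovalRecord:
    """One audit-log row: which set was removed, by which rule, in favour of
    which survivor."""

    removed_id: str
    rule: str
    survivor_id: str


#: At or below this many candidates the packing is solved exactly.
EXACT_PACKING_LIMIT = 15


def find_subset_packing(
    G: GeneSet, candidates: Sequence[GeneSet]
) -> list[GeneSet]:
    """Pairwise-disjoint sub-collection of ``candidates`` maximizing the
    number of G's genes covered.

    Candidates are restricted to proper subsets of G. With at most
    :data:`EXACT_PACKING_LIMIT` candidates the optimum is found by exhaustive
    search (ties broken toward fewer sets, then the lexicographically
    smallest id tuple); otherwise a greedy pass takes the largest set first,
    skipping any that overlaps the selection (ties by id).
    """
    cands = [c for c in candidates if c.gene_set < G.gene_set]
    if not cands:
        return []
    gene_bit = {g: i for i, g in enumerate(G.genes)}
    masks = [
        sum(1 << gene_bit[g] for g in c.genes) for c in cands
    ]
    if len(cands) <= EXACT_PACKING_LIMIT:
        return _exact_packing(cands, masks)
    return _greedy_packing(cands, masks)


def _exact_packing(cands: list[GeneSet], masks: list[int]) -> list[GeneSet]:
    order = sorted(range(len(cands)), key=lambda i: (-len(cands[i]), cands[i].set_id))
    best_key = None
    best_sel: list[int] = []

    def rec(pos: int, used: int, chosen: list[int]) -> None:
        nonlocal best_key, best_sel
        if pos == len(order):
            cov = used.bit_count()
            ids = tuple(sorted(cands[i].set_id for i in chosen))
            key = (-cov, len(chosen), ids)
            if best_key is None or key < best_key:
                best_key, best_sel = key, list(chosen)
            return
        i = order[pos]
        if masks[i] & used == 0:
            chosen.append(i)
            rec(pos + 1, used | masks[i], chosen)
            chosen.pop()
        rec(pos + 1, used, chosen)

    rec(0, 0, [])
    return [cands[i] for i in sorted(best_sel, key=lambda i: cands[i].set_id)]


def _greedy_packing(cands: list[GeneSet], masks: list[int]) -> list[GeneSet]:
    order = sorted(range(len(cands)), key=lambda i: (-len(cands[i]), cands[i].set_id))
    used = 0
    sel: list[int] = []
    for i in order:
        if masks[i] & used == 0:
            sel.append(i)
            used |= masks[i]
    return [cands[i] for i in sorted(sel, key=lambda i: cands[i].set_id)]


def replacement_metrics(
    G: GeneSet, selected: Sequence[GeneSet], mscores: Sequence[MScoreMatrix]
) -> tuple[float, float]:
    """(mean Pearson correlation, information gain in percent).

    The correlation averages over datasets and selected subsets; pairs where
    either profile is constant (undefined correlation) are skipped. The gain
    is the mean over datasets of ``max_g frac(g) - frac(G)`` times 100,
    using the best selected subset per dataset.
    """
    corrs: list[float] = []
    gains: list[float] = []
    for m in mscores:
        pg = m.values.loc[G.set_id].to_numpy()
        frac_G = significant_fraction(m, G.set_id)
        best = -np.inf
        for g in selected:
            ps = m.values.loc[g.set_id].to_numpy()
            if np.std(pg) > 0 and np.std(ps) > 0:
                corrs.append(float(np.corrcoef(pg, ps)[0, 1]))
            best = max(best, significant_fraction(m, g.set_id))
        if np.isfinite(best) and not np.isnan(frac_G):
            gains.append((best - frac_G) * 100.0)
    rbar = float(np.mean(corrs)) if corrs else float("nan")
    gain = float(np.mean(gains)) if gains else float("nan")
    return rbar, gain


def replacement_decision(
    G: GeneSet,
    selected: Sequence[GeneSet],
    mscores: Sequence[MScoreMatrix],
    params: RedundancyParams = RedundancyParams(),
) -> Decision:
    """KEEP_SPLITS when the information gain exceeds the threshold; every
    other case — including the region not covered by the two published
    rules (low correlation, low gain) — conservatively keeps the parent."""
    if not selected:
        return Decision.KEEP_PARENT
    rbar, gain = replacement_metrics(G, selected, mscores)
    if not np.isnan(gain) and gain > params.gain_threshold:
        return Decision.KEEP_SPLITS
    return Decision.KEEP_PARENT


def set_packing_reduce(
    collection: GeneSetCollection,
    mscores: Sequence[MScoreMatrix],
    params: RedundancyParams = RedundancyParams(),
) -> tuple[GeneSetCollection, list[RemovalRecord]]:
    """Run the packing/replacement pass over a whole collection.

    Parents are visited largest first. On KEEP_PARENT all proper-subset
    candidates are removed and the parent absorbs their terms; on
    KEEP_SPLITS the parent and the non-selected subsets are removed, each
    removed set's terms going to the selected survivor with the largest gene
    overlap (the parent's terms go to every selected survivor).
    """
    alive: dict[str, GeneSet] = {s.set_id: s for s in collection}
    audit: list[RemovalRecord] = []
    for parent in sorted(collection, key=lambda s: (-s.size, s.set_id)):
        G = alive.get(parent.set_id)
        if G is None:
            continue
        cands = [
            s
            for sid, s in alive.items()
            if sid != G.set_id and s.gene_set < G.gene_set
        ]
        if not cands:
            continue
        selected = find_subset_packing(G, cands)
        decision = replacement_decision(G, selected, mscores, params)
        if decision is Decision.KEEP_PARENT:
            extra: list[tuple[str, str]] = []
            for c in sorted(cands, key=lambda s: s.set_id):
                extra.extend(c.terms)
                del alive[c.set_id]
                audit.append(RemovalRecord(c.set_id, "set_packing:keep_parent", G.set_id))
            alive[G.set_id] = alive[G.set_id].with_extra_terms(extra)
        else:
            sel_ids = {s.set_id for s in selected}
            for g in selected:
                alive[g.set_id] = alive[g.set_id].with_extra_terms(G.terms)
            for c in sorted(cands, key=lambda s: s.set_id):
                if c.set_id in sel_ids:
                    continue
                host = max(
                    selected,
                    key=lambda s: (len(s.gene_set & c.gene_set), s.set_id),
                )
                alive[host.set_id] = alive[host.set_id].with_extra_terms(c.terms)
                del alive[c.set_id]
                audit.append(
                    RemovalRecord(c.set_id, "set_packing:keep_splits", host.set_id)
                )
            first = min(sel_ids)
            del alive[G.set_id]
            audit.append(RemovalRecord(G.set_id, "set_packing:keep_splits", first))
    kept = GeneSetCollection(
        alive[s.set_id] for s in collection if s.set_id in alive
    )
    return kept, audit


def jaccard_index(a: GeneSet, b: GeneSet) -> float:
    inter = len(a.gene_set & b.gene_set)
    union = len(a.gene_set | b.gene_set)
    return inter / union if union else 0.0


def jaccard_reduce(
    collection: GeneSetCollection, params: RedundancyParams = RedundancyParams()
) -> tuple[GeneSetCollection, list[RemovalRecord]]:
    """Collapse groups of highly similar sets to their largest member.

    Edges link pairs whose Jaccard index strictly exceeds the applicable
    threshold (the small-set threshold applies when either set has fewer
    than ``small_set_size`` genes). Within each connected component the set
    with most genes survives (ties to the lexicographically smallest id) and
    absorbs the other members' terms. The pass is idempotent: survivors of
    distinct components are, by construction, below threshold.
    """
    graph = nx.Graph()
    graph.add_nodes_from(s.set_id for s in collection)
    for a, b in combinations(collection, 2):
        thr = (
            params.jaccard_threshold_small
            if min(a.size, b.size) < params.small_set_size
            else params.jaccard_threshold
        )
        if jaccard_index(a, b) > thr:
            graph.add_edge(a.set_id, b.set_id)

    audit: list[RemovalRecord] = []
    survivors: dict[str, GeneSet] = {}
    for component in nx.connected_components(graph):
        members = sorted(component)
        winner_id = min(members, key=lambda sid: (-collection[sid].size, sid))
        winner = collection[winner_id]
        extra: list[tuple[str, str]] = []
        for sid in members:
            if sid == winner_id:
                continue
            extra.extend(collection[sid].terms)
            audit.append(RemovalRecord(sid, "jaccard", winner_id))
        survivors[winner_id] = winner.with_extra_terms(extra)
    kept = GeneSetCollection(
        survivors[s.set_id] for s in collection if s.set_id in survivors
    )
    return kept, audit
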