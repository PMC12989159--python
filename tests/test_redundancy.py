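from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from diseaseome.redundancy import (
    Decision,
    RedundancyParams,
    find_subset_packing,
    jaccard_index,
    jaccard_reduce,
    replacement_decision,
    replacement_metrics,
    set_packing_reduce,
)
from diseaseome.types import GeneSet, GeneSetCollection, MScoreMatrix


def _gs(set_id, genes, term=None):
    return GeneSet(set_id, tuple(genes), ((term or set_id, "s"),))


def brute_force_packing_coverage(G, candidates):
    """Independent oracle: enumerate every subset of candidates, keep the
    pairwise-disjoint ones, return the best coverage of G's genes."""
    best = 0
    n = len(candidates)
    for r in range(n + 1):
        for combo in combinations(candidates, r):
            union = set()
            ok = True
            for c in combo:
                if union & c.gene_set:
                    ok = False
                    break
                union |= c.gene_set
            if ok:
                best = max(best, len(union & G.gene_set))
    return best


def test_packing_no_subsets_gives_empty():
    G = _gs("G", "abcdef")
    assert find_subset_packing(G, [_gs("X", "xyz")]) == []


def test_packing_worked_example():
    G = _gs("G", "abcdef")
    cands = [_gs("c1", "abc"), _gs("c2", "de"), _gs("c3", "cd")]
    sel = find_subset_packing(G, cands)
    assert {s.set_id for s in sel} == {"c1", "c2"}
    covered = set().union(*(s.gene_set for s in sel))
    assert len(covered) == 5 == brute_force_packing_coverage(G, cands)


def test_packing_single_candidate():
    G = _gs("G", "abcdef")
    c = _gs("c", "abcde")
    assert find_subset_packing(G, [c]) == [c]


def test_packing_exact_beats_naive_largest_first():
    # the largest candidate blocks the optimal pair
    G = _gs("G", "abcdef")
    cands = [_gs("big", "abcd"), _gs("l", "abe"), _gs("r", "cdf")]
    sel = find_subset_packing(G, cands)
    covered = set().union(*(s.gene_set for s in sel))
    assert len(covered) == 6
    assert {s.set_id for s in sel} == {"l", "r"}


@settings(max_examples=150, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_packing_matches_bruteforce_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    universe = [chr(97 + i) for i in range(14)]
    G = _gs("G", universe[: rng.integers(6, 14)])
    n_cands = int(rng.integers(0, 9))
    cands = []
    for i in range(n_cands):
        size = int(rng.integers(1, max(2, len(G.genes))))
        cands.append(_gs(f"c{i}", rng.choice(list(G.genes), size, replace=False)))
    sel = find_subset_packing(G, cands)
    union = set()
    for s in sel:
        assert not (union & s.gene_set), "selection must be pairwise disjoint"
        union |= s.gene_set
    valid = [c for c in cands if c.gene_set < G.gene_set]
    assert len(union & G.gene_set) == brute_force_packing_coverage(G, valid)


def _mscore(rows: dict, dataset_id="D1"):
    return MScoreMatrix(dataset_id, pd.DataFrame(rows).T)


def test_replacement_perfect_redundancy_keeps_parent():
    m = _mscore({"G": [2.0, 0.1, 1.8, 0.2], "g1": [2.0, 0.1, 1.8, 0.2]})
    G, g1 = _gs("G", "abcdef"), _gs("g1", "abc")
    rbar, gain = replacement_metrics(G, [g1], [m])
    assert rbar == pytest.approx(1.0)
    assert gain == pytest.approx(0.0)
    assert replacement_decision(G, [g1], [m]) is Decision.KEEP_PARENT


def test_replacement_subgroup_signal_keeps_splits():
    """A split significant in 40% of patients vs 10% for the diluted parent
    gives a 30% information gain, above the 10% threshold."""
    n = 10
    parent = [2.0] + [0.0] * (n - 1)  # 10% significant
    split = [2.0, 2.0, 2.0, 2.0] + [0.0] * (n - 4)  # 40% significant
    m = _mscore({"G": parent, "g1": split})
    G, g1 = _gs("G", "abcdef"), _gs("g1", "abc")
    _, gain = replacement_metrics(G, [g1], [m])
    assert gain == pytest.approx(30.0)
    assert replacement_decision(G, [g1], [m]) is Decision.KEEP_SPLITS


def test_replacement_empty_selection_keeps_parent():
    G = _gs("G", "abc")
    assert replacement_decision(G, [], []) is Decision.KEEP_PARENT


def test_set_packing_reduce_keep_parent_removes_all_subsets():
    sets = [
        _gs("G", "abcdef"),
        _gs("g1", "abc"),
        _gs("g2", "def"),
    ]
    coll = GeneSetCollection(sets)
    # identical profiles: redundant splits
    m = _mscore({sid: [2.0, 0.0, 1.8] for sid in ["G", "g1", "g2"]})
    out, audit = set_packing_reduce(coll, [m])
    assert out.ids == ("G",)
    # co-annotation conserves the union of terms
    terms_before = {t for s in sets for t in s.terms}
    terms_after = {t for s in out for t in s.terms}
    assert terms_after == terms_before
    assert {r.removed_id for r in audit} == {"g1", "g2"}


def test_set_packing_reduce_keep_splits_removes_parent():
    sets = [_gs("G", "abcdef"), _gs("g1", "abc"), _gs("g2", "def")]
    coll = GeneSetCollection(sets)
    m = _mscore(
        {
            "G": [0.0] * 10,
            "g1": [2.0] * 5 + [0.0] * 5,
            "g2": [0.0] * 10,
        }
    )
    out, _ = set_packing_reduce(coll, [m])
    assert set(out.ids) == {"g1", "g2"}
    terms_after = {t for s in out for t in s.terms}
    assert terms_after == {t for s in sets for t in s.terms}


def test_jaccard_identical_sets_merge_with_terms():
    coll = GeneSetCollection([_gs("A", "abcde"), _gs("B", "abcde")])
    out, audit = jaccard_reduce(coll)
    assert out.ids == ("A",)
    assert set(out["A"].terms) == {("A", "s"), ("B", "s")}


def test_jaccard_arithmetic_example():
    a = _gs("A", "abcdefghij")  # 10 genes
    b = _gs("B", "abcdefghik")  # shares 9, union 11 -> J ~ 0.818
    assert jaccard_index(a, b) == pytest.approx(9 / 11)
    out, _ = jaccard_reduce(GeneSetCollection([a, b]))
    assert set(out.ids) == {"A"}  # tie on size -> lexicographically smallest


def test_jaccard_chain_forms_single_component():
    a = _gs("A", "abcdefghij")
    b = _gs("B", "abcdefghik")
    c = _gs("C", "abcdefghkl")
    assert jaccard_index(a, c) <= 0.8  # no direct edge
    out, _ = jaccard_reduce(GeneSetCollection([a, b, c]))
    assert len(out) == 1


def test_jaccard_small_set_threshold():
    a = _gs("A", "abcd")
    b = _gs("B", "abce")  # J = 3/5 = 0.6: below both thresholds
    c = _gs("C", "uvwxyz")
    d = _gs("D", "uvwxyq")  # J(C,D) = 5/7 ~ 0.714 < 0.8 (both >= 5 genes)
    out, _ = jaccard_reduce(GeneSetCollection([a, b, c, d]))
    assert len(out) == 4
    e = _gs("E", "abcd")
    f = _gs("F", "abcde")  # J = 4/5 = 0.8 > 0.75 small-set rule (|E| < 5)
    out2, _ = jaccard_reduce(GeneSetCollection([e, f]))
    assert out2.ids == ("F",)  # largest survives


@settings(max_examples=60, deadline=None)
@given(seed=st.integers(0, 10_000), n_sets=st.integers(2, 12))
def test_jaccard_reduce_idempotent_and_sound(seed, n_sets):
    from conftest import random_collection

    rng = np.random.default_rng(seed)
    coll = random_collection(rng, n_sets=n_sets)
    params = RedundancyParams()
    once, _ = jaccard_reduce(coll, params)
    twice, removals = jaccard_reduce(once, params)
    assert twice.ids == once.ids and not removals
    for a, b in combinations(once, 2):
        thr = (
            params.jaccard_threshold_small
            if min(a.size, b.size) < params.small_set_size
            else params.jaccard_threshold
        )
        assert jaccard_index(a, b) <= thr
    # term conservation
    assert {t for s in coll for t in s.terms} == {t for s in once for t in s.terms}
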