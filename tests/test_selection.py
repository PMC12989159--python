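import math

import numpy as np
import pandas as pd
import pytest

from diseaseome.errors import NoEligibleParametersError
from diseaseome.selection import (
    FilterParams,
    OptConstraints,
    filter_gene_sets,
    information_loss,
    optimize_parameters,
    passing_mask,
    pca_components_for_variance,
    random_gene_sets,
    sample_random_genesets,
    shannon_index,
    significance_proportions,
    term_root,
)
from diseaseome.types import GeneSet, GeneSetCollection, MScoreMatrix


def _mscore(rows: dict, dataset_id="D1"):
    return MScoreMatrix(dataset_id, pd.DataFrame(rows).T)


def test_significance_proportions_counting():
    m1 = _mscore({"S": [1.7, 1.7, 0.0]}, "D1")
    m2 = _mscore({"S": [0.0, 0.0, 0.0]}, "D2")
    coll = GeneSetCollection([GeneSet("S", ("a", "b", "c"), (("t", "s"),))])
    props = significance_proportions(coll, [m1, m2])
    assert props.loc["S", "D1"] == pytest.approx(2 / 3)
    assert props.loc["S", "D2"] == pytest.approx(0.0)


def test_filter_vacuous_params_keep_everything():
    props = pd.DataFrame(
        {"D1": [0.01, 0.2], "D2": [0.05, 0.9]}, index=["A", "B"]
    )
    coll = GeneSetCollection(
        [GeneSet(i, ("a", "b", "c"), (("t", "s"),)) for i in ["A", "B"]]
    )
    out = filter_gene_sets(coll, props, FilterParams(perc_samples=0.5, min_datasets=1))
    assert out.ids == ("A", "B")


def test_filter_counts_datasets_with_inclusive_bounds():
    rng = np.random.default_rng(0)
    n_ds = 15
    frac = {}
    frac["A"] = [0.12] * 7 + [0.0] * 8  # exactly at both bounds -> kept
    frac["B"] = [0.5] * 6 + [0.119] * 9  # only 6 datasets -> dropped
    frac["C"] = [0.9] * 15  # everywhere -> kept
    props = pd.DataFrame(frac, index=[f"D{i}" for i in range(n_ds)]).T
    coll = GeneSetCollection(
        [GeneSet(i, ("a", "b", "c"), (("t", "s"),)) for i in ["A", "B", "C"]]
    )
    out = filter_gene_sets(coll, props, FilterParams(perc_samples=12, min_datasets=7))
    assert set(out.ids) == {"A", "C"}


def test_filter_monotone_in_both_parameters():
    rng = np.random.default_rng(3)
    props = pd.DataFrame(
        rng.uniform(0, 0.4, size=(40, 6)),
        index=[f"S{i}" for i in range(40)],
        columns=[f"D{i}" for i in range(6)],
    )
    counts = {
        (p, d): int(passing_mask(props, FilterParams(p, d)).sum())
        for p in range(1, 31)
        for d in range(1, 7)
    }
    for (p, d), n in counts.items():
        if (p + 1, d) in counts:
            assert counts[(p + 1, d)] <= n
        if (p, d + 1) in counts:
            assert counts[(p, d + 1)] <= n


def test_random_gene_sets_sizes_and_determinism():
    universe = [f"g{i}" for i in range(300)]
    a = random_gene_sets(universe, 50, (5, 50), seed=9)
    b = random_gene_sets(universe, 50, (5, 50), seed=9)
    assert a == b
    sizes = a.sizes()
    assert sizes.min() >= 5 and sizes.max() <= 50
    assert all(len(set(s.genes)) == s.size for s in a)
    with pytest.raises(ValueError):
        random_gene_sets(universe[:10], 5, (5, 50), seed=0)


def test_sample_random_genesets_respects_reference_percentiles():
    rng = np.random.default_rng(4)
    reference = GeneSetCollection(
        [
            GeneSet(f"R{i}", tuple(f"g{j}" for j in rng.choice(500, size, False)),
                    (("t", "s"),))
            for i, size in enumerate(rng.integers(3, 101, size=80))
        ]
    )
    universe = [f"g{i}" for i in range(500)]
    out = sample_random_genesets(universe, reference, n=200, seed=1)
    assert len(out) == 200
    p10, p90 = np.percentile(reference.sizes(), [10, 90])
    lo, hi = max(3, round(p10)), round(p90)
    sizes = out.sizes()
    assert sizes.min() >= lo and sizes.max() <= hi


def test_information_loss_identity_and_rank_example():
    rng = np.random.default_rng(0)
    full = _mscore({f"S{i}": rng.normal(size=6) for i in range(5)})
    assert information_loss(full, full) == 0.0
    # rank-2 matrix with two equal-variance components vs a rank-1 subset
    a = np.array([1.0, -1.0, 0.0, 0.0])
    b = np.array([0.0, 0.0, 1.0, -1.0])
    full2 = _mscore({"r1": a, "r2": -a, "r3": b, "r4": -b})
    filt2 = _mscore({"r1": a, "r2": -a})
    assert pca_components_for_variance(full2.values.to_numpy()) == 2
    assert pca_components_for_variance(filt2.values.to_numpy()) == 1
    assert information_loss(full2, filt2) == pytest.approx(0.5)


def test_pca_components_single_row_convention():
    assert pca_components_for_variance(np.array([[1.0, 2.0, 3.0]])) == 1


@pytest.mark.parametrize(
    "labels,expected",
    [
        (["root"] * 5, 0.0),
        (["a", "b", "c", "d"], math.log(4)),
        (["x", "x", "y", "z"], -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))),
    ],
    ids=["single-root", "uniform", "counts-2-1-1"],
)
def test_shannon_index_closed_forms(labels, expected):
    assert shannon_index(labels) == pytest.approx(expected)


def test_shannon_index_empty_rejected():
    with pytest.raises(ValueError):
        shannon_index([])


def test_term_root_first_token():
    s = GeneSet("S", ("a", "b", "c"), (("Type I interferon response", "src"),))
    assert term_root(s) == "type"


def _optimization_fixture():
    """3 datasets; two strong true sets, one weak, plus a random background
    where nothing is significant."""
    rng = np.random.default_rng(11)
    ids = ["A", "B", "C"]
    mats, mats_rand = [], []
    for d in range(3):
        rows = {
            "A": [2.0] * 6 + [0.0] * 4,
            "B": [2.0] * 6 + [0.0] * 4,
            "C": [0.0] * 10,
        }
        mats.append(_mscore(rows, f"D{d}"))
        mats_rand.append(
            _mscore({f"R{i}": rng.normal(0, 0.3, 10) for i in range(40)}, f"D{d}")
        )
    coll = GeneSetCollection(
        [
            GeneSet("A", ("a", "b", "c"), (("alpha thing", "s"),)),
            GeneSet("B", ("d", "e", "f"), (("beta thing", "s"),)),
            GeneSet("C", ("g", "h", "i"), (("gamma thing", "s"),)),
        ]
    )
    rand = GeneSetCollection(
        [GeneSet(f"R{i}", ("a", "b", "c"), (("r", "s"),)) for i in range(40)]
    )
    return coll, mats, rand, mats_rand


def test_optimize_parameters_selects_eligible_point():
    coll, mats, rand, mats_rand = _optimization_fixture()
    report = optimize_parameters(
        coll, mats, rand, mats_rand, grid_perc=range(1, 31), grid_datasets=range(1, 4)
    )
    chosen = report.chosen
    assert chosen.perc_samples >= 10
    assert chosen.min_datasets >= math.ceil(0.3 * 3)
    assert chosen.fpr < 5.0
    assert chosen.n_retained == 2  # A and B survive at the chosen point
    # grid covers the full cartesian product
    assert len(report.grid) == 30 * 3


def test_optimize_parameters_no_eligible_point_reports_misses():
    coll, mats, rand, mats_rand = _optimization_fixture()
    # impossible FPR constraint
    with pytest.raises(NoEligibleParametersError) as exc:
        optimize_parameters(
            coll,
            mats,
            rand,
            mats_rand,
            grid_perc=range(1, 3),
            grid_datasets=[1],
            constraints=OptConstraints(min_perc=10.0),
        )
    assert exc.value.nearest_misses


def test_optimize_single_eligible_degenerate_grid():
    coll, mats, rand, mats_rand = _optimization_fixture()
    report = optimize_parameters(
        coll, mats, rand, mats_rand, grid_perc=[12], grid_datasets=[3]
    )
    assert (report.chosen.perc_samples, report.chosen.min_datasets) == (12.0, 3)
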