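import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diseaseome.errors import DegenerateDatasetError
from diseaseome.scoring import (
    gene_zscores,
    mscores,
    significant_fraction,
    significant_fractions,
)
from diseaseome.simulate import SimulationConfig, simulate_null
from diseaseome.types import (
    DISEASE,
    REFERENCE,
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
    MScoreMatrix,
)


def _dataset(ref_values, disease_values, gene="GA"):
    vals = list(disease_values) + list(ref_values)
    cols = [f"d{i}" for i in range(len(disease_values))] + [
        f"r{i}" for i in range(len(ref_values))
    ]
    df = pd.DataFrame([vals], index=[gene], columns=cols)
    groups = pd.Series(
        [DISEASE] * len(disease_values) + [REFERENCE] * len(ref_values), index=cols
    )
    return ExpressionDataset("T", df, groups)


@pytest.mark.parametrize(
    "disease_value,expected_z",
    [(2.0, 0.0), (3.0, 1.0), (4.0, 2.0)],
    ids=["at-ref-mean", "one-sd-above", "hand-computed"],
)
def test_gene_zscores_against_reference_stats(disease_value, expected_z):
    # reference {1,2,3}: mean 2, sd 1 (n-1 denominator)
    ds = _dataset([1.0, 2.0, 3.0], [disease_value])
    z = gene_zscores(ds)
    assert z.values.iloc[0, 0] == pytest.approx(expected_z)


def test_gene_zscores_requires_reference_group():
    ds = _dataset([1.0, 2.0], [5.0])
    with pytest.raises(DegenerateDatasetError):
        gene_zscores(ds)


def test_reference_selfscoring_is_standardized():
    """Scoring the reference samples against their own statistics gives
    per-gene mean 0 and sd 1 (up to the epsilon floor)."""
    rng = np.random.default_rng(0)
    cols = [f"s{i}" for i in range(10)]
    df = pd.DataFrame(rng.normal(5, 2, size=(20, 10)), columns=cols,
                      index=[f"g{i}" for i in range(20)])
    groups = pd.Series([DISEASE] * 10, index=cols)
    # trick: score the reference against itself by labeling it both ways
    both = ExpressionDataset("T", pd.concat([df, df.add_suffix("_r", axis=1)], axis=1),
                             pd.concat([groups, pd.Series([REFERENCE] * 10,
                                                          index=[c + "_r" for c in cols])]))
    z = gene_zscores(both)
    np.testing.assert_allclose(z.values.mean(axis=1), 0, atol=1e-12)
    np.testing.assert_allclose(z.values.std(axis=1, ddof=1), 1, atol=1e-9)


def test_mscores_mean_and_duplicate_invariance():
    z_df = pd.DataFrame(
        {"d1": [1.0, 2.0, 3.0], "d2": [0.0, 0.0, 0.0]},
        index=["A", "B", "C"],
    )
    from diseaseome.types import ZScoreMatrix

    z = ZScoreMatrix("T", z_df)
    coll = GeneSetCollection(
        [
            GeneSet("S", ("A", "B", "C"), (("t", "s"),)),
            GeneSet("Sdup", ("A", "B", "C", "A"), (("t", "s"),)),
            GeneSet("Sperm", ("C", "A", "B"), (("t", "s"),)),
        ]
    )
    m = mscores(coll, z)
    assert m.values.loc["S", "d1"] == pytest.approx(2.0)  # mean(1,2,3)
    assert m.values.loc["S", "d2"] == pytest.approx(0.0)
    # duplicated gene listing and member order do not matter
    np.testing.assert_allclose(m.values.loc["Sdup"], m.values.loc["S"])
    np.testing.assert_allclose(m.values.loc["Sperm"], m.values.loc["S"])


def test_mscores_flags_sets_with_too_few_present_genes():
    from diseaseome.types import ZScoreMatrix

    z = ZScoreMatrix("T", pd.DataFrame({"d1": [1.0, 2.0]}, index=["A", "B"]))
    coll = GeneSetCollection(
        [GeneSet("S", ("A", "B", "X", "Y"), (("t", "s"),)),
         GeneSet("Sgone", ("X", "Y", "Z"), (("t", "s"),))]
    )
    m = mscores(coll, z)
    assert "S" in m.flagged and "Sgone" in m.flagged
    assert m.values.loc["S"].isna().all()
    assert np.isnan(significant_fraction(m, "Sgone"))


def test_significant_fraction_inclusive_threshold():
    m = MScoreMatrix(
        "T",
        pd.DataFrame([[1.7, -1.7, 0.5, 1.65]], index=["S"],
                     columns=["a", "b", "c", "d"]),
    )
    assert significant_fraction(m, "S") == pytest.approx(0.75)
    with pytest.raises(KeyError):
        significant_fraction(m, "nope")
    assert m.threshold == 1.65  # one-sided 5% normal critical value


def test_null_mscore_tail_matches_normal_prediction():
    """Under the null generator with a large reference group, the rate of
    |M| >= 1.65 tracks the two-sided tail of Normal(0, 1/|S|), decreasing
    with set size as 1/sqrt(|S|) scaling predicts."""
    cfg = SimulationConfig(
        n_datasets=1, n_genes=4000, n_disease=150, n_reference=400, seed=42
    )
    datasets, _, _ = simulate_null(cfg)
    z = gene_zscores(datasets[0])
    genes = list(z.values.index)
    sizes = [4, 16]
    sets = []
    rng = np.random.default_rng(1)
    for s in sizes:
        for i in range(120):
            sets.append(
                GeneSet(f"S{s}_{i}", tuple(rng.choice(genes, s, replace=False)),
                        (("t", "s"),))
            )
    m = mscores(GeneSetCollection(sets), z)
    fracs = significant_fractions(m)
    for s in sizes:
        observed = fracs[[i for i in fracs.index if i.startswith(f"S{s}_")]].mean()
        expected = 2 * stats.norm.sf(1.65 * np.sqrt(s))
        n_obs = 120 * 150
        se = np.sqrt(expected * (1 - expected) / n_obs)
        assert observed == pytest.approx(expected, abs=max(4 * se, 0.2 * expected + 1e-4))
    # single-gene surrogate: mean() aggregator applied to 1-gene sets needs
    # min_genes=1; rate approximates the two-sided normal tail ~0.099
    singles = GeneSetCollection(
        [GeneSet(f"one{i}", (g,), (("t", "s"),))
         for i, g in enumerate(rng.choice(genes, 300, replace=False))]
    )
    m1 = mscores(singles, z, min_genes=1)
    rate = float((m1.values.abs() >= 1.65).to_numpy().mean())
    assert rate == pytest.approx(2 * stats.norm.sf(1.65), abs=0.01)
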