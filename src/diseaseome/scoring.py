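"""Gene-level z-scores against the healthy reference and single-sample
gene-set M-scores.

For each disease sample s and gene g,

    z[g, s] = (x[g, s] - mean_REF(g)) / sd_REF(g)

with the reference sd computed with the n−1 denominator and floored at a
small epsilon to avoid division blow-ups. The M-score of a gene set S in
sample s is the arithmetic mean of the member-gene z-scores — the signed
mean, so sets mixing up- and down-regulated genes cancel toward zero, which
is precisely what the granularity-splitting stage exploits. The aggregator
is pluggable for experimentation.

A set is called significantly dysregulated in a sample when |M| >= 1.65, the
5% critical value of the standard normal distribution.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import DegenerateDatasetError
from .types import (
    DEFAULT_M_THRESHOLD,
    ExpressionDataset,
    GeneSetCollection,
    MScoreMatrix,
    ZScoreMatrix,
)

#: Floor applied to the reference sd.
SD_EPSILON = 1e-6


def gene_zscores(dataset: ExpressionDataset, min_reference: int = 3) -> ZScoreMatrix:
    """Z-score every gene of every DISEASE sample against the REFERENCE
    distribution of the same dataset."""
    dataset.validate_for_scoring(min_per_group=1)
    ref = dataset.reference_values
    if ref.shape[1] < min_reference:
        raise DegenerateDatasetError(
            f"{dataset.dataset_id}: need >= {min_reference} REFERENCE samples"
        )
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1).clip(lower=SD_EPSILON)
    z = dataset.disease_values.sub(mu, axis=0).div(sd, axis=0)
    return ZScoreMatrix(dataset_id=dataset.dataset_id, values=z)


def mscores(
    collection: GeneSetCollection,
    z: ZScoreMatrix,
    min_genes: int = 3,
    threshold: float = DEFAULT_M_THRESHOLD,
    aggregator: Callable[[np.ndarray], np.ndarray] | None = None,
) -> MScoreMatrix:
    """Aggregate member-gene z-scores into one score per (set, sample).

    Genes absent from the dataset are dropped from a set for scoring; sets
    with fewer than ``min_genes`` present genes get NaN rows and are listed
    in ``flagged``. The default aggregator is the mean; a custom
    ``aggregator`` receives the (present genes × samples) z block and must
    return one value per sample.
    """
    gene_pos = {g: i for i, g in enumerate(z.values.index)}
    n_samples = z.values.shape[1]
    out = np.full((len(collection), n_samples), np.nan)
    flagged: list[str] = []

    if aggregator is None:
        # sparse membership matrix: fast path for the mean
        rows, cols = [], []
        sizes = np.zeros(len(collection))
        for i, s in enumerate(collection):
            present = [gene_pos[g] for g in s.genes if g in gene_pos]
            if len(present) < min_genes:
                flagged.append(s.set_id)
                continue
            rows.extend([i] * len(present))
            cols.extend(present)
            sizes[i] = len(present)
        if rows:
            A = sparse.csr_matrix(
                (np.ones(len(rows)), (rows, cols)),
                shape=(len(collection), z.values.shape[0]),
            )
            sums = A @ z.values.to_numpy()
            scored = sizes > 0
            out[scored] = sums[scored] / sizes[scored, None]
    else:
        zv = z.values.to_numpy()
        for i, s in enumerate(collection):
            present = [gene_pos[g] for g in s.genes if g in gene_pos]
            if len(present) < min_genes:
                flagged.append(s.set_id)
                continue
            out[i] = aggregator(zv[present])

    values = pd.DataFrame(out, index=list(collection.ids), columns=z.values.columns)
    return MScoreMatrix(
        dataset_id=z.dataset_id,
        values=values,
        threshold=threshold,
        flagged=tuple(flagged),
    )


def significant_fraction(m: MScoreMatrix, set_id: str) -> float:
    """Fraction of disease samples with ``|M| >= threshold`` (inclusive).

    Returns NaN for a set that was flagged (not scored); raises ``KeyError``
    for an unknown set id.
    """
    if set_id not in m.values.index:
        raise KeyError(f"set {set_id!r} not scored in dataset {m.dataset_id!r}")
    row = m.values.loc[set_id]
    if row.isna().all():
        return float("nan")
    return float((row.abs() >= m.threshold).mean())


def significant_fractions(m: MScoreMatrix) -> pd.Series:
    """Vectorized :func:`significant_fraction` over all rows."""
    frac = (m.values.abs() >= m.threshold).mean(axis=1)
    frac[m.values.isna().all(axis=1)] = np.nan
    return frac
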