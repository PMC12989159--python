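"""In-scope preprocessing: duplicate-gene merging and near-zero-variance
filtering.

Input matrices are assumed already normalized and log-scale. Duplicate gene
rows (multiple probes annotated to one symbol) are merged by the per-sample
median. Genes that are near-constant (sample standard deviation below a
threshold, default 0.05) in *either* sample group are removed: a gene that is
flat in the healthy reference makes downstream z-scores unstable even if it
varies among cases, so the conservative either-group reading is used. The
standard deviation uses the n−1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDatasetError
from .types import ExpressionDataset


@dataclass(frozen=True)
class PreprocessParams:
    """Near-zero-variance threshold; the merge statistic is fixed to the
    median."""

    sd_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be positive")


def merge_duplicates(dataset: ExpressionDataset) -> ExpressionDataset:
    """Collapse duplicate gene rows to their per-sample median.

    Gene order is the order of first occurrence; the order of the duplicate
    rows themselves does not matter (the median is symmetric).
    """
    if not dataset.genes.duplicated().any():
        return dataset
    merged = dataset.values.groupby(level=0, sort=False).median()
    first_seen = dataset.genes.drop_duplicates()
    merged = merged.loc[first_seen]
    return ExpressionDataset(
        dataset_id=dataset.dataset_id, values=merged, groups=dataset.groups
    )


def variance_filter(
    dataset: ExpressionDataset, params: PreprocessParams = PreprocessParams()
) -> ExpressionDataset:
    """Drop genes near-constant in either sample group.

    A gene survives iff its sample sd (ddof=1) is ``>= sd_threshold`` in the
    DISEASE group *and* in the REFERENCE group. Groups with fewer than two
    samples have undefined sd and count as near-constant. Order is preserved;
    removing every gene raises :class:`DegenerateDatasetError`.
    """
    dis = dataset.disease_values
    ref = dataset.reference_values
    if dis.shape[1] == 0 or ref.shape[1] == 0:
        raise DegenerateDatasetError(
            f"{dataset.dataset_id}: both sample groups must be present"
        )
    sd_dis = dis.std(axis=1, ddof=1).fillna(0.0)
    sd_ref = ref.std(axis=1, ddof=1).fillna(0.0)
    keep = (sd_dis >= params.sd_threshold) & (sd_ref >= params.sd_threshold)
    if not keep.any():
        raise DegenerateDatasetError(
            f"{dataset.dataset_id}: variance filter removed all genes "
            f"(sd_threshold={params.sd_threshold})"
        )
    return ExpressionDataset(
        dataset_id=dataset.dataset_id,
        values=dataset.values.loc[keep.to_numpy()],
        groups=dataset.groups,
    )


def preprocess(
    dataset: ExpressionDataset, params: PreprocessParams = PreprocessParams()
) -> ExpressionDataset:
    """``merge_duplicates`` followed by ``variance_filter``."""
    return variance_filter(merge_duplicates(dataset), params)
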