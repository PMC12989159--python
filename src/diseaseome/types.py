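"""Core domain containers.

The pipeline moves between four kinds of objects:

* :class:`ExpressionDataset` — one cohort's genes × samples log-expression
  matrix with a DISEASE / REFERENCE label per sample.
* :class:`GeneSet` / :class:`GeneSetCollection` — named gene lists with
  multi-source annotation terms and split provenance.
* :class:`ZScoreMatrix` / :class:`MScoreMatrix` — per-dataset gene-level and
  gene-set-level dysregulation scores of the disease samples relative to the
  same dataset's healthy reference.
* :class:`DiseaseomeModel` — the final disease-relevant collection with
  hierarchical (round-1 / round-2) functional labels.

Gene identifiers are opaque, case-sensitive strings; no symbol aliasing is
performed (annotation to gene symbols is assumed to happen upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDatasetError, ExpressionFormatError

#: Sample-group label for disease (case) samples.
DISEASE = "DISEASE"
#: Sample-group label for healthy-reference samples.
REFERENCE = "REFERENCE"
#: Default |M-score| significance cut-off; 1.65 is the 5% critical value of
#: the standard normal distribution.
DEFAULT_M_THRESHOLD = 1.65

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class GeneSet:
    """A named gene list with annotation terms and split provenance.

    Parameters
    ----------
    set_id
        Unique identifier within a collection.
    genes
        Member gene symbols. Duplicates are removed, first occurrence wins;
        order is preserved for stable serialization.
    terms
        ``(annotation term, source database)`` pairs.
    parent_id
        Identifier of the pathway this set was split from, if any.
    """

    set_id: str
    genes: tuple[str, ...]
    terms: tuple[tuple[str, str], ...] = ()
    parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(dict.fromkeys(self.genes)))
        object.__setattr__(
            self, "terms", tuple(dict.fromkeys(tuple(t) for t in self.terms))
        )

    @cached_property
    def gene_set(self) -> frozenset:
        return frozenset(self.genes)

    @property
    def size(self) -> int:
        return len(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def with_extra_terms(self, terms: Iterable[tuple[str, str]]) -> "GeneSet":
        """Return a copy carrying additional annotation terms (co-annotation)."""
        merged = tuple(dict.fromkeys(list(self.terms) + [tuple(t) for t in terms]))
        return replace(self, terms=merged)


class GeneSetCollection:
    """An ordered collection of :class:`GeneSet` with unique ids."""

    def __init__(self, sets: Iterable[GeneSet]):
        self.sets: tuple[GeneSet, ...] = tuple(sets)
        by_id: dict[str, GeneSet] = {}
        dupes = []
        for s in self.sets:
            if s.set_id in by_id:
                dupes.append(s.set_id)
            by_id[s.set_id] = s
        if dupes:
            raise ValueError(f"duplicate set ids in collection: {sorted(set(dupes))}")
        self._by_id = by_id

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._by_id

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._by_id[set_id]

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneSetCollection) and self.sets == other.sets

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.set_id for s in self.sets)

    @cached_property
    def gene_universe(self) -> frozenset:
        return frozenset(g for s in self.sets for g in s.genes)

    def sizes(self) -> np.ndarray:
        return np.array([s.size for s in self.sets], dtype=int)

    def subset(self, ids: Iterable[str]) -> "GeneSetCollection":
        """Sub-collection restricted to ``ids``, preserving original order."""
        wanted = set(ids)
        return GeneSetCollection(s for s in self.sets if s.set_id in wanted)

    def replace_sets(self, new_sets: Mapping[str, GeneSet]) -> "GeneSetCollection":
        """Swap individual members (e.g. after co-annotation), keeping order."""
        return GeneSetCollection(new_sets.get(s.set_id, s) for s in self.sets)


@dataclass
class ExpressionDataset:
    """One cohort: a genes × samples log-expression matrix plus group labels.

    ``values`` rows are gene symbols (duplicates permitted until
    :func:`diseaseome.preprocess.merge_duplicates` runs), columns are sample
    ids. ``groups`` maps every sample to ``DISEASE`` or ``REFERENCE``.
    """

    dataset_id: str
    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        cols = self.values.columns
        if cols.duplicated().any():
            raise ExpressionFormatError(
                f"{self.dataset_id}: duplicate sample ids "
                f"{sorted(cols[cols.duplicated()].unique())}"
            )
        missing = [c for c in cols if c not in self.groups.index]
        if missing:
            raise ExpressionFormatError(
                f"{self.dataset_id}: samples without a group label: {missing}"
            )
        self.groups = self.groups.reindex(cols)
        bad = sorted(set(self.groups.unique()) - {DISEASE, REFERENCE})
        if bad:
            raise ExpressionFormatError(
                f"{self.dataset_id}: unknown group labels {bad}; "
                f"expected {DISEASE!r} or {REFERENCE!r}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def disease_samples(self) -> list[str]:
        return [s for s in self.samples if self.groups[s] == DISEASE]

    @property
    def reference_samples(self) -> list[str]:
        return [s for s in self.samples if self.groups[s] == REFERENCE]

    @property
    def disease_values(self) -> pd.DataFrame:
        return self.values[self.disease_samples]

    @property
    def reference_values(self) -> pd.DataFrame:
        return self.values[self.reference_samples]

    def validate_for_scoring(self, min_per_group: int = 3) -> None:
        """Check the invariants scoring relies on (≥3 samples per group,
        no duplicate genes, no missing values)."""
        if len(self.disease_samples) < min_per_group:
            raise DegenerateDatasetError(
                f"{self.dataset_id}: fewer than {min_per_group} {DISEASE} samples"
            )
        if len(self.reference_samples) < min_per_group:
            raise DegenerateDatasetError(
                f"{self.dataset_id}: fewer than {min_per_group} {REFERENCE} samples"
            )
        if self.genes.duplicated().any():
            raise ExpressionFormatError(
                f"{self.dataset_id}: duplicate gene rows; run merge_duplicates first"
            )
        if self.values.isna().any().any():
            raise ExpressionFormatError(f"{self.dataset_id}: missing values in matrix")


@dataclass
class ZScoreMatrix:
    """Gene-level dysregulation of each disease sample versus the healthy
    reference of the same dataset (genes × disease samples)."""

    dataset_id: str
    values: pd.DataFrame


@dataclass
class MScoreMatrix:
    """Gene-set × disease-sample M-scores for one dataset.

    Rows of ``values`` are set ids; sets with fewer present genes than the
    scoring minimum hold NaN rows and are listed in ``flagged``.
    """

    dataset_id: str
    values: pd.DataFrame
    threshold: float = DEFAULT_M_THRESHOLD
    flagged: tuple[str, ...] = ()

    def subset(self, ids: Sequence[str]) -> "MScoreMatrix":
        keep = [i for i in ids if i in self.values.index]
        return MScoreMatrix(
            dataset_id=self.dataset_id,
            values=self.values.loc[keep],
            threshold=self.threshold,
            flagged=tuple(f for f in self.flagged if f in set(keep)),
        )


@dataclass
class DiseaseomeModel:
    """Final disease-relevant gene-set collection with three-level labels.

    ``cluster_tree`` maps round-1 cluster ids to round-2 cluster ids to the
    member set ids; ``round1_labels`` / ``round2_labels`` map each set id to
    its main-function and specific-function label. ``provenance`` records the
    parameters used at every stage.
    """

    drgs: GeneSetCollection
    round1_labels: dict[str, str] = field(default_factory=dict)
    round2_labels: dict[str, str] = field(default_factory=dict)
    cluster_tree: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def validate(self) -> None:
        ids = set(self.drgs.ids)
        if set(self.round1_labels) != ids or set(self.round2_labels) != ids:
            raise ValueError("every DRG needs exactly one round-1 and round-2 label")
        seen: set[str] = set()
        for r1, subs in self.cluster_tree.items():
            for r2, members in subs.items():
                overlap = seen & set(members)
                if overlap:
                    raise ValueError(f"sets in multiple clusters: {sorted(overlap)}")
                seen |= set(members)
        if seen != ids:
            raise ValueError("cluster tree does not partition the DRGs")
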