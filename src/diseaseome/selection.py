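"""Multi-cohort selection of disease-relevant gene sets (DRGs) and the
random-gene-set parameter optimization.

A gene set counts as significantly dysregulated in a dataset when at least
``perc_samples`` percent of that dataset's disease samples have
|M-score| >= 1.65; it is retained as a DRG when that holds in at least
``min_datasets`` datasets. Requiring only a fraction of patients captures
subgroup-restricted biology, while the cross-dataset requirement suppresses
cohort-specific artefacts.

The two parameters are calibrated on a technical background of random gene
sets (sizes drawn between the 10th and 90th percentile of the real
collection's sizes): for every grid combination the pipeline records the
false-positive rate on the random sets, the average information loss (how
many fewer principal components are needed to reach 80% of the variance of
the score matrix after filtering), and the Shannon diversity of the retained
sets' functional-term roots. Eligible combinations must call significances
in at least 10% of samples and 30% of datasets with an FPR below 5%; among
those, the one with minimal information loss wins, ties going to the higher
Shannon index.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import NoEligibleParametersError
from .scoring import significant_fractions
from .types import (
    DEFAULT_M_THRESHOLD,
    GeneSet,
    GeneSetCollection,
    MScoreMatrix,
)


@dataclass(frozen=True)
class FilterParams:
    """Meta-filter thresholds: minimum percent of disease samples significant
    per dataset, and minimum number of datasets."""

    perc_samples: float = 12.0
    min_datasets: int = 7
    m_threshold: float = DEFAULT_M_THRESHOLD

    def __post_init__(self) -> None:
        if not 0 < self.perc_samples <= 100:
            raise ValueError("perc_samples must be in (0, 100]")
        if self.min_datasets < 1:
            raise ValueError("min_datasets must be >= 1")


@dataclass(frozen=True)
class OptConstraints:
    """Eligibility constraints of the step-wise parameter selection."""

    min_perc: float = 10.0
    min_dataset_frac: float = 0.30
    max_fpr: float = 5.0


@dataclass(frozen=True)
class GridPoint:
    perc_samples: float
    min_datasets: int
    fpr: float
    info_loss: float
    shannon: float
    n_retained: int


@dataclass
class OptimizationReport:
    grid: list[GridPoint]
    chosen: GridPoint
    constraints: OptConstraints = OptConstraints()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.grid])


def significance_proportions(
    collection: GeneSetCollection | Sequence[str],
    mscores: Sequence[MScoreMatrix],
) -> pd.DataFrame:
    """Set × dataset table of significant-sample fractions (NaN where a set
    was not scored in a dataset)."""
    ids = list(collection.ids if isinstance(collection, GeneSetCollection) else collection)
    cols = {}
    for m in mscores:
        cols[m.dataset_id] = significant_fractions(m).reindex(ids)
    return pd.DataFrame(cols, index=ids)


def passing_mask(props: pd.DataFrame, params: FilterParams) -> pd.Series:
    """Boolean per set: does it pass the meta-filter? Both comparisons are
    inclusive; NaN fractions never count."""
    hits = (props >= params.perc_samples / 100.0).sum(axis=1)
    return hits >= params.min_datasets


def filter_gene_sets(
    collection: GeneSetCollection, props: pd.DataFrame, params: FilterParams
) -> GeneSetCollection:
    """Collection restricted to the sets passing the meta-filter."""
    mask = passing_mask(props, params)
    return collection.subset(mask.index[mask])


def random_gene_sets(
    universe: Iterable[str],
    n: int,
    size_range: tuple[int, int],
    seed: int,
    prefix: str = "RAND",
) -> GeneSetCollection:
    """``n`` random sets with sizes uniform on the integer interval
    ``size_range``, genes drawn without replacement from ``universe``."""
    pool = np.array(sorted(universe))
    lo, hi = size_range
    if hi > len(pool):
        raise ValueError(
            f"gene universe ({len(pool)}) smaller than the maximum set size {hi}"
        )
    rng = np.random.default_rng(seed)
    sets = []
    for i in range(n):
        size = int(rng.integers(lo, hi + 1))
        genes = rng.choice(pool, size=size, replace=False)
        sets.append(
            GeneSet(
                set_id=f"{prefix}{i:04d}",
                genes=tuple(genes),
                terms=(("random background", "random"),),
            )
        )
    return GeneSetCollection(sets)


def sample_random_genesets(
    universe: Iterable[str],
    reference: GeneSetCollection,
    n: int = 1000,
    seed: int = 0,
) -> GeneSetCollection:
    """Random background sized like the real collection: sizes uniform
    between its 10th and 90th size percentiles (linear interpolation,
    rounded, floored at 3)."""
    sizes = reference.sizes()
    p10, p90 = np.percentile(sizes, [10, 90])
    lo = max(3, int(round(p10)))
    hi = max(lo, int(round(p90)))
    return random_gene_sets(universe, n, (lo, hi), seed)


def false_positive_rate(
    random_sets: GeneSetCollection,
    mscores: Sequence[MScoreMatrix],
    params: FilterParams,
) -> float:
    """Percent of random sets that pass the meta-filter."""
    if len(random_sets) == 0:
        raise ValueError("no random sets provided")
    props = significance_proportions(random_sets, mscores)
    return 100.0 * float(passing_mask(props, params).mean())


def pca_components_for_variance(values: np.ndarray, var_frac: float = 0.8) -> int:
    """Smallest number of principal components of a (sets × samples) matrix
    reaching ``var_frac`` cumulative explained variance.

    Rows are the observations (gene sets); single-row or zero-variance
    matrices need one component by convention.
    """
    X = np.asarray(values, dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    if X.shape[0] <= 1:
        return 1
    X = X - X.mean(axis=0)
    sv = np.linalg.svd(X, compute_uv=False)
    var = sv**2
    total = var.sum()
    if total <= 0:
        return 1
    cum = np.cumsum(var) / total
    return int(np.searchsorted(cum, var_frac - 1e-12) + 1)


def information_loss(
    mscores_full: MScoreMatrix, mscores_filtered: MScoreMatrix, var_frac: float = 0.8
) -> float:
    """Relative drop in the number of principal components needed for
    ``var_frac`` of the variance when replacing the full score matrix by the
    filtered one; clipped at 0 from below."""
    extra = set(mscores_filtered.values.index) - set(mscores_full.values.index)
    if extra:
        raise ValueError(f"filtered rows not in full matrix: {sorted(extra)}")
    k_full = pca_components_for_variance(mscores_full.values.to_numpy(), var_frac)
    if mscores_filtered.values.shape[0] == 0:
        return 1.0
    k_filt = pca_components_for_variance(mscores_filtered.values.to_numpy(), var_frac)
    return max(0.0, (k_full - k_filt) / k_full)


def shannon_index(labels: Sequence[str]) -> float:
    """Shannon diversity H = −Σ p ln p of a list of category labels."""
    labels = list(labels)
    if not labels:
        raise ValueError("shannon_index requires a non-empty label list")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


_TOKEN_RE = re.compile(r"[A-Za-z]+")


def term_root(gene_set: GeneSet) -> str:
    """Coarse functional root of a set: the first alphabetic token of its
    first annotation term (lowercase). Used for diversity bookkeeping when
    no curated ontology roots are available."""
    for term, _src in gene_set.terms:
        m = _TOKEN_RE.search(term)
        if m:
            return m.group(0).lower()
    return gene_set.set_id


def optimize_parameters(
    collection: GeneSetCollection,
    mscores: Sequence[MScoreMatrix],
    random_sets: GeneSetCollection,
    random_mscores: Sequence[MScoreMatrix],
    roots: Optional[Mapping[str, str]] = None,
    grid_perc: Iterable[float] = range(1, 31),
    grid_datasets: Optional[Iterable[int]] = None,
    constraints: OptConstraints = OptConstraints(),
    var_frac: float = 0.8,
) -> OptimizationReport:
    """Grid search over (perc_samples, min_datasets).

    For every grid point: FPR on the random background, average information
    loss over datasets, Shannon index of the retained sets' term roots, and
    the retained count. Eligible points satisfy the constraints; selection
    is step-wise — minimal information loss, then maximal Shannon, then more
    sets retained, then the smaller (perc_samples, min_datasets) pair.
    """
    n_datasets = len(mscores)
    if grid_datasets is None:
        grid_datasets = range(1, n_datasets + 1)
    if roots is None:
        roots = {s.set_id: term_root(s) for s in collection}

    props = significance_proportions(collection, mscores)
    props_rand = significance_proportions(random_sets, random_mscores)
    k_full = {
        m.dataset_id: pca_components_for_variance(m.values.to_numpy(), var_frac)
        for m in mscores
    }

    min_md = math.ceil(constraints.min_dataset_frac * n_datasets)
    grid: list[GridPoint] = []
    eligible: list[GridPoint] = []
    for perc in grid_perc:
        params_hits = (props >= perc / 100.0).sum(axis=1)
        rand_hits = (props_rand >= perc / 100.0).sum(axis=1)
        for md in grid_datasets:
            mask = params_hits >= md
            kept_ids = list(props.index[mask])
            fpr = 100.0 * float((rand_hits >= md).mean())
            losses = []
            for m in mscores:
                sub = m.values.loc[[i for i in kept_ids if i in m.values.index]]
                if sub.shape[0] == 0:
                    losses.append(1.0)
                else:
                    kf = pca_components_for_variance(sub.to_numpy(), var_frac)
                    losses.append(max(0.0, (k_full[m.dataset_id] - kf) / k_full[m.dataset_id]))
            loss = float(np.mean(losses)) if losses else 1.0
            shannon = (
                shannon_index([roots.get(i, i) for i in kept_ids]) if kept_ids else 0.0
            )
            point = GridPoint(
                perc_samples=float(perc),
                min_datasets=int(md),
                fpr=fpr,
                info_loss=loss,
                shannon=shannon,
                n_retained=len(kept_ids),
            )
            grid.append(point)
            if (
                perc >= constraints.min_perc
                and md >= min_md
                and fpr < constraints.max_fpr
            ):
                eligible.append(point)

    if not eligible:
        near = sorted(grid, key=lambda p: p.fpr)[:5]
        raise NoEligibleParametersError(
            "no (perc_samples, min_datasets) combination satisfies the "
            f"constraints (min_perc={constraints.min_perc}, "
            f"min_datasets>={min_md}, FPR<{constraints.max_fpr}); "
            f"lowest-FPR grid points: {[(p.perc_samples, p.min_datasets, p.fpr) for p in near]}",
            nearest_misses=near,
        )

    chosen = min(
        eligible,
        key=lambda p: (
            p.info_loss,
            -p.shannon,
            -p.n_retained,
            p.perc_samples,
            p.min_datasets,
        ),
    )
    return OptimizationReport(grid=grid, chosen=chosen, constraints=constraints)
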