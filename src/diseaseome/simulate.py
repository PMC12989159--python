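"""Synthetic multi-cohort expression data with planted pathway structure.

The generator emulates the structure the pipeline consumes: several
independent case/control cohorts of log-scale expression, where each gene
has a cohort-specific Gaussian baseline (mean ~ Normal(7, 1), sd ~
Uniform(0.2, 0.6)) shared by cases and controls, and *planted modules* —
gene groups shifted by ``delta`` reference standard deviations in a random
subgroup of the disease samples of the affected cohorts. Affected-sample
subsets are drawn independently per cohort, mimicking subgroup heterogeneity
across studies; modules that name the same ``sample_group`` share their
affected cohorts and samples, which produces anti-correlated gene blocks
when their deltas have opposite signs.

Pathway specs assemble modules into the structures the pipeline stages are
tested against: a module by itself, the union of an up- and a down-regulated
module (a splitting target), a module padded with noise genes (a
subset-packing target), near-duplicate pairs at controlled Jaccard overlap
(a reduction target), and pure-noise sets (false-positive targets). The
returned :class:`GroundTruth` carries everything needed to score each stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    DISEASE,
    REFERENCE,
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
)


@dataclass(frozen=True)
class PlantedModule:
    """A gene group with a planted disease effect.

    ``delta`` is the shift in units of the gene's reference sd;
    ``frac_samples`` the fraction of disease samples affected in each
    affected cohort; ``frac_datasets`` the fraction of cohorts affected.
    Modules sharing a ``sample_group`` share affected cohorts and samples.
    """

    name: str
    genes: tuple[str, ...]
    delta: float = 2.0
    frac_samples: float = 0.5
    frac_datasets: float = 1.0
    sample_group: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 < self.frac_samples <= 1:
            raise ValueError("frac_samples must be in (0, 1]")
        if len(self.genes) < 3:
            raise ValueError("module size must be >= 3")


@dataclass(frozen=True)
class PathwaySpec:
    """How planted modules (and noise genes) are assembled into pathways.

    ``kind`` is one of ``module``, ``opposite_pair``, ``superset``,
    ``near_duplicate`` (emits two overlapping sets, ids suffixed ``a``/``b``)
    or ``noise``; ``modules`` names planted modules, ``n_extra`` adds that
    many non-module genes.
    """

    pathway_id: str
    kind: str
    modules: tuple[str, ...] = ()
    n_extra: int = 0
    term: str = ""
    source: str = "SIM"


@dataclass(frozen=True)
class SimulationConfig:
    n_datasets: int = 15
    n_genes: int = 2000
    n_disease: int = 60
    n_reference: int = 20
    baseline_mean: tuple[float, float] = (7.0, 1.0)  # Normal(loc, scale)
    baseline_sd: tuple[float, float] = (0.2, 0.6)  # Uniform(lo, hi)
    planted_modules: tuple[PlantedModule, ...] = ()
    pathways: tuple[PathwaySpec, ...] = ()
    seed: int = 0


@dataclass
class GroundTruth:
    """Per-stage answer key for a simulated scenario."""

    module_genes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    affected_datasets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    affected_samples: dict[tuple[str, str], tuple[str, ...]] = field(
        default_factory=dict
    )
    pathway_partition: dict[str, list[tuple[str, ...]]] = field(default_factory=dict)
    noise_pathways: tuple[str, ...] = ()


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def allocate_modules(
    sizes: Sequence[int],
    config_or_genes,
    seed: int = 0,
    names: Optional[Sequence[str]] = None,
    **module_kwargs,
) -> list[PlantedModule]:
    """Carve disjoint modules of the given sizes out of the gene pool."""
    if isinstance(config_or_genes, SimulationConfig):
        pool = _gene_names(config_or_genes.n_genes)
    else:
        pool = list(config_or_genes)
    if sum(sizes) > len(pool):
        raise ValueError("module sizes exceed the gene pool")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=sum(sizes), replace=False)
    out = []
    start = 0
    for i, size in enumerate(sizes):
        genes = tuple(pool[j] for j in chosen[start : start + size])
        start += size
        name = names[i] if names else f"M{i:03d}"
        out.append(PlantedModule(name=name, genes=genes, **module_kwargs))
    return out


def simulate_cohorts(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], GeneSetCollection, GroundTruth]:
    """Generate the cohorts, the pathway collection, and the ground truth."""
    genes = _gene_names(config.n_genes)
    gene_index = set(genes)
    for mod in config.planted_modules:
        extra = set(mod.genes) - gene_index
        if extra:
            raise ValueError(f"module {mod.name}: genes outside the pool: {sorted(extra)}")

    root = np.random.SeedSequence(config.seed)
    ss_data, ss_assign, ss_paths = root.spawn(3)
    rng_assign = np.random.default_rng(ss_assign)

    dataset_ids = [f"DS{i + 1:02d}" for i in range(config.n_datasets)]

    # shared affected-cohort / affected-sample draws per sample group
    group_key = {m.name: (m.sample_group or m.name) for m in config.planted_modules}
    group_of = {}
    for m in config.planted_modules:
        group_of.setdefault(group_key[m.name], m)
    affected_ds: dict[str, tuple[str, ...]] = {}
    for gkey, m in group_of.items():
        n_aff = int(round(m.frac_datasets * config.n_datasets))
        n_aff = min(max(n_aff, 1 if m.frac_datasets > 0 else 0), config.n_datasets)
        idx = sorted(
            rng_assign.choice(config.n_datasets, size=n_aff, replace=False)
        )
        affected_ds[gkey] = tuple(dataset_ids[i] for i in idx)
    sample_draw: dict[tuple[str, str], tuple[int, ...]] = {}

    truth = GroundTruth()
    for m in config.planted_modules:
        truth.module_genes[m.name] = m.genes
        truth.affected_datasets[m.name] = affected_ds[group_key[m.name]]

    datasets: list[ExpressionDataset] = []
    for ds_i, (ds_id, child) in enumerate(
        zip(dataset_ids, ss_data.spawn(config.n_datasets))
    ):
        rng = np.random.default_rng(child)
        loc, scale = config.baseline_mean
        lo, hi = config.baseline_sd
        mean = rng.normal(loc, scale, size=config.n_genes)
        sd = rng.uniform(lo, hi, size=config.n_genes)
        n_s = config.n_disease + config.n_reference
        X = mean[:, None] + sd[:, None] * rng.standard_normal((config.n_genes, n_s))
        dis_cols = [f"{ds_id}_D{i + 1:03d}" for i in range(config.n_disease)]
        ref_cols = [f"{ds_id}_R{i + 1:03d}" for i in range(config.n_reference)]
        gene_pos = {g: i for i, g in enumerate(genes)}

        for m in config.planted_modules:
            gkey = group_key[m.name]
            if ds_id not in affected_ds[gkey]:
                continue
            key = (ds_id, gkey)
            if key not in sample_draw:
                n_hit = max(1, int(round(m.frac_samples * config.n_disease)))
                sample_draw[key] = tuple(
                    sorted(
                        rng_assign.choice(
                            config.n_disease, size=n_hit, replace=False
                        )
                    )
                )
            cols = sample_draw[key]
            rows = [gene_pos[g] for g in m.genes]
            X[np.ix_(rows, list(cols))] += m.delta * sd[rows, None]
            truth.affected_samples[(ds_id, m.name)] = tuple(
                dis_cols[c] for c in cols
            )

        values = pd.DataFrame(X, index=genes, columns=dis_cols + ref_cols)
        groups = pd.Series(
            [DISEASE] * config.n_disease + [REFERENCE] * config.n_reference,
            index=dis_cols + ref_cols,
        )
        datasets.append(
            ExpressionDataset(dataset_id=ds_id, values=values, groups=groups)
        )

    collection = _build_pathways(config, genes, truth, np.random.default_rng(ss_paths))
    return datasets, collection, truth


def _build_pathways(
    config: SimulationConfig,
    genes: list[str],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> GeneSetCollection:
    module_genes = {m.name: m.genes for m in config.planted_modules}
    in_modules = {g for gs in module_genes.values() for g in gs}
    noise_pool = np.array([g for g in genes if g not in in_modules])

    def draw_noise(n: int) -> tuple[str, ...]:
        return tuple(rng.choice(noise_pool, size=n, replace=False))

    sets: list[GeneSet] = []
    noise_ids = []
    for spec in config.pathways:
        mods = [module_genes[name] for name in spec.modules]
        term = spec.term or spec.pathway_id
        terms = ((term, spec.source),)
        if spec.kind == "module":
            sets.append(
                GeneSet(spec.pathway_id, mods[0] + draw_noise(spec.n_extra), terms)
            )
        elif spec.kind == "opposite_pair":
            merged = tuple(g for gs in mods for g in gs) + draw_noise(spec.n_extra)
            sets.append(GeneSet(spec.pathway_id, merged, terms))
            truth.pathway_partition[spec.pathway_id] = [tuple(gs) for gs in mods]
        elif spec.kind == "superset":
            sets.append(
                GeneSet(
                    spec.pathway_id,
                    tuple(g for gs in mods for g in gs) + draw_noise(spec.n_extra),
                    terms,
                )
            )
        elif spec.kind == "near_duplicate":
            base = mods[0]
            swap = draw_noise(1)
            sets.append(GeneSet(spec.pathway_id + "a", base, terms))
            sets.append(
                GeneSet(spec.pathway_id + "b", base[:-1] + swap, terms)
            )
        elif spec.kind == "noise":
            sets.append(GeneSet(spec.pathway_id, draw_noise(spec.n_extra), terms))
            noise_ids.append(spec.pathway_id)
        else:
            raise ValueError(f"unknown pathway kind {spec.kind!r}")
    truth.noise_pathways = tuple(noise_ids)
    return GeneSetCollection(sets)


def simulate_null(config: SimulationConfig) -> tuple[
    list[ExpressionDataset], GeneSetCollection, GroundTruth
]:
    """Same generative model with no planted effects (the FPR backdrop)."""
    from dataclasses import replace

    return simulate_cohorts(replace(config, planted_modules=(), pathways=()))


def splitter_scenario(
    n_pathways: int = 20,
    n_datasets: int = 3,
    module_size: int = 6,
    n_genes: int = 1000,
    n_disease: int = 60,
    n_reference: int = 20,
    delta: float = 2.5,
    frac_samples: float = 0.5,
    seed: int = 0,
) -> SimulationConfig:
    """Planted two-module pathways for splitter-recovery checks.

    Each pathway is the union of an up- and a down-regulated module of
    ``module_size`` genes; the two modules share their affected samples so
    their genes are anti-correlated across patients.
    """
    from dataclasses import replace

    names = [f"{d}{i}" for i in range(n_pathways) for d in ("UP", "DN")]
    allocated = allocate_modules(
        [module_size] * (2 * n_pathways),
        SimulationConfig(n_genes=n_genes),
        seed=seed,
        names=names,
    )
    modules, pathways = [], []
    for i in range(n_pathways):
        up = replace(
            allocated[2 * i],
            delta=delta,
            frac_samples=frac_samples,
            sample_group=f"grp{i}",
        )
        dn = replace(
            allocated[2 * i + 1],
            delta=-delta,
            frac_samples=frac_samples,
            sample_group=f"grp{i}",
        )
        modules += [up, dn]
        pathways.append(
            PathwaySpec(
                pathway_id=f"PW{i:02d}",
                kind="opposite_pair",
                modules=(up.name, dn.name),
                term=f"planted pathway {i}",
            )
        )
    return SimulationConfig(
        n_datasets=n_datasets,
        n_genes=n_genes,
        n_disease=n_disease,
        n_reference=n_reference,
        planted_modules=tuple(modules),
        pathways=tuple(pathways),
        seed=seed,
    )


def drg_scenario(
    n_true: int = 20,
    n_noise: int = 20,
    module_size: int = 8,
    n_datasets: int = 15,
    n_genes: int = 2000,
    n_disease: int = 60,
    n_reference: int = 20,
    delta: float = 2.0,
    frac_samples: float = 0.25,
    frac_datasets: float = 0.6,
    seed: int = 0,
) -> SimulationConfig:
    """Planted single-module gene sets for sensitivity checks of the
    multi-cohort filter: ``n_true`` truly dysregulated sets (shift ``delta``
    reference sds in ``frac_samples`` of patients of ``frac_datasets`` of
    the cohorts) alongside ``n_noise`` pure-noise sets."""
    from dataclasses import replace

    names = [f"TRUE{i:02d}" for i in range(n_true)]
    allocated = allocate_modules(
        [module_size] * n_true,
        SimulationConfig(n_genes=n_genes),
        seed=seed,
        names=names,
    )
    modules = tuple(
        replace(
            m,
            delta=delta,
            frac_samples=frac_samples,
            frac_datasets=frac_datasets,
        )
        for m in allocated
    )
    pathways = [
        PathwaySpec(
            pathway_id=m.name, kind="module", modules=(m.name,), term=f"planted {m.name}"
        )
        for m in modules
    ] + [
        PathwaySpec(
            pathway_id=f"NULL{i:02d}",
            kind="noise",
            n_extra=module_size,
            term=f"noise set {i}",
        )
        for i in range(n_noise)
    ]
    return SimulationConfig(
        n_datasets=n_datasets,
        n_genes=n_genes,
        n_disease=n_disease,
        n_reference=n_reference,
        planted_modules=modules,
        pathways=tuple(pathways),
        seed=seed,
    )


def simulate_hierarchical_profiles(
    n_main: int = 3,
    n_sub: int = 2,
    sets_per_sub: int = 8,
    cols_per_main: int = 30,
    main_scale: float = 6.0,
    sub_scale: float = 1.5,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Planted hierarchical activity profiles for clustering tests.

    Builds a (sets × samples) matrix with ``n_main`` well-separated main
    blocks each split into ``n_sub`` subgroups by a weaker within-block
    offset. Returns the matrix plus the true main and sub labels.
    """
    rng = np.random.default_rng(seed)
    n_rows = n_main * n_sub * sets_per_sub
    n_cols = n_main * cols_per_main
    X = rng.normal(0.0, noise_sd, size=(n_rows, n_cols))
    main_labels = np.empty(n_rows, dtype=int)
    sub_labels = np.empty(n_rows, dtype=int)
    sub_width = cols_per_main // n_sub
    r = 0
    for m in range(n_main):
        for s in range(n_sub):
            rows = slice(r, r + sets_per_sub)
            X[rows, m * cols_per_main : (m + 1) * cols_per_main] += main_scale
            lo = m * cols_per_main + s * sub_width
            X[rows, lo : lo + sub_width] += sub_scale
            main_labels[rows] = m
            sub_labels[rows] = m * n_sub + s
            r += sets_per_sub
    index = [f"SET{i:03d}" for i in range(n_rows)]
    cols = [f"S{j:03d}" for j in range(n_cols)]
    return (
        pd.DataFrame(X, index=index, columns=cols),
        pd.Series(main_labels, index=index),
        pd.Series(sub_labels, index=index),
    )
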