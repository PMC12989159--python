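"""Readers and writers for the interchange formats.

* GMT gene-set files: ``set_id TAB description TAB gene1 TAB ...``. On
  writing, multiple annotation terms are serialized into the description
  joined by ``" | "`` with ``source:`` prefixes, so the files stay usable by
  standard enrichment tools; round-tripping is lossless for set ids and gene
  memberships (term provenance collapses into the description text).
* Expression matrices: TSV with a header of sample ids and gene symbols in
  the first column, plus a two-column ``sample TAB group`` file using the
  DISEASE / REFERENCE labels.
* The serialized diseaseome model: a JSON document with a schema version.

Genes containing tab or newline characters cannot be represented in GMT and
are rejected at write time (spaces are legal GMT content and pass through).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import ExpressionFormatError, GmtParseError
from .types import (
    DISEASE,
    REFERENCE,
    DiseaseomeModel,
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
    MScoreMatrix,
    SCHEMA_VERSION,
)

PathLike = Union[str, Path]

_TERM_SEP = " | "


def read_gmt(path: PathLike, source: str) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Every non-blank line yields one gene set; the description field is stored
    as a single annotation term attributed to ``source``. Duplicate genes
    within a line are collapsed; duplicate set names across lines are an
    error.
    """
    sets: list[GeneSet] = []
    seen: dict[str, int] = {}
    collisions: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected at least 3 tab-separated "
                    f"fields, found {len(fields)}"
                )
            set_id, desc = fields[0], fields[1]
            genes = tuple(g for g in fields[2:] if g)
            if set_id in seen:
                collisions.append(set_id)
                continue
            seen[set_id] = lineno
            term = desc if desc else set_id
            sets.append(GeneSet(set_id=set_id, genes=genes, terms=((term, source),)))
    if collisions:
        raise GmtParseError(
            f"{path}: duplicate set names: {sorted(set(collisions))}"
        )
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: PathLike) -> None:
    """Write a collection as GMT; see the module docstring for the dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            for g in s.genes:
                if "\t" in g or "\n" in g or "\r" in g:
                    raise ValueError(
                        f"gene {g!r} in set {s.set_id!r} contains a GMT "
                        "delimiter character and cannot be serialized"
                    )
            desc = _TERM_SEP.join(f"{src}:{term}" for term, src in s.terms) or s.set_id
            fh.write("\t".join([s.set_id, desc, *s.genes]) + "\n")


def read_expression(
    path: PathLike, groups_path: PathLike, dataset_id: str
) -> ExpressionDataset:
    """Read an expression TSV and its sample→group file.

    Gene and sample order follow file order exactly. Duplicate gene rows are
    accepted here and resolved later by
    :func:`diseaseome.preprocess.merge_duplicates`. Non-numeric or missing
    cells are reported with their (gene, sample) coordinates; any matrix
    sample lacking a group label is an error.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    missing = values.isna() & raw.isna()
    problems = bad | missing
    if problems.any().any():
        r, c = np.argwhere(problems.to_numpy())[0]
        gene, sample = values.index[r], values.columns[c]
        kind = "non-numeric" if bad.iat[r, c] else "missing"
        raise ExpressionFormatError(
            f"{path}: {kind} value at gene {gene!r}, sample {sample!r}"
        )
    groups = read_groups(groups_path)
    unlabeled = [c for c in values.columns if c not in groups.index]
    if unlabeled:
        raise ExpressionFormatError(
            f"{path}: samples missing from {groups_path}: {unlabeled}"
        )
    return ExpressionDataset(
        dataset_id=dataset_id, values=values.astype(float), groups=groups
    )


def read_groups(path: PathLike) -> pd.Series:
    """Read a two-column sample→group TSV (an optional ``sample  group``
    header line is tolerated)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ExpressionFormatError(f"{path}: expected two tab-separated columns")
    if df.iloc[0, 0].strip().lower() == "sample":
        df = df.iloc[1:]
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")
    bad = sorted(set(s.unique()) - {DISEASE, REFERENCE})
    if bad:
        raise ExpressionFormatError(
            f"{path}: unknown group labels {bad}; expected {DISEASE} or {REFERENCE}"
        )
    return s


def write_expression(dataset: ExpressionDataset, path: PathLike) -> None:
    dataset.values.to_csv(path, sep="\t", index_label="gene")


def write_groups(dataset: ExpressionDataset, path: PathLike) -> None:
    dataset.groups.rename_axis("sample").to_csv(path, sep="\t", header=False)


def write_mscores(m: MScoreMatrix, path: PathLike) -> None:
    """TSV export of an M-score matrix (rows = set ids, columns = samples)."""
    m.values.to_csv(path, sep="\t", index_label="set_id")


def _set_to_dict(s: GeneSet) -> dict:
    return {
        "set_id": s.set_id,
        "genes": list(s.genes),
        "terms": [list(t) for t in s.terms],
        "parent_id": s.parent_id,
    }


def _set_from_dict(d: dict) -> GeneSet:
    return GeneSet(
        set_id=d["set_id"],
        genes=tuple(d["genes"]),
        terms=tuple((t[0], t[1]) for t in d["terms"]),
        parent_id=d.get("parent_id"),
    )


def save_model(model: DiseaseomeModel, path: PathLike) -> None:
    """Serialize a :class:`DiseaseomeModel` as a schema-versioned JSON file."""
    doc = {
        "schema_version": model.schema_version,
        "drgs": [_set_to_dict(s) for s in model.drgs],
        "round1_labels": model.round1_labels,
        "round2_labels": model.round2_labels,
        "cluster_tree": model.cluster_tree,
        "provenance": model.provenance,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path: PathLike) -> DiseaseomeModel:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {version!r}")
    return DiseaseomeModel(
        drgs=GeneSetCollection(_set_from_dict(d) for d in doc["drgs"]),
        round1_labels=dict(doc["round1_labels"]),
        round2_labels=dict(doc["round2_labels"]),
        cluster_tree={
            r1: {r2: list(m) for r2, m in subs.items()}
            for r1, subs in doc["cluster_tree"].items()
        },
        provenance=doc.get("provenance", {}),
        schema_version=version,
    )
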