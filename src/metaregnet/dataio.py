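"""Expression-matrix container, TSV round-tripping, gene-space harmonization.

Cohorts measured on different platforms (RNA-seq counts, microarray
intensities) are carried as :class:`ExpressionMatrix` objects: a genes x
samples grid plus per-sample annotations (cohort, histological subtype,
batch).  Downstream network inference requires a common gene space, obtained
by intersecting the gene lists of all cohorts, and subtype-stratified
matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

PLATFORMS = ("counts", "intensity")


class DataIOError(ValueError):
    """Raised for malformed inputs or contract violations in this module."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression grid with a platform tag and annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier, columns are sample identifiers.
    platform
        ``"counts"`` (non-negative integers, RNA-seq style) or
        ``"intensity"`` (continuous, microarray style).
    annotations
        Optional DataFrame indexed by sample identifier with columns such as
        ``cohort``, ``subtype`` and ``batch``.
    """

    values: pd.DataFrame
    platform: str
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise DataIOError(
                f"unknown platform {self.platform!r}; expected one of {PLATFORMS}"
            )
        dup_genes = self.values.index[self.values.index.duplicated()].unique()
        if len(dup_genes):
            raise DataIOError(f"duplicate gene identifiers: {list(dup_genes)}")
        dup_samples = self.values.columns[self.values.columns.duplicated()].unique()
        if len(dup_samples):
            raise DataIOError(f"duplicate sample identifiers: {list(dup_samples)}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = np.argwhere(
                ~self.values.map(lambda v: isinstance(v, (int, float, np.number))).to_numpy()
            )
            loc = ", ".join(
                f"(gene {self.values.index[i]!r}, sample {self.values.columns[j]!r})"
                for i, j in bad[:5]
            )
            raise DataIOError(f"non-numeric cells at {loc}")
        if self.platform == "counts":
            if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
                raise DataIOError("counts platform requires non-negative integers")
        if self.annotations is not None:
            missing = self.values.columns.difference(self.annotations.index)
            if len(missing):
                raise DataIOError(f"samples without annotations: {list(missing)}")
            self.annotations = self.annotations.loc[self.values.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.platform, self.annotations)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        ann = self.annotations.loc[list(samples)] if self.annotations is not None else None
        return ExpressionMatrix(self.values[list(samples)], self.platform, ann)


@dataclass
class GeneSpace:
    """Intersection of the gene lists of several matrices, with a Venn summary."""

    genes: tuple[str, ...]
    per_source: dict[str, int] = field(default_factory=dict)
    pairwise: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_common": len(self.genes),
                    "per_source": self.per_source,
                    "pairwise": self.pairwise,
                },
                indent=2,
                sort_keys=True,
            )
        )


def read_expression_tsv(path, platform: str, annotations_path=None) -> ExpressionMatrix:
    """Read a genes-rows / samples-columns TSV (first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    for j, col in enumerate(df.columns):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col].map(lambda v: not _is_number(v))
            row = df.index[bad.to_numpy().argmax()]
            raise DataIOError(
                f"non-numeric cell at row {row!r}, column {col!r} in {path}"
            )
    ann = read_annotations_tsv(annotations_path) if annotations_path else None
    return ExpressionMatrix(df, platform, ann)


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_annotations_tsv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0)
    ann.index = ann.index.astype(str)
    return ann


def write_annotations_tsv(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index_label="sample")


def intersect_gene_space(matrices: list[ExpressionMatrix], names=None) -> GeneSpace:
    """Intersect gene lists across matrices; error if the intersection is empty.

    The returned :class:`GeneSpace` also carries per-source and pairwise
    overlap counts (a Venn-diagram summary).  Order-invariant and idempotent:
    gene order in the result follows the first matrix.
    """
    if len(matrices) < 2:
        raise DataIOError("need at least two matrices to intersect")
    if names is None:
        names = [f"matrix{i}" for i in range(len(matrices))]
    sets = [set(m.genes) for m in matrices]
    common = set.intersection(*sets)
    if not common:
        raise DataIOError("empty gene intersection; cohorts share no genes")
    ordered = tuple(g for g in matrices[0].genes if g in common)
    per_source = {n: len(s) for n, s in zip(names, sets)}
    pairwise = {
        f"{names[i]}&{names[j]}": len(sets[i] & sets[j])
        for i in range(len(sets))
        for j in range(i + 1, len(sets))
    }
    return GeneSpace(ordered, per_source, pairwise)


def stratify_samples(matrix: ExpressionMatrix) -> dict[str, ExpressionMatrix]:
    """Partition samples by the ``subtype`` annotation (e.g. diffuse/intestinal)."""
    if matrix.annotations is None or "subtype" not in matrix.annotations.columns:
        raise DataIOError("subtype annotation required for stratification")
    sub = matrix.annotations["subtype"]
    unlabeled = [s for s in matrix.samples if pd.isna(sub.get(s))]
    if unlabeled:
        raise DataIOError(f"samples missing subtype label: {unlabeled}")
    out: dict[str, ExpressionMatrix] = {}
    for name in pd.unique(sub):
        keep = [s for s in matrix.samples if sub[s] == name]
        out[str(name)] = matrix.subset_samples(keep)
    return out


def quartile_classify(values: Mapping[str, float] | pd.Series) -> dict[str, str]:
    """Classify entities into low / mid / high by quartiles of one gene's expression.

    Entities at or below the first quartile are ``low``; at or above the third
    quartile are ``high``; the rest are ``mid``.  Quartiles are empirical
    quantiles with linear interpolation.  A tied value that satisfies both
    boundary conditions simultaneously (degenerate spread) is assigned ``mid``.
    """
    s = pd.Series(values, dtype=float)
    if len(s) < 4:
        raise DataIOError("quartile classification requires at least 4 entities")
    q1, q3 = np.quantile(s.to_numpy(), [0.25, 0.75])
    out = {}
    for entity, v in s.items():
        lo, hi = v <= q1, v >= q3
        if lo and hi:
            out[entity] = "mid"
        elif lo:
            out[entity] = "low"
        elif hi:
            out[entity] = "high"
        else:
            out[entity] = "mid"
    return out


def concatenate(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-wise concatenation of matrices on an identical gene index."""
    first = matrices[0]
    for m in matrices[1:]:
        if m.genes != first.genes:
            raise DataIOError("matrices must share an identical gene index")
        if m.platform != first.platform:
            raise DataIOError("matrices must share a platform")
    values = pd.concat([m.values for m in matrices], axis=1)
    anns = [m.annotations for m in matrices]
    ann = pd.concat(anns) if all(a is not None for a in anns) else None
    return ExpressionMatrix(values, first.platform, ann)
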