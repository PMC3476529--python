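"""Expression-matrix, annotation and gene-set (GMT) input/output.

The on-disk matrix format is tab-delimited with genes in rows and samples in
columns; the first column holds the gene identifier and the header row holds
sample identifiers.  Sample annotations live in a separate tab-delimited file
with one row per sample and the columns ``sample``, ``subset``, ``tissue``,
``species`` and ``donor``.  Gene identifiers are opaque, case-sensitive
strings; missing values are rejected rather than imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ("subset", "tissue", "species", "donor")

__all__ = [
    "ANNOTATION_COLUMNS",
    "ExpressionMatrix",
    "GeneSet",
    "read_expression",
    "write_expression",
    "subset_mean_profile",
    "read_gmt",
    "write_gmt",
]


def _duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in items:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class ExpressionMatrix:
    """A log2-scale gene-by-sample expression matrix with sample annotations.

    Parameters
    ----------
    values
        DataFrame of shape (genes, samples); index = gene ids, columns =
        sample ids, entries finite log2 intensities.
    annotations
        DataFrame indexed by sample id with at least the columns
        ``subset``, ``tissue``, ``species`` and ``donor``, aligned with
        ``values.columns``.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        dup_genes = _duplicates(self.values.index)
        if dup_genes:
            raise ValueError(f"duplicate gene ids: {dup_genes}")
        dup_samples = _duplicates(self.values.columns)
        if dup_samples:
            raise ValueError(f"duplicate sample ids: {dup_samples}")
        missing_cols = [c for c in ANNOTATION_COLUMNS if c not in self.annotations.columns]
        if missing_cols:
            raise ValueError(f"annotation columns missing: {missing_cols}")
        unannotated = [s for s in self.values.columns if s not in self.annotations.index]
        if unannotated:
            raise ValueError(f"samples missing from annotations: {unannotated}")
        if self.annotations[list(ANNOTATION_COLUMNS)].loc[list(self.values.columns)].isna().any().any():
            raise ValueError("annotations contain missing values")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        # keep annotations in sample order, required columns complete
        self.annotations = self.annotations.loc[list(self.values.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def select_samples(self, mask: Sequence[bool] | pd.Series) -> "ExpressionMatrix":
        if isinstance(mask, pd.Series):
            mask = mask.loc[list(self.values.columns)].to_numpy()
        cols = self.values.columns[np.asarray(mask, dtype=bool)]
        return ExpressionMatrix(self.values[cols].copy(), self.annotations.loc[cols].copy())

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.annotations.copy())

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.values.equals(other.values) and self.annotations[
            list(ANNOTATION_COLUMNS)
        ].equals(other.annotations[list(ANNOTATION_COLUMNS)])


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (order-preserving, duplicate-free).

    May be empty: e.g. a tissue filter on a cohort without tissue effects
    legitimately returns no genes.
    """

    name: str
    genes: tuple[str, ...] = field(default_factory=tuple)
    description: str = ""

    def __post_init__(self) -> None:
        dups = _duplicates(self.genes)
        if dups:
            raise ValueError(f"gene set {self.name!r} contains duplicates: {dups}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)


def read_expression(path: str | Path, annotation_path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix plus its sample annotations.

    Fails hard on duplicate gene/sample ids (naming the offenders), on
    samples absent from the annotation table, and on non-finite values.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    anno = pd.read_csv(annotation_path, sep="\t", dtype=str)
    if "sample" not in anno.columns:
        raise ValueError(f"{annotation_path}: annotation file needs a 'sample' column")
    dup_anno = _duplicates(anno["sample"])
    if dup_anno:
        raise ValueError(f"{annotation_path}: duplicate sample annotations: {dup_anno}")
    anno = anno.set_index("sample")
    extra = [s for s in anno.index if s not in set(values.columns)]
    if extra:
        raise ValueError(f"{annotation_path}: annotated samples absent from matrix: {extra}")
    return ExpressionMatrix(values, anno)


def write_expression(
    m: ExpressionMatrix, path: str | Path, annotation_path: str | Path
) -> None:
    """Write matrix and annotations in the canonical tab-delimited layout.

    Floats are rendered with repr-level precision so that
    ``write(read(x))`` round-trips byte-identically for canonical files.
    """
    out = m.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")
    anno = m.annotations[list(ANNOTATION_COLUMNS)].copy()
    anno.index.name = "sample"
    anno.to_csv(annotation_path, sep="\t", lineterminator="\n")


def subset_mean_profile(
    m: ExpressionMatrix, group_by: Sequence[str] = ("subset",), sep: str = "|"
) -> ExpressionMatrix:
    """Average samples within groups defined by annotation keys.

    One output column per group, named by joining the group's annotation
    values with ``sep``; entries are arithmetic means of member samples.
    Annotation keys not used for grouping are kept when constant within the
    group and set to ``"mixed"`` otherwise.
    """
    keys = list(group_by)
    missing = [k for k in keys if k not in m.annotations.columns]
    if missing:
        raise ValueError(f"grouping keys not in annotations: {missing}")
    anno = m.annotations
    labels = anno[keys].astype(str).agg(sep.join, axis=1)
    order = list(dict.fromkeys(labels))  # first-appearance order
    cols = {}
    new_anno = {}
    for g in order:
        members = labels.index[labels == g]
        cols[g] = m.values[members].mean(axis=1)
        rec = {}
        for c in ANNOTATION_COLUMNS:
            vals = anno.loc[members, c].unique()
            rec[c] = vals[0] if len(vals) == 1 else "mixed"
        new_anno[g] = rec
    values = pd.DataFrame(cols, index=m.values.index)
    annotations = pd.DataFrame.from_dict(new_anno, orient="index")
    return ExpressionMatrix(values, annotations)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT v2 file: ``name<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a set are dropped with a warning; lines with
    fewer than three fields are an error reported with their line number.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                warnings.warn(
                    f"{path}: line {lineno}: duplicate genes in set {name!r} were dropped",
                    stacklevel=2,
                )
            sets.append(GeneSet(name=name, genes=tuple(deduped), description=desc))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    """Write gene sets as GMT v2. Empty sets are skipped with a warning
    (a GMT line requires at least one gene)."""
    with open(path, "w") as fh:
        for s in sets:
            if len(s) == 0:
                warnings.warn(f"gene set {s.name!r} is empty and was not written", stacklevel=2)
                continue
            desc = s.description or "na"
            fh.write("\t".join([s.name, desc, *s.genes]) + "\n")
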