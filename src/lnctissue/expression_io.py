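"""Expression-matrix and gene-catalog I/O.

Expression levels enter the pipeline as a gene x tissue FPKM table
(tab-separated, header row of tissue names, one gene per row).  FPKM is
always an *input* here, never computed.  Two preprocessing steps match the
standard treatment of multi-tissue RNA-seq compendia before entropy-based
specificity scoring:

* ``filter_expressed`` keeps genes with >= 1 FPKM in at least one tissue
  (applied on the raw scale);
* ``log_transform`` maps every value to log2(FPKM + 1).

Gene biotypes (lncRNA vs protein-coding) come from a two-column TSV or from
gene-level records of a GENCODE-style GTF.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, UsageError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "GeneCatalog",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gene_catalog",
    "filter_expressed",
    "log_transform",
]

BIOTYPES = ("lncRNA", "protein_coding", "other")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x tissue expression values.

    Parameters
    ----------
    data
        DataFrame with gene IDs as index, tissue names as columns.  Values
        are raw FPKM when ``transformed`` is False, log2(FPKM+1) otherwise.
    transformed
        Whether :func:`log_transform` has been applied.
    """

    data: pd.DataFrame
    transformed: bool = False

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[1] < 2:
            raise ValidationError(
                f"expression matrix needs at least 2 tissues, got {df.shape[1]}"
            )
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dups[:5]}")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate tissue names in header")
        vals = df.to_numpy(dtype=float)
        if vals.size and not np.isfinite(vals).all():
            raise ValidationError("expression values must be finite (no NA)")
        if vals.size and (vals < 0).any():
            raise ValidationError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def tissue_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_tissues(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class GeneCatalog:
    """Mapping of gene ID to biotype (lncRNA / protein_coding / other)."""

    biotypes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {b for b in self.biotypes.values() if b not in BIOTYPES}
        if bad:
            raise ValidationError(f"unknown biotype labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.biotypes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.biotypes

    def biotype(self, gene_id: str) -> str:
        """Biotype of ``gene_id``; genes absent from the catalog are 'other'."""
        return self.biotypes.get(gene_id, "other")

    def genes_of(self, biotype: str) -> list[str]:
        if biotype not in BIOTYPES:
            raise UsageError(f"biotype must be one of {BIOTYPES}, got {biotype!r}")
        return [g for g, b in self.biotypes.items() if b == biotype]


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a gene x tissue FPKM table.

    The first header column labels the gene-ID column; the remaining header
    columns are tissue names.  Every value cell must parse as a non-negative
    real; empty cells and ``NA`` are rejected rather than imputed, because
    silently imputed values would corrupt downstream entropy scores.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty file")
        cols = header.rstrip("\n").rstrip("\r").split("\t")
        if len(cols) < 3:
            raise ParseError(
                f"{path}, line 1: header needs a gene-ID column and >= 2 tissues"
            )
        tissues = cols[1:]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").rstrip("\r").split("\t")
            if len(parts) != len(cols):
                raise ParseError(
                    f"{path}, line {lineno}: expected {len(cols)} columns, "
                    f"found {len(parts)}"
                )
            vals = []
            for cell in parts[1:]:
                try:
                    v = float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}, line {lineno}: value {cell!r} is not a number "
                        "(missing values are not allowed)"
                    ) from None
                if math.isnan(v):
                    raise ParseError(
                        f"{path}, line {lineno}: NaN value (missing values are "
                        "not allowed)"
                    )
                if v < 0:
                    raise ValidationError(
                        f"{path}, line {lineno}: negative expression value {v}"
                    )
                vals.append(v)
            gene_ids.append(parts[0])
            rows.append(vals)
    df = pd.DataFrame(rows, index=gene_ids, columns=tissues, dtype=float)
    df.index.name = cols[0]
    return ExpressionMatrix(df, transformed=False)


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    """Write the symmetric TSV form read by :func:`read_expression_tsv`.

    Values are written with full (shortest round-trip) float precision, so
    write -> read is the identity on the data model.
    """
    df = m.data.copy()
    df.index.name = df.index.name or "gene_id"
    df.to_csv(path, sep="\t")


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _gtf_biotype(gene_type: str, lncrna_aliases: frozenset[str]) -> str:
    if gene_type == "lncRNA" or gene_type in lncrna_aliases:
        return "lncRNA"
    if gene_type == "protein_coding":
        return "protein_coding"
    return "other"


def read_gene_catalog(
    path: str | Path,
    format: str = "tsv",
    lncrna_aliases: Iterable[str] = (),
) -> GeneCatalog:
    """Read a gene catalog from a 2-column TSV or a GTF.

    TSV mode expects columns ``gene_id`` and ``biotype`` (an optional header
    row with exactly those labels is skipped); biotypes other than
    ``lncRNA``/``protein_coding`` map to ``other``.  GTF mode keys on
    gene-level records (feature column == ``gene``) and consumes only the
    ``gene_id`` and ``gene_type`` attributes, deduplicating by gene_id
    (first occurrence kept).

    ``lncrna_aliases`` optionally lists annotation sub-biotypes (e.g.
    ``lincRNA``, ``antisense``) to merge into the ``lncRNA`` label; by
    default only ``gene_type == "lncRNA"`` maps there, because sub-biotype
    granularity is annotation-release-dependent and the merge should be an
    explicit analyst choice.
    """
    path = Path(path)
    aliases = frozenset(lncrna_aliases)
    mapping: dict[str, str] = {}
    if format == "tsv":
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").rstrip("\r").split("\t")
                if len(parts) != 2:
                    raise ParseError(
                        f"{path}, line {lineno}: expected 2 columns, "
                        f"found {len(parts)}"
                    )
                gid, biotype = parts
                if lineno == 1 and (gid, biotype) == ("gene_id", "biotype"):
                    continue
                if gid not in mapping:
                    mapping[gid] = _gtf_biotype(biotype, aliases)
    elif format == "gtf":
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 9:
                    raise ParseError(
                        f"{path}, line {lineno}: expected 9 GTF columns, "
                        f"found {len(parts)}"
                    )
                if parts[2] != "gene":
                    continue
                attrs = dict(_GTF_ATTR.findall(parts[8]))
                if "gene_id" not in attrs or "gene_type" not in attrs:
                    raise ParseError(
                        f"{path}, line {lineno}: gene record lacks gene_id/"
                        "gene_type attributes"
                    )
                gid = attrs["gene_id"]
                if gid not in mapping:
                    mapping[gid] = _gtf_biotype(attrs["gene_type"], aliases)
    else:
        raise UsageError(f"format must be 'tsv' or 'gtf', got {format!r}")
    if not mapping:
        raise ValidationError(f"{path}: empty gene catalog")
    return GeneCatalog(mapping)


def write_gene_catalog_tsv(catalog: GeneCatalog, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene_id\tbiotype\n")
        for gid, biotype in catalog.biotypes.items():
            fh.write(f"{gid}\t{biotype}\n")


def filter_expressed(m: ExpressionMatrix, threshold: float = 1.0) -> ExpressionMatrix:
    """Keep genes with max FPKM across tissues >= ``threshold`` (inclusive).

    Defined on the raw FPKM scale only; the threshold of 1 FPKM is the
    conventional detection floor for bulk RNA-seq compendia.
    """
    if m.transformed:
        raise UsageError("filter_expressed is defined on raw FPKM, not log2 values")
    if m.n_genes == 0:
        return m
    keep = m.values.max(axis=1) >= threshold
    return replace(m, data=m.data.loc[keep])


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Map every value x to log2(x + 1); the +1 avoids log(0) for silent genes."""
    if m.transformed:
        raise UsageError("matrix is already log2(FPKM+1)-transformed")
    df = pd.DataFrame(
        np.log2(m.values + 1.0), index=m.data.index, columns=m.data.columns
    )
    df.index.name = m.data.index.name
    return ExpressionMatrix(df, transformed=True)
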