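"""Reading, validating and aligning per-phenotype GWAS p-value tables.

Each phenotype enters the analysis as a two-column table of SNP identifiers
and association p-values (tab-separated, header row, optionally gzipped).
Tables from several studies are combined by exact-identity intersection of
their SNP ids into an aligned M x K matrix, the substrate of every
downstream computation.  Only p-values are consumed: effect sizes, alleles
and standard errors play no role in the mixture model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

__all__ = [
    "PvalueTable",
    "PvalueMatrix",
    "read_pvalue_table",
    "write_pvalue_table",
    "intersect_tables",
]

DEFAULT_SNP_COL = "snp"
DEFAULT_PVAL_COL = "pvalue"


@dataclass(frozen=True)
class PvalueTable:
    """One phenotype's GWAS p-values, keyed by SNP identifier.

    Row order is preserved from the source; SNP ids must be unique and every
    p-value must be a finite number in [0, 1].
    """

    phenotype_label: str
    snp_ids: np.ndarray
    pvalues: np.ndarray

    def __post_init__(self) -> None:
        snp_ids = np.asarray(self.snp_ids, dtype=object)
        pvalues = np.asarray(self.pvalues, dtype=float)
        object.__setattr__(self, "snp_ids", snp_ids)
        object.__setattr__(self, "pvalues", pvalues)
        if snp_ids.ndim != 1 or pvalues.ndim != 1:
            raise ValidationError("snp_ids and pvalues must be 1-dimensional")
        if len(snp_ids) != len(pvalues):
            raise ValidationError(
                f"length mismatch: {len(snp_ids)} SNP ids vs {len(pvalues)} p-values"
            )
        _check_pvalues(pvalues, label=self.phenotype_label)
        if len(np.unique(snp_ids)) != len(snp_ids):
            dup = pd.Index(snp_ids)
            dup = dup[dup.duplicated()][0]
            raise ValidationError(
                f"duplicate SNP id {dup!r} in table {self.phenotype_label!r}"
            )

    def __len__(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {DEFAULT_SNP_COL: self.snp_ids, DEFAULT_PVAL_COL: self.pvalues}
        )


@dataclass(frozen=True)
class PvalueMatrix:
    """M SNPs x K phenotypes of p-values over a common SNP set."""

    snp_ids: np.ndarray
    phenotype_labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        snp_ids = np.asarray(self.snp_ids, dtype=object)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "snp_ids", snp_ids)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "phenotype_labels", tuple(self.phenotype_labels))
        if values.ndim != 2:
            raise ValidationError("values must be a 2-d array")
        m, k = values.shape
        if m < 1 or k < 2:
            raise ValidationError(f"need M >= 1 SNPs and K >= 2 phenotypes, got {m} x {k}")
        if len(snp_ids) != m or len(self.phenotype_labels) != k:
            raise ValidationError("label/axis length mismatch")
        if len(np.unique(snp_ids)) != m:
            raise ValidationError("duplicate SNP ids in matrix")
        for j, lab in enumerate(self.phenotype_labels):
            _check_pvalues(values[:, j], label=lab)

    @property
    def n_snps(self) -> int:
        return self.values.shape[0]

    @property
    def n_phenotypes(self) -> int:
        return self.values.shape[1]

    def column(self, which: int | str) -> np.ndarray:
        return self.values[:, self._index(which)]

    def pair(self, first: int | str, second: int | str) -> "PvalueMatrix":
        """Two-phenotype sub-matrix, in the requested column order."""
        i, j = self._index(first), self._index(second)
        return PvalueMatrix(
            snp_ids=self.snp_ids,
            phenotype_labels=(self.phenotype_labels[i], self.phenotype_labels[j]),
            values=self.values[:, [i, j]],
        )

    def _index(self, which: int | str) -> int:
        if isinstance(which, str):
            try:
                return self.phenotype_labels.index(which)
            except ValueError:
                raise KeyError(f"unknown phenotype label {which!r}") from None
        return int(which)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.snp_ids, name=DEFAULT_SNP_COL),
            columns=list(self.phenotype_labels),
        )


def _check_pvalues(pvalues: np.ndarray, label: str | None = None) -> None:
    where = f" in table {label!r}" if label else ""
    bad = ~np.isfinite(pvalues)
    if bad.any():
        row = int(np.nonzero(bad)[0][0])
        raise ValidationError(f"non-numeric or non-finite p-value at row {row}{where}")
    bad = (pvalues < 0.0) | (pvalues > 1.0)
    if bad.any():
        row = int(np.nonzero(bad)[0][0])
        raise ValidationError(
            f"p-value {pvalues[row]!r} outside [0, 1] at row {row}{where}"
        )


def read_pvalue_table(
    path: str | Path,
    phenotype_label: str | None = None,
    snp_col: str = DEFAULT_SNP_COL,
    pval_col: str = DEFAULT_PVAL_COL,
) -> PvalueTable:
    """Read one phenotype's p-value table from a TSV (optionally .gz) file.

    Parameters
    ----------
    path
        Tab-separated file with a header row naming at least `snp_col` and
        `pval_col`.  Gzip compression is inferred from the ``.gz`` suffix.
    phenotype_label
        Label for the phenotype; defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if phenotype_label is None:
        phenotype_label = path.name.removesuffix(".gz").rsplit(".", 1)[0]
    frame = pd.read_csv(path, sep="\t", dtype={snp_col: str}, compression="infer")
    for col in (snp_col, pval_col):
        if col not in frame.columns:
            raise FormatError(
                f"{path}: missing required column {col!r} "
                f"(found: {list(frame.columns)})"
            )
    pvals = pd.to_numeric(frame[pval_col], errors="coerce").to_numpy(dtype=float)
    return PvalueTable(
        phenotype_label=phenotype_label,
        snp_ids=frame[snp_col].to_numpy(dtype=object),
        pvalues=pvals,
    )


def write_pvalue_table(table: PvalueTable, path: str | Path,
                       snp_col: str = DEFAULT_SNP_COL,
                       pval_col: str = DEFAULT_PVAL_COL) -> None:
    """Write a table back in the same TSV dialect (round-trip/debug aid)."""
    frame = table.to_frame().rename(
        columns={DEFAULT_SNP_COL: snp_col, DEFAULT_PVAL_COL: pval_col}
    )
    frame.to_csv(path, sep="\t", index=False)


def intersect_tables(tables: Sequence[PvalueTable]) -> PvalueMatrix:
    """Align >= 2 tables on the intersection of their SNP ids.

    SNPs are ordered by sorted identifier so the result does not depend on
    the row order of the inputs; columns follow the input table order.
    """
    if len(tables) < 2:
        raise ValidationError(f"need at least 2 tables, got {len(tables)}")
    common: set[str] | None = None
    for t in tables:
        ids = set(t.snp_ids.tolist())
        common = ids if common is None else (common & ids)
    assert common is not None
    if not common:
        raise ValidationError("SNP id intersection across tables is empty")
    snp_ids = np.array(sorted(common), dtype=object)
    cols = []
    for t in tables:
        lookup = pd.Index(t.snp_ids)
        cols.append(t.pvalues[lookup.get_indexer(snp_ids)])
    return PvalueMatrix(
        snp_ids=snp_ids,
        phenotype_labels=tuple(t.phenotype_label for t in tables),
        values=np.column_stack(cols),
    )
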