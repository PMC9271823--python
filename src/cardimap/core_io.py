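"""Data model and on-disk formats for the pipeline.

Count matrices travel as Matrix Market files with ``genes.tsv`` /
``barcodes.tsv`` sidecars (genes as rows, the 10x-style convention), cell
metadata as a ``cells.tsv`` table, developmental-stage order as an explicit
``stage_order.txt`` (one label per line -- never inferred by string sorting,
which would put "e10.5" before "e8.5"), ortholog pairs as a two-column TSV,
and gene sets in the Broad GMT dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "NormMatrix",
    "CellMeta",
    "OrthologMap",
    "GeneSetCollection",
    "read_counts",
    "write_counts",
    "read_ortholog_table",
    "read_gmt",
    "read_stage_order",
]


class FormatError(ValueError):
    """A structured on-disk format violation, naming the offending file."""


def _check_unique(ids: np.ndarray, what: str, where: str = "") -> None:
    if len(ids) != len(set(ids)):
        dup = pd.Index(ids)[pd.Index(ids).duplicated()].unique()[:5]
        suffix = f" in {where}" if where else ""
        raise FormatError(f"duplicate {what} identifiers{suffix}: {list(dup)}")


@dataclass
class ExpressionMatrix:
    """Sparse nonnegative gene x cell count matrix with identifiers.

    Parameters
    ----------
    values
        ``scipy.sparse`` matrix, genes as rows, cells as columns.
    gene_ids, cell_ids
        Unique string identifiers matching the matrix dimensions.
    species
        Tag in ``{"human", "mouse", "other"}``.
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    species: str = "other"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("negative values in count matrix")
        if self.species not in ("human", "mouse", "other"):
            raise FormatError(f"unknown species tag {self.species!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, genes) -> np.ndarray:
        """Row positions of ``genes``; raises on absent identifiers."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in matrix") from None

    def subset_cells(self, mask_or_index) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionMatrix(
            self.values[:, idx], self.gene_ids, self.cell_ids[idx], self.species
        )

    def subset_genes(self, mask_or_index) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionMatrix(
            self.values[idx, :], self.gene_ids[idx], self.cell_ids, self.species
        )


@dataclass
class NormMatrix:
    """Log-normalized expression: ``log(1 + count / cell_total * scale_factor)``.

    Shares the gene x cell orientation and identifier contract of
    :class:`ExpressionMatrix`; ``scale_factor`` records provenance.
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    species: str = "other"
    scale_factor: float = 10_000.0

    __post_init__ = ExpressionMatrix.__post_init__
    n_genes = ExpressionMatrix.n_genes
    n_cells = ExpressionMatrix.n_cells
    gene_index = ExpressionMatrix.gene_index

    def subset_cells(self, mask_or_index) -> "NormMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormMatrix(
            self.values[:, idx], self.gene_ids, self.cell_ids[idx],
            self.species, self.scale_factor,
        )

    def subset_genes(self, mask_or_index) -> "NormMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormMatrix(
            self.values[idx, :], self.gene_ids[idx], self.cell_ids,
            self.species, self.scale_factor,
        )


@dataclass
class CellMeta:
    """Per-cell metadata table with an explicitly ordered stage column.

    ``table`` is indexed by cell_id and must carry at least ``stage`` and
    ``batch`` columns; ``stage_order`` is the total order over observed stage
    labels (e.g. 5W < 6W < ... < 25W, or e8.5 < e9.5 < ...).
    """

    table: pd.DataFrame
    stage_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise FormatError("duplicate cell ids in cell metadata")
        for col in ("stage", "batch"):
            if col not in self.table.columns:
                raise FormatError(f"cell metadata missing required column {col!r}")
        observed = set(self.table["stage"].astype(str))
        missing = observed - set(self.stage_order)
        if missing:
            raise FormatError(
                f"stage order does not cover observed stages: {sorted(missing)}"
            )
        self.table = self.table.copy()
        self.table["stage"] = pd.Categorical(
            self.table["stage"].astype(str), categories=self.stage_order, ordered=True
        )

    def aligned_to(self, cell_ids) -> "CellMeta":
        """Rows reordered/subset to ``cell_ids`` (every id must be present)."""
        missing = [c for c in cell_ids if c not in self.table.index]
        if missing:
            raise FormatError(f"cells absent from metadata: {missing[:5]}")
        return CellMeta(self.table.loc[list(cell_ids)], self.stage_order)

    def stages(self, cell_ids=None) -> pd.Series:
        t = self.table if cell_ids is None else self.table.loc[list(cell_ids)]
        return t["stage"]

    def stage_rank(self, cell_ids=None) -> np.ndarray:
        return self.stages(cell_ids).cat.codes.to_numpy()


@dataclass
class OrthologMap:
    """One-to-one gene pairing between two species (injective both ways)."""

    pairs: pd.DataFrame  # columns: gene_a, gene_b

    def __post_init__(self) -> None:
        self.pairs = pd.DataFrame(self.pairs, columns=["gene_a", "gene_b"]).astype(str)
        if self.pairs["gene_a"].duplicated().any() or self.pairs["gene_b"].duplicated().any():
            raise FormatError("ortholog map is not one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def a_to_b(self) -> dict[str, str]:
        return dict(zip(self.pairs["gene_a"], self.pairs["gene_b"]))

    def b_to_a(self) -> dict[str, str]:
        return dict(zip(self.pairs["gene_b"], self.pairs["gene_a"]))


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets (the GMT payload)."""

    sets: dict[str, set]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_stage_order(path) -> list[str]:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    order = [ln for ln in lines if ln]
    if len(order) != len(set(order)):
        raise FormatError(f"{path}: duplicate stage labels")
    return order


def read_counts(directory) -> tuple[ExpressionMatrix, CellMeta]:
    """Read a counts bundle: matrix.mtx + genes.tsv + barcodes.tsv + cells.tsv.

    Stage order is taken from ``stage_order.txt`` in the same directory.
    Dimension mismatches and duplicated identifiers raise :class:`FormatError`
    naming the offending file.
    """
    d = Path(directory)
    for fname in ("matrix.mtx", "genes.tsv", "barcodes.tsv", "cells.tsv"):
        if not (d / fname).exists():
            raise FormatError(f"missing {d / fname}")
    mat = sp.csr_matrix(scipy.io.mmread(d / "matrix.mtx"))
    genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None, dtype=str)
    if mat.shape[0] != len(genes):
        raise FormatError(
            f"{d/'matrix.mtx'} declares {mat.shape[0]} genes but "
            f"{d/'genes.tsv'} lists {len(genes)}"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{d/'matrix.mtx'} declares {mat.shape[1]} cells but "
            f"{d/'barcodes.tsv'} lists {len(barcodes)}"
        )
    gene_ids = genes.iloc[:, 0].to_numpy(dtype=object)
    cell_ids = barcodes.iloc[:, 0].to_numpy(dtype=object)
    _check_unique(gene_ids, "gene", str(d / "genes.tsv"))
    _check_unique(cell_ids, "cell", str(d / "barcodes.tsv"))

    cells = pd.read_csv(d / "cells.tsv", sep="\t", dtype=str).set_index("cell_id")
    species = "other"
    if "species" in cells.columns and cells["species"].nunique() == 1:
        species = cells["species"].iloc[0]
    order_file = d / "stage_order.txt"
    if order_file.exists():
        stage_order = read_stage_order(order_file)
    else:
        stage_order = list(pd.unique(cells["stage"]))
        logger.warning("%s: no stage_order.txt; using order of appearance", d)
    matrix = ExpressionMatrix(mat, gene_ids, cell_ids, species)
    meta = CellMeta(cells, stage_order).aligned_to(cell_ids)
    return matrix, meta


def write_counts(matrix: ExpressionMatrix, meta: CellMeta, directory,
                 gene_symbols=None) -> list[str]:
    """Write a counts bundle readable by :func:`read_counts`; returns filenames."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(d / "matrix.mtx", sp.coo_matrix(matrix.values), field="integer"
                     if np.issubdtype(matrix.values.dtype, np.integer) else "real")
    symbols = matrix.gene_ids if gene_symbols is None else gene_symbols
    pd.DataFrame({"gene_id": matrix.gene_ids, "gene_symbol": symbols}).to_csv(
        d / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.DataFrame({"barcode": matrix.cell_ids}).to_csv(
        d / "barcodes.tsv", sep="\t", header=False, index=False
    )
    table = meta.aligned_to(matrix.cell_ids).table.copy()
    if "species" not in table.columns:
        table["species"] = matrix.species
    table.insert(0, "cell_id", table.index)
    table.to_csv(d / "cells.tsv", sep="\t", index=False)
    (d / "stage_order.txt").write_text("\n".join(meta.stage_order) + "\n")
    return ["matrix.mtx", "genes.tsv", "barcodes.tsv", "cells.tsv", "stage_order.txt"]


def read_ortholog_table(path) -> OrthologMap:
    """Read a two-column TSV of gene pairs, enforcing one-to-one.

    Any gene appearing in more than one row (in either column) violates the
    one-to-one contract; *all* of its rows are dropped and the count logged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns")
    df = df.iloc[:, :2]
    df.columns = ["gene_a", "gene_b"]
    if df.empty:
        raise FormatError(f"{path}: empty ortholog table")
    bad = df["gene_a"].duplicated(keep=False) | df["gene_b"].duplicated(keep=False)
    if bad.any():
        logger.warning("%s: dropped %d rows violating one-to-one", path, int(bad.sum()))
    return OrthologMap(df.loc[~bad].reset_index(drop=True))


def read_gmt(path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name <TAB> description <TAB> genes..."""
    sets: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 fields")
            name, desc, *genes = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g for g in genes if g]
            sets[name] = set(genes)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)
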