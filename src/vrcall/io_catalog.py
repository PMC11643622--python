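"""Readers and writers for count matrices, gene catalogs, labels, and result tables.

Count matrices are accepted either as a CellRanger-style MatrixMarket
triplet (``matrix.mtx[.gz]`` + ``features.tsv[.gz]``/``genes.tsv[.gz]`` +
``barcodes.tsv[.gz]``, genes-by-cells on disk) or as a dense TSV with one
row per cell and one column per gene. In memory, cells are always rows.

Gene catalogs map every gene to a receptor family / functional class used
downstream: V1R, the V2R subfamilies (ABDE, C1, C2), H2-Mv, cell-type
markers, mitochondrial and hemoglobin QC genes, an endoplasmic-reticulum
gene set, or ``other``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from vrcall.errors import FormatError, ValidationError

VALID_CLASSES = frozenset(
    {
        "V1R",
        "V2R_ABDE",
        "V2R_C1",
        "V2R_C2",
        "H2Mv",
        "marker",
        "mito",
        "hemoglobin",
        "ER",
        "other",
    }
)

#: Family keys used for threshold derivation and receptor calling.
#: All V2R subfamilies share one pooled threshold, as do the H2-Mv genes.
CLASS_TO_FAMILY = {
    "V1R": "V1R",
    "V2R_ABDE": "V2R",
    "V2R_C1": "V2R",
    "V2R_C2": "V2R",
    "H2Mv": "H2Mv",
}


def _check_unique(values: Sequence[str], what: str) -> None:
    if len(set(values)) != len(values):
        seen: set[str] = set()
        dup = next(v for v in values if v in seen or seen.add(v))
        raise ValidationError(f"duplicate {what}: {dup!r}")


@dataclass
class CountMatrix:
    """Raw integer counts, cells x genes, with identifier lists.

    Counts are stored as a CSR sparse matrix; they must be non-negative
    and integral, and the matrix shape must match the identifier lists.
    """

    barcodes: list[str]
    genes: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.barcodes = list(self.barcodes)
        self.genes = list(self.genes)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        _check_unique(self.barcodes, "barcode")
        _check_unique(self.genes, "gene ID")
        if self.counts.shape != (len(self.barcodes), len(self.genes)):
            raise FormatError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.genes)} genes"
            )
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise ValidationError("negative counts are not allowed")
            if np.issubdtype(data.dtype, np.floating) and not np.allclose(
                data, np.round(data)
            ):
                raise ValidationError("counts must be integral")
        self.counts.data = np.asarray(np.round(data), dtype=np.int64)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def subset_cells(self, keep: Sequence[int] | np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        return CountMatrix(
            [self.barcodes[i] for i in keep], list(self.genes), self.counts[keep]
        )

    def to_dense_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.toarray(), index=self.barcodes, columns=self.genes
        )


@dataclass
class NormMatrix:
    """Log-normalized expression, cells x genes, dense float values."""

    barcodes: list[str]
    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.barcodes = list(self.barcodes)
        self.genes = list(self.genes)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.barcodes), len(self.genes)):
            raise FormatError("values shape does not match identifier lists")
        if self.values.size and self.values.min() < 0:
            raise ValidationError("normalized values must be non-negative")
        self._gene_pos = {g: i for i, g in enumerate(self.genes)}
        self._cell_pos = {b: i for i, b in enumerate(self.barcodes)}

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def gene_values(self, gene: str) -> np.ndarray:
        if gene not in self._gene_pos:
            raise KeyError(f"gene {gene!r} not in matrix")
        return self.values[:, self._gene_pos[gene]]

    def cell_indices(self, barcodes: Iterable[str]) -> np.ndarray:
        return np.array([self._cell_pos[b] for b in barcodes], dtype=int)

    def gene_indices(self, genes: Iterable[str]) -> np.ndarray:
        return np.array([self._gene_pos[g] for g in genes], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.barcodes, columns=self.genes)


@dataclass
class GeneCatalog:
    """Gene -> family/class assignment table.

    Wraps a DataFrame indexed by gene_id with columns ``class``,
    ``subfamily`` and ``display_name``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        required = {"class", "subfamily"}
        if not required.issubset(df.columns):
            raise FormatError(f"catalog needs columns {sorted(required)}")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate gene_id in catalog: {dup!r}")
        unknown = set(df["class"]) - VALID_CLASSES
        if unknown:
            raise ValidationError(f"unknown gene class(es): {sorted(unknown)}")
        if "display_name" not in df.columns:
            df = df.assign(display_name=df.index)
        c1 = set(df.index[df["class"] == "V2R_C1"])
        c2 = set(df.index[df["class"] == "V2R_C2"])
        if c1 & c2:
            raise ValidationError("C1 and C2 gene sets must be disjoint")
        self.table = df

    def genes_of_class(self, cls: str | Iterable[str]) -> list[str]:
        classes = {cls} if isinstance(cls, str) else set(cls)
        unknown = classes - VALID_CLASSES
        if unknown:
            raise ValidationError(f"unknown gene class(es): {sorted(unknown)}")
        return list(self.table.index[self.table["class"].isin(classes)])

    def genes_of_family(self, family: str) -> list[str]:
        """Genes pooled under one thresholding family: V1R, V2R, or H2Mv."""
        classes = [c for c, f in CLASS_TO_FAMILY.items() if f == family]
        if not classes:
            raise ValidationError(f"unknown receptor family {family!r}")
        return self.genes_of_class(classes)

    def class_of(self, gene: str) -> str:
        return str(self.table.loc[gene, "class"])

    def __contains__(self, gene: str) -> bool:
        return gene in self.table.index

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# count matrix I/O
# ---------------------------------------------------------------------------


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _find_triplet_member(folder: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = folder / f"{stem}{suffix}"
            if p.exists():
                return p
    raise FormatError(f"none of {stems} found in {folder}")


def _read_id_column(path: Path) -> list[str]:
    with _open_maybe_gz(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return ids


def load_counts(path: str | Path, format: str = "mtx_triplet") -> CountMatrix:
    """Load a raw count matrix.

    ``mtx_triplet``: *path* is a directory containing ``matrix.mtx[.gz]``,
    ``features.tsv[.gz]`` (or ``genes.tsv[.gz]``; 1-3 columns, first is the
    gene ID) and ``barcodes.tsv[.gz]``. The on-disk matrix is
    genes-by-cells and is transposed on load; gene order follows the
    features file.

    ``dense_tsv``: *path* is a TSV with barcodes in the first column and
    one gene per remaining column.
    """
    path = Path(path)
    if format == "mtx_triplet":
        mtx = _find_triplet_member(path, ["matrix.mtx"])
        feats = _find_triplet_member(path, ["features.tsv", "genes.tsv"])
        bcs = _find_triplet_member(path, ["barcodes.tsv"])
        with _open_maybe_gz(mtx) as fh:
            mat = scipy.io.mmread(fh)
        genes = _read_id_column(feats)
        barcodes = _read_id_column(bcs)
        if mat.shape != (len(genes), len(barcodes)):
            raise FormatError(
                f"matrix is {mat.shape} but features/barcodes give "
                f"({len(genes)}, {len(barcodes)})"
            )
        data = mat.tocoo().data
        if data.size and (np.any(data < 0) or not np.allclose(data, np.round(data))):
            raise ValidationError("matrix entries must be non-negative integers")
        return CountMatrix(barcodes, genes, sp.csr_matrix(mat.T))
    if format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        arr = df.to_numpy()
        if arr.size and (np.any(arr < 0) or not np.allclose(arr, np.round(arr))):
            raise ValidationError("matrix entries must be non-negative integers")
        return CountMatrix(
            [str(b) for b in df.index], [str(g) for g in df.columns], sp.csr_matrix(arr)
        )
    raise FormatError(f"unknown count format {format!r}")


def write_counts(matrix: CountMatrix, path: str | Path, format: str = "mtx_triplet") -> None:
    """Write a count matrix as an MTX triplet directory or a dense TSV."""
    path = Path(path)
    if format == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path / "matrix.mtx"), matrix.counts.T.tocoo(), field="integer")
        (path / "features.tsv").write_text(
            "".join(f"{g}\t{g}\tGene Expression\n" for g in matrix.genes)
        )
        (path / "barcodes.tsv").write_text("".join(f"{b}\n" for b in matrix.barcodes))
        return
    if format == "dense_tsv":
        matrix.to_dense_frame().rename_axis("barcode").to_csv(path, sep="\t")
        return
    raise FormatError(f"unknown count format {format!r}")


# ---------------------------------------------------------------------------
# catalog / labels / generic tables
# ---------------------------------------------------------------------------


def load_gene_catalog(path: str | Path) -> GeneCatalog:
    """Load a gene catalog TSV with columns gene_id, class, subfamily[, display_name]."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "gene_id" not in df.columns:
        raise FormatError("catalog TSV must have a gene_id column")
    return GeneCatalog(df.set_index("gene_id"))


def write_gene_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    catalog.table.rename_axis("gene_id").to_csv(path, sep="\t")


def load_labels(path: str | Path) -> pd.Series:
    """Load a barcode -> cell-type label table (TSV: barcode, label)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("label TSV must have barcode and label columns")
    barcode_col, label_col = df.columns[:2]
    if df[barcode_col].duplicated().any():
        dup = df[barcode_col][df[barcode_col].duplicated()].iloc[0]
        raise ValidationError(f"barcode {dup!r} labeled more than once")
    return pd.Series(
        df[label_col].to_numpy(), index=df[barcode_col].to_numpy(), name="label"
    ).rename_axis("barcode")


def write_table(table: pd.DataFrame | pd.Series, path: str | Path) -> None:
    """Write a result table as UTF-8 TSV with a header row."""
    if isinstance(table, pd.Series):
        table = table.to_frame()
    table.to_csv(path, sep="\t", index=not isinstance(table.index, pd.RangeIndex))


def read_table(path: str | Path, index_col: int | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
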