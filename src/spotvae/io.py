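"""Reading, writing and aligning count matrices, coordinates, labels and proportions.

On-disk conventions
-------------------
* **MTX triplet**: a Matrix Market coordinate file (``matrix.mtx``) oriented
  spots/cells x genes, with sibling TSVs ``barcodes.tsv`` (one row id per
  line) and ``features.tsv`` (one gene id per line) in the same directory.
* **Dense TSV**: header row = gene ids, first column = spot/cell ids.
* **Proportions TSV**: header row = cell-type names, first column = spot ids,
  values written with 10 significant digits.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .errors import DomainError, FormatError, IncompatibleError

__all__ = [
    "CountMatrix",
    "SpotCoordinates",
    "LabelVector",
    "ProportionMatrix",
    "read_counts",
    "write_counts",
    "read_proportions",
    "write_proportions",
    "read_labels",
    "write_labels",
    "read_coordinates",
    "write_coordinates",
    "align_genes",
]


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        for i, x in enumerate(ids):
            if x in seen:
                raise FormatError(f"duplicate {what} id {x!r} at position {i}")
            seen.add(x)


@dataclass
class CountMatrix:
    """A spots-x-genes (or cells-x-genes) nonnegative integer count matrix.

    ``values`` is stored as int64 so totals beyond 2^31 cannot overflow.
    """

    values: np.ndarray
    row_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise FormatError(f"count matrix must be 2-D, got shape {v.shape}")
        if not np.issubdtype(v.dtype, np.integer):
            if not np.all(np.isfinite(v)) or np.any(v != np.floor(v)):
                bad = np.argwhere(v != np.floor(v))
                loc = tuple(bad[0]) if bad.size else "?"
                raise FormatError(f"non-integer count entry at {loc}")
            v = v.astype(np.int64)
        else:
            v = v.astype(np.int64, copy=False)
        if np.any(v < 0):
            loc = tuple(np.argwhere(v < 0)[0])
            raise FormatError(f"negative count entry at {loc}")
        self.values = v
        self.row_ids = [str(r) for r in self.row_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if v.shape != (len(self.row_ids), len(self.gene_ids)):
            raise FormatError(
                f"shape {v.shape} inconsistent with {len(self.row_ids)} row ids "
                f"and {len(self.gene_ids)} gene ids"
            )
        _check_unique(self.row_ids, "row")
        _check_unique(self.gene_ids, "gene")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def total_counts(self) -> np.ndarray:
        """Per-row total UMI counts."""
        return self.values.sum(axis=1)

    def subset_genes(self, gene_ids: list[str]) -> "CountMatrix":
        idx = {g: j for j, g in enumerate(self.gene_ids)}
        cols = [idx[g] for g in gene_ids]
        return CountMatrix(self.values[:, cols], list(self.row_ids), list(gene_ids))


@dataclass
class SpotCoordinates:
    """Planar coordinates for spots; row order aligns with a CountMatrix."""

    row_ids: list[str]
    xy: np.ndarray

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise FormatError(f"coordinates must be N x 2, got {self.xy.shape}")
        if len(self.row_ids) != self.xy.shape[0]:
            raise FormatError("row ids and coordinate rows differ in length")
        _check_unique(self.row_ids, "row")


@dataclass
class LabelVector:
    """Cell-type labels for reference cells plus the canonical type order."""

    row_ids: list[str]
    labels: list[str]
    type_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.row_ids) != len(self.labels):
            raise FormatError("row ids and labels differ in length")
        _check_unique(self.row_ids, "row")
        if not self.type_order:
            self.type_order = sorted(set(self.labels))
        _check_unique(self.type_order, "type")
        missing = set(self.labels) - set(self.type_order)
        if missing:
            raise FormatError(f"labels not in type_order: {sorted(missing)}")
        if len(self.type_order) < 2:
            raise FormatError("at least 2 cell types are required")

    @property
    def n_types(self) -> int:
        return len(self.type_order)

    def indices(self) -> np.ndarray:
        """Integer type index per cell, following type_order."""
        lut = {t: i for i, t in enumerate(self.type_order)}
        return np.array([lut[l] for l in self.labels], dtype=np.int64)


@dataclass
class ProportionMatrix:
    """Per-spot cell-type proportions; every row lies on the simplex."""

    values: np.ndarray
    row_ids: list[str]
    type_order: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise FormatError("proportion matrix must be 2-D")
        if v.shape != (len(self.row_ids), len(self.type_order)):
            raise FormatError("proportion shape inconsistent with ids")
        if v.size:
            if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
                raise DomainError("proportion entries must lie in [0, 1]")
            sums = v.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                i = int(np.argmax(np.abs(sums - 1.0)))
                raise DomainError(
                    f"proportion row {self.row_ids[i]!r} sums to {sums[i]:.8f}, not 1"
                )
        self.values = v
        _check_unique(self.row_ids, "row")
        _check_unique(self.type_order, "type")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def support_sizes(self) -> np.ndarray:
        return (self.values > 0).sum(axis=1)


# ---------------------------------------------------------------------------
# readers / writers


def _read_id_file(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FormatError(f"missing sibling {what} file: {path}")
    ids = [line.split("\t")[0].strip() for line in path.read_text().splitlines() if line.strip()]
    return ids


def read_counts(path: str | os.PathLike, format: str = "dense_tsv") -> CountMatrix:
    """Read a count matrix from ``dense_tsv`` or ``mtx_triplet`` format.

    For ``mtx_triplet``, *path* may be the ``.mtx`` file or the directory
    containing ``matrix.mtx``; ``barcodes.tsv`` and ``features.tsv`` must sit
    beside the matrix file.
    """
    p = Path(path)
    if format == "dense_tsv":
        if not p.exists():
            raise FormatError(f"no such file: {p}")
        try:
            df = pd.read_csv(p, sep="\t", index_col=0)
        except Exception as e:  # malformed header / ragged rows
            raise FormatError(f"malformed dense TSV {p}: {e}") from e
        return CountMatrix(df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns])
    if format == "mtx_triplet":
        mtx = p / "matrix.mtx" if p.is_dir() else p
        if not mtx.exists():
            raise FormatError(f"no such file: {mtx}")
        try:
            m = spio.mmread(str(mtx))
        except Exception as e:
            raise FormatError(f"malformed MTX file {mtx}: {e}") from e
        m = sparse.coo_matrix(m).toarray()
        rows = _read_id_file(mtx.parent / "barcodes.tsv", "barcode")
        genes = _read_id_file(mtx.parent / "features.tsv", "feature")
        if m.shape != (len(rows), len(genes)):
            raise FormatError(
                f"MTX shape {m.shape} does not match {len(rows)} barcodes x {len(genes)} features"
            )
        return CountMatrix(m, rows, genes)
    raise ValueError(f"unknown format {format!r}; use 'dense_tsv' or 'mtx_triplet'")


def write_counts(cm: CountMatrix, path: str | os.PathLike, format: str = "dense_tsv") -> None:
    """Write a count matrix in the same formats ``read_counts`` accepts."""
    p = Path(path)
    if format == "dense_tsv":
        df = pd.DataFrame(cm.values, index=cm.row_ids, columns=cm.gene_ids)
        df.to_csv(p, sep="\t")
        return
    if format == "mtx_triplet":
        p.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(str(p / "matrix.mtx"), sparse.coo_matrix(cm.values))
        (p / "barcodes.tsv").write_text("".join(r + "\n" for r in cm.row_ids))
        (p / "features.tsv").write_text("".join(g + "\n" for g in cm.gene_ids))
        return
    raise ValueError(f"unknown format {format!r}")


def write_proportions(props: ProportionMatrix, path: str | os.PathLike) -> None:
    """Write proportions as TSV with >= 6 significant digits."""
    df = pd.DataFrame(props.values, index=props.row_ids, columns=props.type_order)
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_proportions(path: str | os.PathLike) -> ProportionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(dtype=float)
    if vals.size:  # renormalize away formatting round-off
        sums = vals.sum(axis=1, keepdims=True)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise FormatError(f"proportion rows in {path} do not sum to 1")
        vals = vals / sums
    return ProportionMatrix(vals, [str(i) for i in df.index], [str(c) for c in df.columns])


def write_labels(labels: LabelVector, path: str | os.PathLike) -> None:
    pd.DataFrame({"cell_id": labels.row_ids, "cell_type": labels.labels}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path: str | os.PathLike) -> LabelVector:
    df = pd.read_csv(path, sep="\t")
    if not {"cell_id", "cell_type"} <= set(df.columns):
        raise FormatError(f"label TSV {path} needs columns cell_id, cell_type")
    return LabelVector([str(x) for x in df["cell_id"]], [str(x) for x in df["cell_type"]])


def write_coordinates(coords: SpotCoordinates, path: str | os.PathLike) -> None:
    pd.DataFrame(coords.xy, index=coords.row_ids, columns=["x", "y"]).to_csv(path, sep="\t")


def read_coordinates(path: str | os.PathLike) -> SpotCoordinates:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not {"x", "y"} <= set(df.columns):
        raise FormatError(f"coordinate TSV {path} needs columns x, y")
    return SpotCoordinates([str(i) for i in df.index], df[["x", "y"]].to_numpy(dtype=float))


def align_genes(a: CountMatrix, b: CountMatrix) -> tuple[CountMatrix, CountMatrix]:
    """Restrict two count matrices to their shared genes, lexicographically ordered.

    The shared lexicographic order makes downstream training reproducible
    regardless of the input gene order. Idempotent.
    """
    shared = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not shared:
        raise IncompatibleError("no shared genes between the two count matrices")
    return a.subset_genes(shared), b.subset_genes(shared)
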