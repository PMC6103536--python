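"""Peak-by-cell matrix and interval I/O.

The on-disk bundle is the standard single-cell ATAC triplet layout: a
matrix-market ``.mtx`` file, a BED file of peak intervals (0-based,
half-open), and a plain-text barcode list, any of which may be gzipped.
In memory, cells are always rows and peaks are columns; the on-disk
orientation is auto-detected from the sidecar file lengths.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import io as spio
from scipy import sparse

from .exceptions import (
    DimensionMismatchError,
    DuplicatePeakError,
    EmptyFeatureSetError,
)

__all__ = [
    "PeakTable",
    "CountMatrix",
    "BinaryAccessibilityMatrix",
    "FeaturePeakSet",
    "read_peak_matrix",
    "read_bed_intervals",
    "write_bundle",
    "binarize",
    "map_feature_to_peaks",
    "mean_accessibility",
]


def _open_text(path):
    """Open a possibly-gzipped text file for reading."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass(frozen=True)
class PeakTable:
    """Genomic intervals (BED convention) with optional per-peak annotation.

    ``gc`` is the GC fraction of determined bases in the peak sequence and
    ``mean_accessibility`` the fraction of cells in which the peak is
    accessible; both are NaN when not yet annotated (or unannotatable, e.g.
    an all-N sequence).
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    peak_id: np.ndarray
    gc: np.ndarray = None  # type: ignore[assignment]
    mean_accessibility: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        n = len(self.chrom)
        object.__setattr__(self, "chrom", np.asarray(self.chrom, dtype=object))
        object.__setattr__(self, "start", np.asarray(self.start, dtype=np.int64))
        object.__setattr__(self, "end", np.asarray(self.end, dtype=np.int64))
        object.__setattr__(self, "peak_id", np.asarray(self.peak_id, dtype=object))
        for name in ("gc", "mean_accessibility"):
            v = getattr(self, name)
            v = np.full(n, np.nan) if v is None else np.asarray(v, dtype=float)
            object.__setattr__(self, name, v)
        if not (len(self.start) == len(self.end) == len(self.peak_id) == n
                and len(self.gc) == len(self.mean_accessibility) == n):
            raise DimensionMismatchError("peak table columns have unequal lengths")
        if np.any(self.start >= self.end):
            bad = self.peak_id[self.start >= self.end]
            raise ValueError(f"peaks with start >= end: {list(bad[:5])}")
        if len(np.unique(self.peak_id)) != n:
            raise DuplicatePeakError("peak_ids are not unique")
        for name in ("gc", "mean_accessibility"):
            v = getattr(self, name)
            ok = np.isnan(v) | ((v >= 0.0) & (v <= 1.0))
            if not ok.all():
                raise ValueError(f"{name} values outside [0, 1]")

    def __len__(self) -> int:
        return len(self.chrom)

    @property
    def is_sorted(self) -> bool:
        order = np.lexsort((self.start, self.chrom.astype(str)))
        return bool(np.all(order == np.arange(len(self))))

    def sort(self) -> tuple["PeakTable", np.ndarray]:
        """Return the table sorted by (chrom, start) and the permutation used."""
        order = np.lexsort((self.start, self.chrom.astype(str)))
        return self.take(order), order

    def take(self, idx) -> "PeakTable":
        idx = np.asarray(idx)
        return PeakTable(self.chrom[idx], self.start[idx], self.end[idx],
                         self.peak_id[idx], self.gc[idx],
                         self.mean_accessibility[idx])

    def with_gc(self, gc: np.ndarray) -> "PeakTable":
        return PeakTable(self.chrom, self.start, self.end, self.peak_id,
                         np.asarray(gc, dtype=float), self.mean_accessibility)

    def with_mean_accessibility(self, acc: np.ndarray) -> "PeakTable":
        return PeakTable(self.chrom, self.start, self.end, self.peak_id,
                         self.gc, np.asarray(acc, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom, "start": self.start, "end": self.end,
            "peak_id": self.peak_id, "gc": self.gc,
            "mean_accessibility": self.mean_accessibility,
        })

    @classmethod
    def from_bed(cls, path, sort: bool = True) -> "PeakTable":
        df = _read_bed_df(path)
        table = cls(df["chrom"].to_numpy(), df["start"].to_numpy(),
                    df["end"].to_numpy(), df["peak_id"].to_numpy())
        if sort:
            table, _ = table.sort()
        return table

    def to_annotated_tsv(self, path, header_lines: Sequence[str] = ()) -> None:
        """Write a BED6+ style TSV with gc and mean_accessibility columns."""
        with open(path, "wt") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("# chrom\tstart\tend\tpeak_id\tscore\tstrand\tgc\tmean_accessibility\n")
            for i in range(len(self)):
                fh.write(f"{self.chrom[i]}\t{self.start[i]}\t{self.end[i]}\t"
                         f"{self.peak_id[i]}\t0\t.\t{self.gc[i]:.6g}\t"
                         f"{self.mean_accessibility[i]:.6g}\n")

    @classmethod
    def from_annotated_tsv(cls, path) -> "PeakTable":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["chrom", "start", "end", "peak_id", "score",
                                "strand", "gc", "mean_accessibility"])
        return cls(df["chrom"].to_numpy(), df["start"].to_numpy(),
                   df["end"].to_numpy(), df["peak_id"].to_numpy(),
                   df["gc"].to_numpy(), df["mean_accessibility"].to_numpy())


def _read_bed_df(path) -> pd.DataFrame:
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", header=None)
    if df.shape[1] < 3:
        raise DimensionMismatchError(f"{path}: BED needs >=3 columns")
    df = df.iloc[:, : min(df.shape[1], 4)]
    df.columns = ["chrom", "start", "end", "peak_id"][: df.shape[1]]
    if "peak_id" not in df.columns or df["peak_id"].isna().any():
        df["peak_id"] = [f"{c}:{s}-{e}" for c, s, e in
                         zip(df["chrom"], df["start"], df["end"])]
    df["chrom"] = df["chrom"].astype(str)
    coords = list(zip(df["chrom"], df["start"], df["end"]))
    if len(set(coords)) != len(coords):
        raise DuplicatePeakError(f"{path}: duplicated peak coordinates")
    return df


@dataclass(frozen=True)
class CountMatrix:
    """Raw (pre-binarization) fragment/insertion counts, cells x peaks."""

    values: np.ndarray
    cell_ids: list[str]
    peak_ids: list[str]

    def __post_init__(self):
        v = np.asarray(self.values)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.cell_ids), len(self.peak_ids)):
            raise DimensionMismatchError(
                f"counts shape {v.shape} != ({len(self.cell_ids)} cells, "
                f"{len(self.peak_ids)} peaks)")


@dataclass(frozen=True)
class BinaryAccessibilityMatrix:
    """Binarized accessibility: entry (c, j) is 1 iff peak j is open in cell c.

    ``per_cell_total`` (row sums) is the cell's total accessibility — the
    number of open regions in that cell.
    """

    values: np.ndarray
    cell_ids: list[str]
    peak_ids: list[str]
    per_cell_total: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.values, dtype=np.uint8))
        if not np.isin(v, (0, 1)).all():
            raise ValueError("binary matrix entries must be exactly 0 or 1")
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.cell_ids), len(self.peak_ids)):
            raise DimensionMismatchError(
                f"matrix shape {v.shape} != ({len(self.cell_ids)} cells, "
                f"{len(self.peak_ids)} peaks)")
        totals = v.sum(axis=1, dtype=np.int64)
        if self.per_cell_total is not None and not np.array_equal(
                np.asarray(self.per_cell_total), totals):
            raise ValueError("per_cell_total does not equal row sums")
        object.__setattr__(self, "per_cell_total", totals)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.values.shape[1]

    def restrict_cells(self, idx) -> "BinaryAccessibilityMatrix":
        idx = np.asarray(idx)
        return BinaryAccessibilityMatrix(
            self.values[idx], [self.cell_ids[i] for i in idx], self.peak_ids)


@dataclass(frozen=True)
class FeaturePeakSet:
    """An ordered subset of the peak universe carrying a common annotation.

    Order is meaningful: background sets built against a feature set are
    aligned position-by-position (peak-for-peak matching).
    """

    name: str
    peak_indices: np.ndarray
    universe_size: int | None = None

    def __post_init__(self):
        idx = np.asarray(self.peak_indices, dtype=np.int64)
        object.__setattr__(self, "peak_indices", idx)
        if idx.size == 0:
            raise EmptyFeatureSetError(f"feature set {self.name!r} is empty")
        if len(np.unique(idx)) != idx.size:
            raise ValueError(f"feature set {self.name!r} has duplicate indices")
        if idx.min() < 0:
            raise IndexError(f"feature set {self.name!r} has negative indices")
        if self.universe_size is not None and idx.max() >= self.universe_size:
            raise IndexError(
                f"feature set {self.name!r} indexes beyond the peak universe")

    def __len__(self) -> int:
        return int(self.peak_indices.size)


def read_peak_matrix(matrix_path, peaks_path, barcodes_path,
                     orientation: str | None = None,
                     ) -> tuple[CountMatrix, PeakTable]:
    """Load a matrix bundle, returning cells-x-peaks counts plus the peak table.

    Orientation on disk is resolved by matching matrix dimensions against
    the number of peaks and barcodes; a square matrix with equally long
    sidecars is ambiguous and requires ``orientation`` ("cells_by_peaks" or
    "peaks_by_cells").  Peaks are returned sorted by (chrom, start) with the
    count columns permuted in step, so column j always corresponds to peak j.
    """
    with _open_text(matrix_path) as fh:
        mat = spio.mmread(fh)
    counts = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    peaks_df = _read_bed_df(peaks_path)
    with _open_text(barcodes_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    n_peaks, n_cells = len(peaks_df), len(barcodes)

    if counts.shape == (n_cells, n_peaks):
        if n_cells == n_peaks and orientation is None:
            raise DimensionMismatchError(
                "square matrix with equally many peaks and barcodes: pass an "
                "explicit orientation")
        if orientation == "peaks_by_cells":
            counts = counts.T
    elif counts.shape == (n_peaks, n_cells):
        counts = counts.T
    else:
        raise DimensionMismatchError(
            f"matrix shape {counts.shape} matches neither {n_cells} barcodes x "
            f"{n_peaks} peaks nor its transpose")

    table = PeakTable(peaks_df["chrom"].to_numpy(), peaks_df["start"].to_numpy(),
                      peaks_df["end"].to_numpy(), peaks_df["peak_id"].to_numpy())
    table, order = table.sort()
    counts = counts[:, order]
    return CountMatrix(counts, barcodes, list(table.peak_id)), table


def write_bundle(matrix: BinaryAccessibilityMatrix, peaks: PeakTable, outdir,
                 prefix: str = "fixture") -> dict[str, Path]:
    """Write a matrix-market + BED + barcodes bundle (peaks x cells on disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{prefix}.mtx",
        "peaks": outdir / f"{prefix}.peaks.bed",
        "barcodes": outdir / f"{prefix}.barcodes.txt",
    }
    spio.mmwrite(str(paths["matrix"]),
                 sparse.csc_matrix(matrix.values.T.astype(np.int64)))
    with open(paths["peaks"], "wt") as fh:
        for i in range(len(peaks)):
            fh.write(f"{peaks.chrom[i]}\t{peaks.start[i]}\t{peaks.end[i]}\t"
                     f"{peaks.peak_id[i]}\n")
    with open(paths["barcodes"], "wt") as fh:
        fh.write("\n".join(matrix.cell_ids) + "\n")
    return paths


def binarize(counts, threshold: int = 1,
             cell_ids: Sequence[str] | None = None,
             peak_ids: Sequence[str] | None = None) -> BinaryAccessibilityMatrix:
    """Binarize counts: a region is accessible (1) iff its count >= threshold.

    Accepts either a :class:`CountMatrix` or a bare array (identifiers then
    default to ``cell<i>`` / ``peak<j>`` unless given).
    """
    if threshold < 1:
        raise ValueError("threshold must be a positive integer")
    if isinstance(counts, CountMatrix):
        cell_ids = counts.cell_ids
        peak_ids = counts.peak_ids
        counts = counts.values
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    n_cells, n_peaks = counts.shape
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(n_cells)]
    if peak_ids is None:
        peak_ids = [f"peak{j}" for j in range(n_peaks)]
    return BinaryAccessibilityMatrix((counts >= threshold).astype(np.uint8),
                                     list(cell_ids), list(peak_ids))


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    """Read a feature BED as a list of (chrom, start, end) tuples."""
    df = _read_bed_df(path)
    return list(zip(df["chrom"], df["start"].astype(int), df["end"].astype(int)))


def map_feature_to_peaks(peaks: PeakTable,
                         feature_intervals: Iterable[tuple[str, int, int]],
                         min_overlap_bp: int = 1,
                         name: str = "feature") -> FeaturePeakSet:
    """Indices of peaks overlapping any feature interval by >= min_overlap_bp.

    Both interval sets are 0-based half-open; touching intervals do not
    overlap.  Strand is ignored.  Raises :class:`EmptyFeatureSetError` when
    no peak qualifies, so callers never score variability on zero peaks.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in feature_intervals:
        if end > start:
            trees.setdefault(str(chrom), IntervalTree()).addi(int(start), int(end))
    hits = []
    for j in range(len(peaks)):
        tree = trees.get(str(peaks.chrom[j]))
        if tree is None:
            continue
        s, e = int(peaks.start[j]), int(peaks.end[j])
        for iv in tree.overlap(s, e):
            if min(e, iv.end) - max(s, iv.begin) >= min_overlap_bp:
                hits.append(j)
                break
    if not hits:
        raise EmptyFeatureSetError(
            f"feature {name!r}: no peak overlaps any interval by "
            f">={min_overlap_bp} bp")
    return FeaturePeakSet(name, np.asarray(hits), universe_size=len(peaks))


def mean_accessibility(matrix: BinaryAccessibilityMatrix) -> np.ndarray:
    """Per-peak fraction of cells in which the peak is accessible."""
    if matrix.n_cells == 0:
        raise DimensionMismatchError("matrix has no cells")
    return matrix.values.mean(axis=0)
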