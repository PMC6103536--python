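"""Raw cell-to-cell variability of a peak subset.

Each cell is a binary vector over the peaks of interest.  The dissimilarity
between two cells is the angular cosine distance

    d(a, b) = arccos( a.b / (|a| |b|) ) / (pi/2),

which for nonnegative vectors lies in [0, 1]: 0 for cells open at the same
set of regions (up to scaling) and 1 for cells whose open regions are
disjoint.  The full pairwise distance matrix is embedded into Euclidean
space by classical multidimensional scaling (principal coordinate
analysis), and the raw variability is the mean Euclidean distance of the
embedded cells from their centroid — how far a typical cell sits from the
group norm for chromatin accessibility.

Classical scaling double-centers the elementwise-squared distance matrix,
B = -1/2 J (D o D) J, and eigendecomposes B; coordinates are eigenvectors
scaled by the square roots of positive eigenvalues.  Angular cosine
distance matrices need not be exactly Euclidean, so negative eigenvalues
can occur; they are dropped and their relative mass is reported.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientCellsError, UndefinedAngleError
from .matrix_io import BinaryAccessibilityMatrix, FeaturePeakSet

__all__ = [
    "DistanceMatrix",
    "Embedding",
    "RawVariability",
    "cosine_distance",
    "pairwise_distances",
    "pcoa_embed",
    "raw_variability",
]

_HALF_PI = np.pi / 2.0


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise angular cosine distances between cells."""

    d: np.ndarray
    cell_ids: list[str]

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.cell_ids)
        assert d.shape == (n, n), "distance matrix shape mismatch"
        assert np.allclose(np.diag(d), 0.0), "nonzero diagonal"
        assert np.allclose(d, d.T), "asymmetric distance matrix"
        assert d.min() >= -1e-12 and d.max() <= 1.0 + 1e-12, \
            "distances outside [0, 1]"

    @property
    def n_cells(self) -> int:
        return self.d.shape[0]


@dataclass(frozen=True)
class Embedding:
    """Principal-coordinate embedding with the centroid at the origin.

    ``dropped_negative_mass`` is sum(|negative eigenvalues|) / sum(|all
    eigenvalues|), a diagnostic for how non-Euclidean the distances were.
    """

    coords: np.ndarray
    eigenvalues: np.ndarray
    dropped_negative_mass: float

    @property
    def n_axes(self) -> int:
        return self.coords.shape[1]

    def centroid_distances(self) -> np.ndarray:
        return np.sqrt((self.coords ** 2).sum(axis=1))


@dataclass(frozen=True)
class RawVariability:
    """Mean distance to the embedding centroid, before bias correction."""

    value: float
    n_cells_used: int
    n_cells_dropped_zero: int


def cosine_distance(a, b) -> float:
    """Angular cosine distance between two binary accessibility vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    na2, nb2 = float(a @ a), float(b @ b)
    if na2 == 0.0 or nb2 == 0.0:
        raise UndefinedAngleError("angle undefined for an all-zero vector")
    # sqrt of the product (not product of sqrts) keeps the cosine exactly 1
    # for parallel binary vectors, whose dot products are exact integers
    cos = np.clip(a @ b / np.sqrt(na2 * nb2), -1.0, 1.0)
    return float(np.arccos(cos) / _HALF_PI)


def _cosine_distance_matrix(x: np.ndarray) -> np.ndarray:
    """Pairwise angular cosine distances between the rows of ``x``.

    Rows must each have at least one nonzero entry.
    """
    xf = x.astype(np.float64, copy=False)
    gram = xf @ xf.T
    sq = np.diag(gram)
    cos = gram / np.sqrt(np.outer(sq, sq))
    np.clip(cos, -1.0, 1.0, out=cos)
    d = np.arccos(cos) / _HALF_PI
    np.fill_diagonal(d, 0.0)
    return np.minimum(d, d.T)  # exact symmetry against fp round-off


def pairwise_distances(matrix: BinaryAccessibilityMatrix,
                       peaks: FeaturePeakSet,
                       ) -> tuple[DistanceMatrix, list[str]]:
    """Distance matrix over cells, restricted to the feature's peak columns.

    Cells with no accessible peak in the subset have an undefined angle;
    they are dropped and returned as the second element.  Fewer than three
    usable cells is an error.
    """
    sub = matrix.values[:, peaks.peak_indices]
    keep = sub.sum(axis=1) > 0
    dropped = [cid for cid, k in zip(matrix.cell_ids, keep) if not k]
    if int(keep.sum()) < 3:
        raise InsufficientCellsError(
            f"only {int(keep.sum())} cells accessible at feature "
            f"{peaks.name!r}; need >=3")
    d = _cosine_distance_matrix(sub[keep])
    return DistanceMatrix(d, [c for c, k in zip(matrix.cell_ids, keep) if k]), dropped


def _gower_center(d: np.ndarray) -> np.ndarray:
    """B = -1/2 J (D o D) J with J the centering projector."""
    d2 = d * d
    row = d2.mean(axis=1)
    grand = row.mean()
    return -0.5 * (d2 - row[:, None] - row[None, :] + grand)


def _embed_arrays(d: np.ndarray, eig_tol: float) -> tuple[np.ndarray, np.ndarray, float]:
    b = _gower_center(d)
    w, v = np.linalg.eigh(b)
    total = np.abs(w).sum()
    neg_mass = float(np.abs(w[w < 0]).sum() / total) if total > 0 else 0.0
    cutoff = eig_tol * max(w.max(initial=0.0), 0.0)
    keep = w > cutoff
    w, v = w[keep], v[:, keep]
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    # deterministic sign: largest-magnitude component of each axis positive
    for k in range(v.shape[1]):
        i = int(np.argmax(np.abs(v[:, k])))
        if v[i, k] < 0:
            v[:, k] = -v[:, k]
    coords = v * np.sqrt(w)
    return coords, w, neg_mass


def pcoa_embed(dist: DistanceMatrix, eig_tol: float = 1e-9) -> Embedding:
    """Classical scaling of an angular cosine distance matrix.

    Only eigenvalues above ``eig_tol`` times the largest are retained; a
    matrix of identical cells yields a valid zero-axis embedding.
    """
    coords, w, neg_mass = _embed_arrays(dist.d, eig_tol)
    return Embedding(coords, w, neg_mass)


def _dispersion(x: np.ndarray, eig_tol: float = 1e-9) -> float:
    """Mean centroid distance of the rows of a binary submatrix (no checks)."""
    d = _cosine_distance_matrix(x)
    coords, _, _ = _embed_arrays(d, eig_tol)
    if coords.shape[1] == 0:
        return 0.0
    return float(np.sqrt((coords ** 2).sum(axis=1)).mean())


def raw_variability(matrix: BinaryAccessibilityMatrix,
                    peaks: FeaturePeakSet,
                    eig_tol: float = 1e-9) -> RawVariability:
    """Mean distance of cells from the centroid at the feature's peaks.

    Zero iff all usable cells have identical accessibility vectors on the
    subset.  Invariant to cell and peak ordering.
    """
    dist, dropped = pairwise_distances(matrix, peaks)
    emb = pcoa_embed(dist, eig_tol)
    if emb.n_axes == 0:
        value = 0.0
    else:
        value = float(emb.centroid_distances().mean())
    return RawVariability(value, dist.n_cells, len(dropped))
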