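"""Bray-Curtis distance matrices and principal-coordinates analysis."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from skinmatch.tables import OtuTable

log = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "Ordination",
    "bray_curtis",
    "pcoa",
    "read_distance_matrix",
    "write_distance_matrix",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with sample ids."""

    sample_ids: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        n = len(self.sample_ids)
        if data.shape != (n, n):
            raise ValueError(f"matrix shape {data.shape} does not match {n} ids")
        if not np.allclose(data, data.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(data), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(data < -1e-12):
            raise ValueError("negative dissimilarity")
        sym = (data + data.T) / 2.0
        np.fill_diagonal(sym, 0.0)
        object.__setattr__(self, "data", sym)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def between(self, a: str, b: str) -> float:
        return float(self.data[self.index(a), self.index(b)])

    def subset(self, sample_ids: Iterable[str]) -> "DistanceMatrix":
        ids = list(sample_ids)
        idx = [self.index(s) for s in ids]
        return DistanceMatrix(tuple(ids), self.data[np.ix_(idx, idx)])


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y) between rows.

    Computed on counts; rarefied (equal-depth) input is expected and a
    warning is logged otherwise, since only then do count- and
    proportion-based distances agree.
    """
    sums = table.sample_sums()
    if np.any(sums == 0):
        sid = table.sample_ids[int(np.flatnonzero(sums == 0)[0])]
        raise ValueError(f"sample {sid!r} has zero total count")
    if len(set(sums.tolist())) > 1:
        log.warning(
            "bray_curtis on unequal sample depths (min=%d max=%d); rarefy first "
            "for depth-independent distances", sums.min(), sums.max(),
        )
    condensed = pdist(table.counts.astype(float), metric="braycurtis")
    return DistanceMatrix(table.sample_ids, squareform(condensed))


@dataclass(frozen=True)
class Ordination:
    """Principal-coordinate embedding of a distance matrix.

    ``coordinates`` holds one column per retained positive axis, ordered
    by descending eigenvalue; ``eigenvalues`` includes any negative
    eigenvalues for reporting, but their axes are dropped.
    """

    sample_ids: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> Ordination:
    """Classical metric scaling (Gower double-centering + eigendecomposition).

    Coordinates are eigenvectors scaled by the square roots of the
    positive eigenvalues; pairwise Euclidean distances across all
    positive axes reproduce the input exactly when it is
    Euclidean-embeddable.  No Lingoes/Cailliez correction is applied;
    negative eigenvalues are reported as-is.
    """
    n = dm.n_samples
    if n_axes is not None and n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    a = -0.5 * dm.data**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    b = a - row - col + a.mean()
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-12, 1e-10 * abs(vals[0])) if vals.size else 0.0
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    keep = coords.shape[1] if n_axes is None else min(n_axes, coords.shape[1])
    pos_sum = vals[pos].sum()
    prop = (vals[pos][:keep] / pos_sum) if pos_sum > 0 else np.zeros(keep)
    return Ordination(dm.sample_ids, coords[:, :keep], vals, prop)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Square TSV: ids as header row and first column."""
    df = pd.DataFrame(dm.data, index=list(dm.sample_ids), columns=list(dm.sample_ids))
    df.to_csv(path, sep="\t", index_label="")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = tuple(str(s) for s in df.columns)
    if tuple(str(s) for s in df.index) != ids:
        raise ValueError("distance matrix row and column ids differ")
    return DistanceMatrix(ids, df.to_numpy(dtype=float))


def write_ordination(ord_: Ordination, path: str | Path) -> None:
    """Coordinates TSV preceded by an eigenvalue header block."""
    with open(path, "w") as fh:
        fh.write("# eigenvalues\t" + "\t".join(f"{v:.10g}" for v in ord_.eigenvalues) + "\n")
        fh.write(
            "# proportion_explained\t"
            + "\t".join(f"{v:.10g}" for v in ord_.proportion_explained)
            + "\n"
        )
        cols = "\t".join(f"PC{i + 1}" for i in range(ord_.n_axes))
        fh.write(f"sample_id\t{cols}\n")
        for i, sid in enumerate(ord_.sample_ids):
            vals = "\t".join(f"{v:.10g}" for v in ord_.coordinates[i])
            fh.write(f"{sid}\t{vals}\n")
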