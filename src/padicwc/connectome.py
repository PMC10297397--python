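"""Approximation of connection matrices by locally translation-invariant
p-adic kernels.

A connection matrix A (weighted directed adjacency of cortical regions) is
first zero-padded to size p^k x p^k and its rows/columns are read as elements
of G_k.  For a resolution 0 <= r <= k, the reduction-mod-p^r map partitions
the entries into p^(2r) blocks: block (a, b) collects the entries whose row
lies in the ball a + p^r Z_p and whose column lies in b + p^r Z_p.  Within
each block the entries are replaced by the mean over their group-difference
class (i - j) mod p^k, yielding the kernel matrix K_r of a kernel K_r(x, y)
that depends only on x - y inside each pair of balls.  This wrapped-diagonal
averaging is the mean-square orthogonal projection onto locally
translation-invariant kernels: it is idempotent, preserves the total entry
sum, reproduces A exactly at r = k, and its approximation error is
nonincreasing in r.

The resulting K_r can replace the excitatory-excitatory convolution in the
Wilson-Cowan dynamics (see :func:`padicwc.dynamics.integral_operator`),
injecting measured connectivity into the model.  A synthetic generator
emulates matrices of this kind — entries decaying with ultrametric distance
plus noise — for testing in place of external datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .grid import PadicGrid

__all__ = [
    "ConnectionMatrix",
    "KernelMatrixApprox",
    "pad_matrix",
    "block_partition",
    "local_circulant_average",
    "approximation_error",
    "synthetic_hierarchical_matrix",
    "read_matrix",
    "write_matrix",
]


@dataclass
class ConnectionMatrix:
    """Square real matrix of directed connection weights, with optional node
    labels."""

    values: np.ndarray
    labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"connection matrix must be square, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("connection matrix entries must be finite")
        if self.labels is not None and len(self.labels) != self.values.shape[0]:
            raise ValueError("label count does not match matrix size")


@dataclass
class KernelMatrixApprox:
    """Resolution-r locally translation-invariant kernel matrix.

    ``block_profiles[(a, b)]`` is the difference profile psi_{a,b} of block
    (a, b): psi[d] is the kernel value for entries (i, j) of the block with
    (i - j - (a - b)) / p^r = d (mod p^(k-r)).
    """

    values: np.ndarray
    p: int
    k: int
    r: int
    block_profiles: dict

    def __post_init__(self) -> None:
        n = self.p**self.k
        if self.values.shape != (n, n):
            raise ValueError(f"kernel matrix shape {self.values.shape}, expected {(n, n)}")


def pad_matrix(A, p: int) -> tuple[np.ndarray, int]:
    """Zero-pad a square matrix into the top-left corner of the smallest
    p^k x p^k matrix that holds it; returns (padded, k)."""
    values = np.asarray(getattr(A, "values", A), dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"matrix must be square, got {values.shape}")
    n = values.shape[0]
    if n < 1:
        raise ValueError("matrix must have at least one row")
    k = 0
    while p**k < n:
        k += 1
    padded = np.zeros((p**k, p**k))
    padded[:n, :n] = values
    return padded, k


def block_partition(k: int, r: int, p: int) -> dict:
    """Map (a, b) in G_r x G_r to the set of entry pairs {(i, j) : i = a,
    j = b (mod p^r)}; the p^(2r) blocks partition all p^(2k) entries."""
    if not 0 <= r <= k:
        raise ValueError(f"resolution r={r} outside [0, {k}]")
    m = p ** (k - r)
    offsets = p**r * np.arange(m)
    blocks = {}
    for a in range(p**r):
        rows = a + offsets
        for b in range(p**r):
            cols = b + offsets
            blocks[(a, b)] = {(int(i), int(j)) for i in rows for j in cols}
    return blocks


def local_circulant_average(A_padded: np.ndarray, p: int, k: int, r: int) -> KernelMatrixApprox:
    """Project a p^k x p^k matrix onto resolution-r locally translation-
    invariant kernels by averaging each block over its wrapped diagonals."""
    A_padded = np.asarray(A_padded, dtype=float)
    n = p**k
    if A_padded.shape != (n, n):
        raise ValueError(f"matrix shape {A_padded.shape}, expected {(n, n)}")
    if not 0 <= r <= k:
        raise ValueError(f"resolution r={r} outside [0, {k}]")

    m = p ** (k - r)
    offsets = p**r * np.arange(m)
    s = np.arange(m)[:, None]
    t = np.arange(m)[None, :]
    d = (s - t) % m  # local difference class of entry (s, t) within a block
    K = np.empty_like(A_padded)
    profiles = {}
    for a in range(p**r):
        rows = a + offsets
        for b in range(p**r):
            cols = b + offsets
            block = A_padded[np.ix_(rows, cols)]
            # each class has exactly m entries in the m x m block
            psi = np.bincount(d.ravel(), weights=block.ravel(), minlength=m) / m
            K[np.ix_(rows, cols)] = psi[d]
            profiles[(a, b)] = psi
    return KernelMatrixApprox(values=K, p=p, k=k, r=r, block_profiles=profiles)


def approximation_error(A_padded: np.ndarray, K: KernelMatrixApprox) -> tuple[float, float]:
    """(max absolute, mean squared) entrywise difference between a padded
    matrix and its kernel approximation."""
    A_padded = np.asarray(A_padded, dtype=float)
    if A_padded.shape != K.values.shape:
        raise ValueError(f"shape mismatch: {A_padded.shape} vs {K.values.shape}")
    diff = A_padded - K.values
    return float(np.max(np.abs(diff))), float(np.mean(diff**2))


def synthetic_hierarchical_matrix(
    p: int, k: int, decay: float = 2.0, noise_sd: float = 0.15, seed: int = 0
) -> np.ndarray:
    """Synthetic stand-in for a cortical connection matrix with ultrametric
    structure: a_ij = exp(-decay |i - j|_p) plus Gaussian noise of standard
    deviation ``noise_sd`` truncated at 0, with zero diagonal.  Deterministic
    given ``seed``.  With ``noise_sd`` = 0 the matrix is circulant with
    respect to mod-p^k subtraction, hence an exact fixed point of
    :func:`local_circulant_average` at every resolution.
    """
    if decay <= 0:
        raise ValueError(f"decay must be > 0, got {decay}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    grid = PadicGrid(p, k)
    n = grid.size
    idx = np.arange(n)
    dist = grid.norms[(idx[:, None] - idx[None, :]) % n]
    A = np.exp(-decay * dist)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        A = A + rng.normal(0.0, noise_sd, size=(n, n))
    A = np.maximum(A, 0.0)
    np.fill_diagonal(A, 0.0)
    return A


# -- delimited-text I/O ------------------------------------------------------


class MatrixParseError(ValueError):
    def __init__(self, message: str, row: int, col: Optional[int] = None):
        loc = f"row {row}" + ("" if col is None else f", column {col}")
        super().__init__(f"{message} ({loc})")
        self.row = row
        self.col = col


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_matrix(path) -> ConnectionMatrix:
    """Read a square matrix from comma- or tab-delimited text, with an
    optional header row of node labels."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    delim = _detect_delimiter(lines[0])
    rows = [ln.split(delim) for ln in lines]

    labels = None
    first = rows[0]
    try:
        [float(c) for c in first]
    except ValueError:
        labels = [c.strip() for c in first]
        rows = rows[1:]

    n_cols = len(rows[0]) if rows else 0
    values = np.empty((len(rows), n_cols))
    for i, cells in enumerate(rows):
        if len(cells) != n_cols:
            raise MatrixParseError(
                f"ragged row: expected {n_cols} cells, got {len(cells)}", row=i
            )
        for j, cell in enumerate(cells):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise MatrixParseError(f"non-numeric cell {cell!r}", row=i, col=j) from None
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: matrix is {values.shape[0]}x{values.shape[1]}, not square")
    if labels is not None and len(labels) != values.shape[1]:
        raise ValueError(f"{path}: {len(labels)} labels for {values.shape[1]} columns")
    return ConnectionMatrix(values=values, labels=labels)


def write_matrix(path, matrix: ConnectionMatrix, delimiter: str = ",") -> None:
    """Write a matrix as delimited text at 17 significant digits (lossless
    round-trip for doubles)."""
    values = matrix.values
    with open(path, "w", encoding="utf-8") as fh:
        if matrix.labels is not None:
            fh.write(delimiter.join(matrix.labels) + "\n")
        for row in values:
            fh.write(delimiter.join(f"{x:.17g}" for x in row) + "\n")
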