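"""Finite-level p-adic arithmetic on the quotient group G_l = Z_p / p^l Z_p.

The ring of p-adic integers Z_p is an ultrametric, compact abelian group whose
elements are organized as the branches of an infinite rooted p-ary tree.  All
computations in this package happen on the finite quotient G_l, identified with
the canonical representatives 0..p^l-1 written in base p: the index
i = i_0 + i_1 p + ... + i_{l-1} p^{l-1} is the leaf reached by following digits
i_0, i_1, ... down the depth-l tree.  The p-adic norm |i - j|_p measures how
deep the first common ancestor of two leaves sits: norm p^-v means the leaves
agree on their first v digits.

The normalized Haar measure of Z_p assigns mass p^-l to every leaf of G_l, so
integrals over Z_p become Haar-weighted sums over grid indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = [
    "PadicGrid",
    "BallSpec",
    "padic_norm",
    "ball_indicator",
    "monna_map",
    "tree_order",
]


def _is_prime(n: int) -> bool:
    if n < 2:
        return False
    if n < 4:
        return True
    if n % 2 == 0:
        return False
    d = 3
    while d * d <= n:
        if n % d == 0:
            return False
        d += 2
    return True


def padic_norm(i: int, p: int) -> float:
    """p-adic norm of an integer: 0 for i = 0, else p^-v with v the
    multiplicity of p in i."""
    i = int(i)
    if i == 0:
        return 0.0
    v = 0
    while i % p == 0:
        i //= p
        v += 1
    return float(p) ** (-v)


@dataclass(frozen=True)
class PadicGrid:
    """The group G_l = Z_p/p^l Z_p with its norm, Haar weight and orderings.

    Parameters
    ----------
    p : prime >= 2
    l : tree depth (level) >= 1; the grid has p**l sites.
    """

    p: int
    l: int

    def __post_init__(self) -> None:
        if not _is_prime(self.p):
            raise ValueError(f"p must be prime, got {self.p}")
        if self.l < 1:
            raise ValueError(f"level l must be >= 1, got {self.l}")

    @property
    def size(self) -> int:
        return self.p**self.l

    @property
    def haar_weight(self) -> float:
        """Quadrature weight per site: p^-l (total mass exactly 1)."""
        return float(self.p) ** (-self.l)

    # -- index arithmetic ---------------------------------------------------

    def _check_index(self, i: int) -> int:
        i = int(i)
        if not 0 <= i < self.size:
            raise IndexError(f"index {i} out of range for grid of size {self.size}")
        return i

    def digits(self, i: int) -> tuple[int, ...]:
        """Base-p digit expansion (i_0, ..., i_{l-1}) with i = sum i_j p^j."""
        i = self._check_index(i)
        out = []
        for _ in range(self.l):
            out.append(i % self.p)
            i //= self.p
        return tuple(out)

    def from_digits(self, digits) -> int:
        if len(digits) != self.l:
            raise ValueError(f"expected {self.l} digits, got {len(digits)}")
        i = 0
        for j, d in enumerate(digits):
            if not 0 <= d < self.p:
                raise ValueError(f"digit {d} out of range for p={self.p}")
            i += d * self.p**j
        return i

    def add(self, i: int, j: int) -> int:
        return (self._check_index(i) + self._check_index(j)) % self.size

    def sub(self, i: int, j: int) -> int:
        """Group subtraction (i - j) mod p^l."""
        return (self._check_index(i) - self._check_index(j)) % self.size

    def norm(self, i: int) -> float:
        """Norm of the canonical representative; the class of 0 has norm 0."""
        return padic_norm(self._check_index(i), self.p)

    def distance(self, i: int, j: int) -> float:
        """Ultrametric distance |i - j|_p on the grid."""
        return padic_norm(self.sub(i, j), self.p)

    def reduce(self, i: int, r: int) -> int:
        """Reduction mod p^r: truncate the expansion to its first r digits."""
        if not 0 <= r <= self.l:
            raise ValueError(f"resolution r={r} outside [0, {self.l}]")
        return self._check_index(i) % self.p**r

    def monna(self, i: int) -> float:
        """Monna map m(i) = sum_j i_j p^-(j+1): digit reversal into [0, 1)."""
        return sum(d * float(self.p) ** (-(j + 1)) for j, d in enumerate(self.digits(i)))

    # -- vectorized site data ----------------------------------------------

    @cached_property
    def norms(self) -> np.ndarray:
        """|i|_p for every canonical representative i (read-only array)."""
        out = np.array([padic_norm(i, self.p) for i in range(self.size)])
        out.setflags(write=False)
        return out

    @cached_property
    def monna_values(self) -> np.ndarray:
        out = np.array([self.monna(i) for i in range(self.size)])
        out.setflags(write=False)
        return out

    @cached_property
    def tree_order(self) -> np.ndarray:
        """Permutation sorting indices by Monna value, so every ball
        a + p^r Z_p occupies a contiguous run of length p^(l-r)."""
        out = np.argsort(self.monna_values, kind="stable")
        out.setflags(write=False)
        return out

    def ball_mask(self, ball: "BallSpec") -> np.ndarray:
        """Boolean indicator of the ball over all grid sites."""
        r = ball.radius_exponent
        if not 0 <= r <= self.l:
            raise ValueError(f"radius exponent {r} outside [0, {self.l}]")
        c = self._check_index(ball.center)
        return (np.arange(self.size) - c) % self.p**r == 0


@dataclass(frozen=True)
class BallSpec:
    """The ball center + p^radius_exponent Z_p, of radius p^-radius_exponent."""

    center: int
    radius_exponent: int


def ball_indicator(x: int, ball: BallSpec, grid: PadicGrid) -> int:
    """Characteristic function Omega(p^r |x - a|_p): 1 iff x = a (mod p^r)."""
    r = ball.radius_exponent
    if not 0 <= r <= grid.l:
        raise ValueError(f"radius exponent {r} outside [0, {grid.l}]")
    return int(grid.sub(x, ball.center) % grid.p**r == 0)


def monna_map(i: int, grid: PadicGrid) -> float:
    return grid.monna(i)


def tree_order(grid: PadicGrid) -> np.ndarray:
    return grid.tree_order
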