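"""Constitutive functions of the hierarchical Wilson-Cowan model.

Couplings between populations A, B in {E, I} are radial functions of the
p-adic distance,

    w_AB(x) = b_AB exp(sigma_AB) - b_AB exp(sigma_AB |x|_p),

which vanish at |x|_p = 1 and peak at x = 0: nearby leaves of the tree
interact strongly, maximally distant ones not at all.  The population gain is
the two-term logistic sigmoid

    S_A(z) = 1/(1 + exp(-v_A (z - theta_A))) - 1/(1 + exp(v_A theta_A)),

shifted so that S_A(0) = 0 exactly (a quiescent network stays quiescent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .grid import PadicGrid

__all__ = ["RadialExpKernel", "Sigmoid", "kernel_eval", "discretize_kernel", "sigmoid_eval"]


@dataclass(frozen=True)
class RadialExpKernel:
    """Radial exponential coupling kernel with amplitude ``b`` and shape
    ``sigma`` (both > 0, dimensionless)."""

    b: float
    sigma: float

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError(f"kernel amplitude b must be > 0, got {self.b}")
        if self.sigma <= 0:
            raise ValueError(f"kernel shape sigma must be > 0, got {self.sigma}")

    def at_norm(self, norm):
        """Kernel value as a function of the p-adic norm |x|_p in [0, 1]."""
        return self.b * np.exp(self.sigma) - self.b * np.exp(self.sigma * np.asarray(norm))

    def evaluate(self, grid: PadicGrid, x: int) -> float:
        return float(self.at_norm(grid.norm(x)))

    def discretize(self, grid: PadicGrid) -> np.ndarray:
        """Sample the kernel at every canonical representative of G_l."""
        return np.asarray(self.at_norm(grid.norms))


@dataclass(frozen=True)
class Sigmoid:
    """Two-term logistic gain with slope ``v`` > 0 and threshold ``theta``."""

    v: float
    theta: float

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValueError(f"sigmoid slope v must be > 0, got {self.v}")

    def __call__(self, z):
        # expit is overflow-safe; at z = 0 the two terms cancel exactly.
        return expit(self.v * (np.asarray(z, dtype=float) - self.theta)) - expit(
            -self.v * self.theta
        )

    @property
    def lower(self) -> float:
        """Infimum -1/(1 + e^{v theta}), approached as z -> -inf."""
        return -float(expit(-self.v * self.theta))

    @property
    def upper(self) -> float:
        """Supremum 1 - 1/(1 + e^{v theta}), approached as z -> +inf."""
        return 1.0 - float(expit(-self.v * self.theta))

    @property
    def sup_abs(self) -> float:
        return max(abs(self.lower), abs(self.upper))


def kernel_eval(kernel: RadialExpKernel, x: int, grid: PadicGrid) -> float:
    return kernel.evaluate(grid, x)


def discretize_kernel(kernel: RadialExpKernel, grid: PadicGrid) -> np.ndarray:
    return kernel.discretize(grid)


def sigmoid_eval(z, s: Sigmoid):
    return s(z)
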