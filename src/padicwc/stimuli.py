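"""Stimulus protocols for the hierarchical Wilson-Cowan experiments.

A stimulus is a callable ``h(grid, t) -> array`` giving the input to one
population at every grid site.  Three families are provided:

* :class:`BallPulse` — a constant level on a p-adic ball, optionally gated to
  the time window [0, delta] (the localized pulse / maintained stimulus of the
  single-pulse experiments, and the constant inputs of the connectome runs).
* :class:`HysteresisStimulus` — the moving twin-Gaussian binocular stimulus of
  the spatial-hysteresis experiment, expressed through the Monna coordinate
  m(x) so that the two bumps travel along the tree's leaf ordering.
* :class:`ZeroStimulus` — no input.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .grid import BallSpec, PadicGrid

__all__ = [
    "BallPulse",
    "HysteresisStimulus",
    "ZeroStimulus",
    "pulse_stimulus",
    "hysteresis_stimulus",
    "constant_stimulus",
]


@lru_cache(maxsize=None)
def _ball_mask(grid: PadicGrid, center: int, radius_exponent: int) -> np.ndarray:
    mask = grid.ball_mask(BallSpec(center, radius_exponent)).astype(float)
    mask.setflags(write=False)
    return mask


@dataclass(frozen=True)
class BallPulse:
    """amplitude * Omega(p^r |x - center|_p) * 1_[0, duration](t).

    ``radius_exponent`` r = 0 makes the spatial factor 1 everywhere on Z_p
    (a spatially uniform input); ``duration`` None means never switched off.
    """

    amplitude: float
    center: int = 0
    radius_exponent: int = 0
    duration: float | None = None

    def __post_init__(self) -> None:
        if self.duration is not None and self.duration <= 0:
            raise ValueError(f"pulse duration must be > 0, got {self.duration}")

    def profile(self, grid: PadicGrid) -> np.ndarray:
        return self.amplitude * _ball_mask(grid, self.center, self.radius_exponent)

    def __call__(self, grid: PadicGrid, t: float) -> np.ndarray:
        if self.duration is not None and not 0.0 <= t <= self.duration:
            return np.zeros(grid.size)
        return self.profile(grid)


@dataclass(frozen=True)
class HysteresisStimulus:
    """Twin Gaussian bumps in the Monna coordinate.

    In ``open`` mode the bumps start merged at m(x) = 0.5 and separate at a
    constant rate,

        h(x, t) = exp(-(30(0.5 - m(x)) - 0.5 t)^2)
                + exp(-(30(0.5 - m(x)) + 0.5 t)^2).

    In ``return`` mode the separation is played forward for t <= 18, reversed
    for 18 < t <= 36 (h(x, 36 - t)), and the stimulus is 0 for t > 36.
    """

    mode: str = "open"

    def __post_init__(self) -> None:
        if self.mode not in ("open", "return"):
            raise ValueError(f"mode must be 'open' or 'return', got {self.mode!r}")

    def _open(self, grid: PadicGrid, t: float) -> np.ndarray:
        u = 30.0 * (0.5 - grid.monna_values)
        return np.exp(-((u - 0.5 * t) ** 2)) + np.exp(-((u + 0.5 * t) ** 2))

    def __call__(self, grid: PadicGrid, t: float) -> np.ndarray:
        if self.mode == "open":
            return self._open(grid, t)
        if t <= 18.0:
            return self._open(grid, t)
        if t <= 36.0:
            return self._open(grid, 36.0 - t)
        return np.zeros(grid.size)


@dataclass(frozen=True)
class ZeroStimulus:
    def __call__(self, grid: PadicGrid, t: float) -> np.ndarray:
        return np.zeros(grid.size)


# -- pointwise conveniences -------------------------------------------------


def pulse_stimulus(
    spec: BallPulse, x: int, t: float, grid: PadicGrid
) -> float:
    """Pointwise evaluation of a ball pulse at site x, time t."""
    return float(spec(grid, t)[grid._check_index(x)])


def hysteresis_stimulus(x: int, t: float, mode: str, grid: PadicGrid) -> float:
    return float(HysteresisStimulus(mode)(grid, t)[grid._check_index(x)])


def constant_stimulus(x: int, population: str, grid: PadicGrid) -> float:
    """The connectome-run inputs: 3.5 on the ball 1 + p^2 Z_p for E,
    -30 everywhere for I, constant in time."""
    if population == "E":
        return float(BallPulse(3.5, center=1, radius_exponent=2)(grid, 0.0)[x])
    if population == "I":
        return -30.0
    raise ValueError(f"population must be 'E' or 'I', got {population!r}")
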