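"""Group convolution on G_l, the Wilson-Cowan vector field, and integration.

A locally constant function on Z_p at level l is a vector of p^l values, one
per leaf (a :class:`Field`).  Convolution against a kernel field is the cyclic
convolution of the two vectors scaled by the Haar weight p^-l,

    (w * phi)_k = p^-l sum_i w_{(k-i) mod p^l} phi_i,

which this module evaluates through length-p^l FFTs.  A general (not
translation-invariant) coupling is the Haar-weighted matrix-vector product
(phi -> p^-l K phi).  The coupled evolution

    tau dE/dt = -E + (1 - r_E E) . S_E(w_EE*E - w_EI*I + h_E)
    tau dI/dt = -I + (1 - r_I I) . S_I(w_IE*E - w_II*I + h_I)

is integrated with a fixed-step explicit scheme (classical RK4 by default;
forward Euler available for comparison).  No randomness anywhere: trajectories
are bit-reproducible.

The level-change operators tie the finite levels together: ``refine_embed``
re-expresses a level-l step function on a finer grid without changing it as a
function on Z_p, and ``coarse_project`` samples a fine field at the coarse
representatives; projecting a refined field returns the original exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
from scipy import fft as sp_fft

from .grid import PadicGrid
from .kernels import RadialExpKernel, Sigmoid

__all__ = [
    "Field",
    "ConvolutionCoupling",
    "MatrixCoupling",
    "WCModel",
    "Trajectory",
    "IntegrationError",
    "group_convolve",
    "integral_operator",
    "wc_rhs",
    "integrate",
    "coarse_project",
    "refine_embed",
    "as_coupling",
]

Stimulus = Callable[[PadicGrid, float], np.ndarray]


@dataclass
class Field:
    """A real vector indexed by G_l: the locally constant function
    sum_i values[i] Omega(p^l |x - i|_p)."""

    grid: PadicGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.size,):
            raise ValueError(
                f"field has {self.values.shape} values for grid of size {self.grid.size}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")

    @classmethod
    def zeros(cls, grid: PadicGrid) -> "Field":
        return cls(grid, np.zeros(grid.size))

    @classmethod
    def constant(cls, grid: PadicGrid, c: float) -> "Field":
        return cls(grid, np.full(grid.size, float(c)))


class ConvolutionCoupling:
    """Cyclic-convolution coupling against a kernel vector (FFT fast path,
    kernel transform precomputed once)."""

    def __init__(self, grid: PadicGrid, kernel_values: np.ndarray):
        kernel_values = np.asarray(kernel_values, dtype=float)
        if kernel_values.shape != (grid.size,):
            raise ValueError("kernel vector length must equal grid size")
        self.grid = grid
        self.kernel_values = kernel_values
        self._rfft = sp_fft.rfft(kernel_values)

    def apply(self, phi: np.ndarray) -> np.ndarray:
        out = sp_fft.irfft(self._rfft * sp_fft.rfft(phi), n=self.grid.size)
        return out * self.grid.haar_weight


class MatrixCoupling:
    """General integral-operator coupling phi -> p^-l K phi for a p^l x p^l
    kernel matrix K (e.g. a locally translation-invariant connectome kernel)."""

    def __init__(self, grid: PadicGrid, matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (grid.size, grid.size):
            raise ValueError(
                f"kernel matrix shape {matrix.shape} does not match grid size {grid.size}"
            )
        self.grid = grid
        self.matrix = matrix

    def apply(self, phi: np.ndarray) -> np.ndarray:
        return (self.matrix @ phi) * self.grid.haar_weight


Coupling = Union[ConvolutionCoupling, MatrixCoupling]


def as_coupling(obj, grid: PadicGrid) -> Coupling:
    """Coerce a kernel description to a coupling operator on ``grid``.

    Accepts a RadialExpKernel (sampled at the representatives), a kernel
    vector, a square kernel matrix, an object with a ``values`` matrix
    attribute (connectome kernel approximation), or a ready coupling.
    """
    if isinstance(obj, (ConvolutionCoupling, MatrixCoupling)):
        if obj.grid != grid:
            raise ValueError("coupling grid mismatch")
        return obj
    if isinstance(obj, RadialExpKernel):
        return ConvolutionCoupling(grid, obj.discretize(grid))
    values = getattr(obj, "values", obj)
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        return ConvolutionCoupling(grid, values)
    if values.ndim == 2:
        return MatrixCoupling(grid, values)
    raise TypeError(f"cannot interpret {type(obj).__name__} as a coupling")


def group_convolve(w: Field, phi: Field) -> Field:
    """Haar-weighted cyclic convolution of two fields on the same grid."""
    if w.grid != phi.grid:
        raise ValueError("fields live on different grids")
    return Field(w.grid, ConvolutionCoupling(w.grid, w.values).apply(phi.values))


def integral_operator(K, phi: Field) -> Field:
    """Haar-weighted matrix-vector product against a kernel matrix."""
    values = np.asarray(getattr(K, "values", K), dtype=float)
    return Field(phi.grid, MatrixCoupling(phi.grid, values).apply(phi.values))


@dataclass
class WCModel:
    """All dynamical parameters of one experiment.

    Couplings may be given as RadialExpKernel, kernel vector, kernel matrix or
    coupling operator; they are coerced once at construction.  Stimuli are
    callables ``h(grid, t) -> array`` (None = no input).
    """

    grid: PadicGrid
    tau: float
    r_e: float
    r_i: float
    w_ee: object
    w_ei: object
    w_ie: object
    w_ii: object
    s_e: Sigmoid
    s_i: Sigmoid
    stimulus_e: Optional[Stimulus] = None
    stimulus_i: Optional[Stimulus] = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"time constant tau must be > 0, got {self.tau}")
        self.w_ee = as_coupling(self.w_ee, self.grid)
        self.w_ei = as_coupling(self.w_ei, self.grid)
        self.w_ie = as_coupling(self.w_ie, self.grid)
        self.w_ii = as_coupling(self.w_ii, self.grid)

    def rhs(self, e: np.ndarray, i: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Time derivatives (dE/dt, dI/dt), including the 1/tau factor."""
        z_e = self.w_ee.apply(e) - self.w_ei.apply(i)
        z_i = self.w_ie.apply(e) - self.w_ii.apply(i)
        if self.stimulus_e is not None:
            z_e = z_e + self.stimulus_e(self.grid, t)
        if self.stimulus_i is not None:
            z_i = z_i + self.stimulus_i(self.grid, t)
        de = (-e + (1.0 - self.r_e * e) * self.s_e(z_e)) / self.tau
        di = (-i + (1.0 - self.r_i * i) * self.s_i(z_i)) / self.tau
        return de, di


def wc_rhs(E: Field, I: Field, t: float, model: WCModel) -> tuple[Field, Field]:
    if E.grid != model.grid or I.grid != model.grid:
        raise ValueError("state fields must live on the model grid")
    de, di = model.rhs(E.values, I.values, t)
    if not (np.all(np.isfinite(de)) and np.all(np.isfinite(di))):
        raise IntegrationError(t, "non-finite derivative")
    return Field(model.grid, de), Field(model.grid, di)


class IntegrationError(RuntimeError):
    def __init__(self, t: float, message: str = "non-finite state"):
        super().__init__(f"{message} at t = {t:g}")
        self.t = t


@dataclass
class Trajectory:
    """Uniform time grid plus the E and I fields at each step
    (rows of ``E``/``I`` are time points, columns are grid sites)."""

    grid: PadicGrid
    times: np.ndarray
    E: np.ndarray
    I: np.ndarray

    def __post_init__(self) -> None:
        nt = len(self.times)
        if self.E.shape != (nt, self.grid.size) or self.I.shape != (nt, self.grid.size):
            raise ValueError("history shapes do not match times/grid")
        if nt > 1:
            dts = np.diff(self.times)
            if np.any(np.abs(dts - dts[0]) > 1e-12):
                raise ValueError("time grid is not uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def e_field(self, step: int) -> Field:
        return Field(self.grid, self.E[step])

    def i_field(self, step: int) -> Field:
        return Field(self.grid, self.I[step])


def integrate(
    model: WCModel,
    E0: Field,
    I0: Field,
    t_end: float,
    dt: float,
    method: str = "rk4",
) -> Trajectory:
    """Fixed-step explicit integration from (E0, I0), recording every step."""
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if t_end < dt:
        raise ValueError(f"t_end must be >= dt, got {t_end}")
    if method not in ("rk4", "euler"):
        raise ValueError(f"method must be 'rk4' or 'euler', got {method!r}")
    if E0.grid != model.grid or I0.grid != model.grid:
        raise ValueError("initial fields must live on the model grid")

    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    n = model.grid.size
    E = np.empty((n_steps + 1, n))
    I = np.empty((n_steps + 1, n))
    E[0], I[0] = E0.values, I0.values

    e, i = E0.values.copy(), I0.values.copy()
    rhs = model.rhs
    for step in range(n_steps):
        t = times[step]
        if method == "euler":
            de, di = rhs(e, i, t)
            e = e + dt * de
            i = i + dt * di
        else:
            k1e, k1i = rhs(e, i, t)
            k2e, k2i = rhs(e + 0.5 * dt * k1e, i + 0.5 * dt * k1i, t + 0.5 * dt)
            k3e, k3i = rhs(e + 0.5 * dt * k2e, i + 0.5 * dt * k2i, t + 0.5 * dt)
            k4e, k4i = rhs(e + dt * k3e, i + dt * k3i, t + dt)
            e = e + (dt / 6.0) * (k1e + 2.0 * k2e + 2.0 * k3e + k4e)
            i = i + (dt / 6.0) * (k1i + 2.0 * k2i + 2.0 * k3i + k4i)
        if not (np.all(np.isfinite(e)) and np.all(np.isfinite(i))):
            raise IntegrationError(times[step + 1])
        E[step + 1], I[step + 1] = e, i
    return Trajectory(model.grid, times, E, I)


def coarse_project(f: Field, l: int) -> Field:
    """Sample a level-l' field at the coarse representatives 0..p^l - 1."""
    if l >= f.grid.l:
        raise ValueError(f"target level {l} must be below {f.grid.l}")
    coarse = PadicGrid(f.grid.p, l)
    return Field(coarse, f.values[: coarse.size].copy())


def refine_embed(f: Field, l_fine: int) -> Field:
    """Re-express a level-l step function at a finer level l' > l; the fine
    value at index j is the coarse value at j mod p^l."""
    if l_fine <= f.grid.l:
        raise ValueError(f"target level {l_fine} must exceed {f.grid.l}")
    fine = PadicGrid(f.grid.p, l_fine)
    reps = np.arange(fine.size) % f.grid.size
    return Field(fine, f.values[reps])
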