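"""End-to-end experiment presets, runners, exporters and summary metrics.

The presets reproduce the published experiment settings of the hierarchical
Wilson-Cowan study: tau = 10, r_E = r_I = 1, p = 3, l = 6, kernels
(b_EE, sigma_EE) = (1.5, 4), (b_EI, sigma_EI) = (b_IE, sigma_IE) = (1.35, 6),
(b_II, sigma_II) = (1.8, 3), sigmoids (v_E, theta_E) = (2.75, 9) and
(v_I, theta_I) = (0.3, 17), integrated at dt = 0.05.

* ``sim1_pulse``      — brief localized pulse (Q = 0, delta = 5, t_end = 100)
* ``sim1_maintained`` — maintained stimulus   (Q = 0, delta = 100, t_end = 200)
* ``sim1_inhib``      — maintained stimulus with an inhibitory input
                        (Q = -30, delta = 100, t_end = 100)
* ``hysteresis_open``   — twin stimuli separating              (t_end = 60)
* ``hysteresis_return`` — twin stimuli separating then merging (t_end = 60)
* ``connectome_run``  — EE coupling replaced by a resolution-r connectome
                        kernel on p = 2, l = 6 (t_end = 150)

Initial conditions are the resting state E = I = 0 unless overridden.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import connectome as conn
from .dynamics import Field, Trajectory, WCModel, integrate
from .grid import PadicGrid
from .kernels import RadialExpKernel, Sigmoid
from .stimuli import BallPulse, HysteresisStimulus

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "PRESETS",
    "build_model",
    "run_experiment",
    "export_heatmap",
    "count_spatial_peaks",
    "count_temporal_oscillations",
]

PRESETS = (
    "sim1_pulse",
    "sim1_maintained",
    "sim1_inhib",
    "hysteresis_open",
    "hysteresis_return",
    "connectome_run",
)

_SIM1 = dict(
    tau=10.0,
    r_e=1.0,
    r_i=1.0,
    b_ee=1.5,
    sigma_ee=4.0,
    b_ei=1.35,
    sigma_ei=6.0,
    b_ie=1.35,
    sigma_ie=6.0,
    b_ii=1.8,
    sigma_ii=3.0,
    v_e=2.75,
    theta_e=9.0,
    v_i=0.3,
    theta_i=17.0,
    dt=0.05,
)


@dataclass
class ExperimentConfig:
    """Everything needed to run one experiment deterministically."""

    name: str = "custom"
    p: int = 3
    l: int = 6
    tau: float = 10.0
    r_e: float = 1.0
    r_i: float = 1.0
    b_ee: float = 1.5
    sigma_ee: float = 4.0
    b_ei: float = 1.35
    sigma_ei: float = 6.0
    b_ie: float = 1.35
    sigma_ie: float = 6.0
    b_ii: float = 1.8
    sigma_ii: float = 3.0
    v_e: float = 2.75
    theta_e: float = 9.0
    v_i: float = 0.3
    theta_i: float = 17.0
    # stimulus
    stimulus_kind: str = "none"  # none | pulse | hysteresis | constant
    amplitude: float = 3.7
    center: int = 4
    radius_exponent: int = 2
    q_level: float = 0.0
    q_center: int = 4
    q_radius_exponent: int = 0
    delta: Optional[float] = None  # pulse window; None = never switched off
    hysteresis_mode: str = "open"
    # time grid
    t_end: float = 100.0
    dt: float = 0.05
    method: str = "rk4"
    # connectome options
    matrix_path: Optional[str] = None
    resolution: Optional[int] = None
    synth_decay: float = 2.0
    synth_noise_sd: float = 0.15
    synth_seed: int = 1
    # output
    ordering: str = "monna"

    @classmethod
    def preset(cls, name: str, **overrides) -> "ExperimentConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
        cfg = dict(_SIM1, name=name, p=3, l=6)
        if name == "sim1_pulse":
            cfg.update(stimulus_kind="pulse", q_level=0.0, delta=5.0, t_end=100.0)
        elif name == "sim1_maintained":
            cfg.update(stimulus_kind="pulse", q_level=0.0, delta=100.0, t_end=200.0)
        elif name == "sim1_inhib":
            cfg.update(stimulus_kind="pulse", q_level=-30.0, delta=100.0, t_end=100.0)
        elif name == "hysteresis_open":
            cfg.update(stimulus_kind="hysteresis", hysteresis_mode="open", t_end=60.0)
        elif name == "hysteresis_return":
            cfg.update(stimulus_kind="hysteresis", hysteresis_mode="return", t_end=60.0)
        elif name == "connectome_run":
            cfg.update(
                p=2,
                l=6,
                stimulus_kind="constant",
                amplitude=3.5,
                center=1,
                radius_exponent=2,
                q_level=-30.0,
                q_radius_exponent=0,
                t_end=150.0,
                resolution=0,
            )
        cfg.update(overrides)
        return cls(**cfg)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        preset = data.pop("preset", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if preset is not None:
            return cls.preset(preset, **data)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def build_model(config: ExperimentConfig) -> WCModel:
    grid = PadicGrid(config.p, config.l)
    couplings = dict(
        w_ee=RadialExpKernel(config.b_ee, config.sigma_ee),
        w_ei=RadialExpKernel(config.b_ei, config.sigma_ei),
        w_ie=RadialExpKernel(config.b_ie, config.sigma_ie),
        w_ii=RadialExpKernel(config.b_ii, config.sigma_ii),
    )

    stimulus_e = stimulus_i = None
    if config.stimulus_kind == "pulse":
        stimulus_e = BallPulse(
            config.amplitude, config.center, config.radius_exponent, config.delta
        )
        if config.q_level != 0.0:
            stimulus_i = BallPulse(
                config.q_level, config.q_center, config.q_radius_exponent, config.delta
            )
    elif config.stimulus_kind == "hysteresis":
        stimulus_e = HysteresisStimulus(config.hysteresis_mode)
    elif config.stimulus_kind == "constant":
        stimulus_e = BallPulse(config.amplitude, config.center, config.radius_exponent)
        if config.q_level != 0.0:
            stimulus_i = BallPulse(config.q_level, config.q_center, config.q_radius_exponent)
    elif config.stimulus_kind != "none":
        raise ValueError(f"unknown stimulus kind {config.stimulus_kind!r}")

    if config.name == "connectome_run" or config.resolution is not None:
        if config.matrix_path is not None:
            A = conn.read_matrix(config.matrix_path)
        else:
            A = conn.synthetic_hierarchical_matrix(
                config.p,
                config.l,
                decay=config.synth_decay,
                noise_sd=config.synth_noise_sd,
                seed=config.synth_seed,
            )
        padded, k = conn.pad_matrix(A, config.p)
        if k > config.l:
            raise ValueError(f"matrix needs k={k} but the grid has level l={config.l}")
        if k < config.l:
            # embed the p^k x p^k matrix into the p^l x p^l grid by padding
            full = np.zeros((grid.size, grid.size))
            full[: padded.shape[0], : padded.shape[1]] = padded
            padded, k = full, config.l
        r = config.resolution if config.resolution is not None else k
        couplings["w_ee"] = conn.local_circulant_average(padded, config.p, k, r)

    return WCModel(
        grid=grid,
        tau=config.tau,
        r_e=config.r_e,
        r_i=config.r_i,
        s_e=Sigmoid(config.v_e, config.theta_e),
        s_i=Sigmoid(config.v_i, config.theta_i),
        stimulus_e=stimulus_e,
        stimulus_i=stimulus_i,
        **couplings,
    )


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    model: WCModel
    trajectory: Trajectory
    metrics: dict = field(default_factory=dict)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run one experiment from the resting state and compute summary metrics."""
    model = build_model(config)
    grid = model.grid
    traj = integrate(
        model, Field.zeros(grid), Field.zeros(grid), config.t_end, config.dt, config.method
    )

    metrics = {
        "max_abs_E": float(np.max(np.abs(traj.E))),
        "max_abs_I": float(np.max(np.abs(traj.I))),
        "final_spatial_peaks_E": count_spatial_peaks(traj.e_field(-1), config.ordering),
        "temporal_oscillations_at_center": count_temporal_oscillations(
            traj, config.center % grid.size
        ),
    }
    if config.r_e == 0.0 and config.r_i == 0.0:
        # sup-norm a priori bound for the refractory-free (coupled perceptron)
        # regime: |E| <= |E0| + tau sup|S_E|, and likewise for I
        bound_e = float(np.max(np.abs(traj.E[0]))) + config.tau * model.s_e.sup_abs
        bound_i = float(np.max(np.abs(traj.I[0]))) + config.tau * model.s_i.sup_abs
        metrics["bound_E"] = bound_e
        metrics["bound_I"] = bound_i
        metrics["bound_satisfied"] = bool(
            metrics["max_abs_E"] <= bound_e + 1e-6 and metrics["max_abs_I"] <= bound_i + 1e-6
        )
    return ExperimentResult(config=config, model=model, trajectory=traj, metrics=metrics)


def _ordering_permutation(grid: PadicGrid, ordering: str) -> np.ndarray:
    if ordering == "monna":
        return grid.tree_order
    if ordering == "integer":
        return np.arange(grid.size)
    raise ValueError(f"ordering must be 'monna' or 'integer', got {ordering!r}")


def export_heatmap(
    traj: Trajectory,
    ordering: str,
    path,
    which: str = "E",
    image: bool = False,
) -> list[Path]:
    """Write the space x time matrix (rows = sites in the chosen ordering,
    columns = time points) as tab-delimited text plus a JSON sidecar with the
    grid/time metadata; optionally also a raster image.  The text output is
    byte-deterministic."""
    if which not in ("E", "I"):
        raise ValueError(f"which must be 'E' or 'I', got {which!r}")
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    path = Path(path)
    perm = _ordering_permutation(traj.grid, ordering)
    data = (traj.E if which == "E" else traj.I).T[perm]

    with open(path, "w", encoding="utf-8") as fh:
        for row in data:
            fh.write("\t".join(f"{x:.15g}" for x in row) + "\n")
    meta = {
        "p": traj.grid.p,
        "l": traj.grid.l,
        "dt": traj.dt,
        "t_end": float(traj.times[-1]),
        "ordering": ordering,
        "population": which,
        "rows": int(data.shape[0]),
        "columns": int(data.shape[1]),
    }
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    written = [path, meta_path]
    if image:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        img_path = path.with_suffix(".png")
        fig, ax = plt.subplots(figsize=(8, 4))
        im = ax.imshow(data, aspect="auto", origin="lower", cmap="hot",
                       extent=(0, meta["t_end"], 0, 1))
        ax.set_xlabel("time")
        ax.set_ylabel("position (Monna coordinate)" if ordering == "monna" else "site index")
        fig.colorbar(im, ax=ax, label=which)
        fig.savefig(img_path, dpi=150)
        plt.close(fig)
        written.append(img_path)
    return written


def _count_peaks(values: np.ndarray, include_endpoints: bool) -> int:
    """Count local maxima above 10% of the maximum.

    Runs of exactly equal consecutive values are treated as one candidate
    (fields on G_l are locally constant on balls, so plateaus are the rule,
    not the exception); a run is a peak when its value is strictly greater
    than both neighboring runs (endpoint runs, when counted, must exceed
    their single neighbor).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        return 0
    vmax = values.max()
    if vmax <= 0:
        return 0
    threshold = 0.1 * vmax
    # compress plateaus to single run values
    keep = np.ones(len(values), dtype=bool)
    keep[1:] = values[1:] != values[:-1]
    runs = values[keep]
    if len(runs) == 1:
        return 0
    count = 0
    if len(runs) > 2:
        interior = (runs[1:-1] > runs[:-2]) & (runs[1:-1] > runs[2:])
        count += int(np.sum(interior & (runs[1:-1] > threshold)))
    if include_endpoints:
        if runs[0] > runs[1] and runs[0] > threshold:
            count += 1
        if runs[-1] > runs[-2] and runs[-1] > threshold:
            count += 1
    return count


def count_spatial_peaks(field: Field, ordering: str = "monna") -> int:
    """Local maxima of the field in the given spatial ordering, above 10% of
    its maximum; endpoints count when greater than their neighbor."""
    perm = _ordering_permutation(field.grid, ordering)
    return _count_peaks(field.values[perm], include_endpoints=True)


def count_temporal_oscillations(traj: Trajectory, site: int) -> int:
    """Interior local maxima of E(site, t) above 10% of its maximum."""
    site = traj.grid._check_index(site)
    return _count_peaks(traj.E[:, site], include_endpoints=False)
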