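"""Rigid-body trajectory integration above a chosen surface.

The squirmer state (X, n) evolves by dX/dt = U, dn/dt = Omega x n, with
(U, Omega) from an instantaneous mobility solve.  In the discretised-wall
mode, the wall patch is re-centred under the squirmer at every
right-hand-side evaluation, so the truncation error is independent of the
horizontal position.  Integration uses adaptive Runge-Kutta 4(5); the
orientation is renormalised after every accepted step.  Runs terminate at
``max_time``, when the surface clearance drops to ``stop_clearance``
(short-range surface physics is outside the model, so the simulation
stops just before it would matter), when the swimmer escapes upwards, or
when a user-supplied settling predicate fires.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
from scipy.integrate import RK45
from scipy.signal import find_peaks

from .errors import AnalysisError, IntegrationError, ParameterError
from .geometry import Topography, WallPatchSpec, min_clearance
from .kernels import KernelSpec
from .solver import MobilityProblem, solve_mobility
from .squirmer import SquirmerState, orientation_angles

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "rhs",
    "simulate",
    "oscillation_metrics",
]


@dataclass
class SimulationConfig:
    """Everything needed to integrate one trajectory.

    ``wall`` selects the wall representation: a :class:`WallPatchSpec`
    for an explicitly discretised (optionally rescaled) patch, the string
    ``"blakelet"`` for the image-system flat wall, or ``"free"`` for
    unbounded fluid.  ``stop_clearance`` is the surface gap (in radii) at
    which a run is stopped; the default 0.02 sits well above the
    regularisation scale (20 eps) but below every steady swimming gap
    seen in practice, including the ~0.05 crest clearance of the
    short-wavelength topography orbits, which a larger threshold would
    cut off during their initial transient.
    """

    topography: Topography = field(default_factory=lambda: Topography("flat", 0.0, 1.0))
    kernel: KernelSpec = field(default_factory=KernelSpec)
    wall: Union[WallPatchSpec, str] = "blakelet"
    n_s: int = 4
    N_s: int = 18
    rescale: bool = True
    rtol: float = 1e-6
    atol: float = 1e-8
    max_time: float = 30.0
    stop_clearance: float = 0.02
    escape_height: float = 8.0
    output_stride: float = 0.1
    #: a run is declared in contact when the step size has collapsed
    #: below stall_step while the clearance sits below stall_clearance:
    #: trial steps are then penetrating a gap the wall mesh cannot
    #: resolve, and the integrator cannot advance
    stall_step: float = 1e-3
    stall_clearance: float = 0.06

    def __post_init__(self):
        if self.max_time <= 0:
            raise ParameterError("max_time must be > 0")
        if self.stop_clearance < 0:
            raise ParameterError("stop_clearance must be >= 0")
        if isinstance(self.wall, str) and self.wall not in ("blakelet", "free"):
            raise ParameterError("wall must be a WallPatchSpec, 'blakelet' or 'free'")
        if self.wall == "blakelet" and self.kernel.kind != "reg_blakelet":
            self.kernel = KernelSpec(
                "reg_blakelet", self.kernel.epsilon, self.kernel.wall_plane_height
            )
        if (self.wall == "free" or isinstance(self.wall, WallPatchSpec)) and (
            self.kernel.kind != "reg_stokeslet"
        ):
            raise ParameterError("discretised-wall and free runs use the reg_stokeslet kernel")


@dataclass
class Trajectory:
    """Sampled time series of one run plus the termination record."""

    times: np.ndarray
    positions: np.ndarray       # (M, 3)
    orientations: np.ndarray    # (M, 3), unit rows
    clearances: np.ndarray
    termination: str            # max_time | contact_stop | escaped | settled
    termination_time: float
    config: Optional[SimulationConfig] = None

    @property
    def z_series(self) -> np.ndarray:
        return self.positions[:, 2]

    @property
    def theta_series(self) -> np.ndarray:
        return np.arcsin(np.clip(self.orientations[:, 2], -1.0, 1.0))

    @property
    def phi_series(self) -> np.ndarray:
        return np.arctan2(self.orientations[:, 0], self.orientations[:, 1])

    @property
    def final_state(self) -> SquirmerState:
        return SquirmerState(
            centre=self.positions[-1],
            orientation=self.orientations[-1],
        )

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {
                "t": self.times,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "n_x": self.orientations[:, 0],
                "n_y": self.orientations[:, 1],
                "n_z": self.orientations[:, 2],
                "theta": self.theta_series,
                "phi": self.phi_series,
                "clearance": self.clearances,
            }
        )
        df.to_csv(path, index=False)

    def metadata(self) -> dict:
        cfg = self.config
        meta = {
            "termination": self.termination,
            "termination_time": self.termination_time,
            "samples": int(len(self.times)),
        }
        if cfg is not None:
            wall = cfg.wall
            meta["config"] = {
                "topography": {
                    "kind": cfg.topography.kind,
                    "amplitude": cfg.topography.amplitude,
                    "wave_parameter": cfg.topography.wave_parameter,
                },
                "kernel": {"kind": cfg.kernel.kind, "epsilon": cfg.kernel.epsilon},
                "wall": (
                    wall
                    if isinstance(wall, str)
                    else {
                        "side_length": wall.side_length,
                        "coarse_per_side": wall.coarse_per_side,
                        "fine_per_side": wall.fine_per_side,
                    }
                ),
                "n_s": cfg.n_s,
                "N_s": cfg.N_s,
                "rescale": cfg.rescale,
                "rtol": cfg.rtol,
                "atol": cfg.atol,
                "max_time": cfg.max_time,
                "stop_clearance": cfg.stop_clearance,
            }
        return meta

    def write_metadata(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2)


def _build_problem(state: SquirmerState, config: SimulationConfig) -> MobilityProblem:
    if isinstance(config.wall, WallPatchSpec):
        return MobilityProblem.build(
            state,
            config.kernel,
            config.n_s,
            config.N_s,
            wall_spec=config.wall,
            topography=config.topography,
            rescale=config.rescale,
        )
    return MobilityProblem.build(state, config.kernel, config.n_s, config.N_s)


def rhs(state: SquirmerState, config: SimulationConfig) -> tuple:
    """(dX/dt, dn/dt) from one mobility solve at the current state."""
    solution = solve_mobility(_build_problem(state, config))
    return solution.U, np.cross(solution.Omega, state.orientation)


def _clearance(centre, config: SimulationConfig) -> float:
    if config.wall == "free":
        return np.inf
    return min_clearance(centre, config.topography)


def simulate(
    state0: SquirmerState,
    config: SimulationConfig,
    stop_condition: Optional[Callable[[np.ndarray, np.ndarray], bool]] = None,
) -> Trajectory:
    """Integrate a trajectory from ``state0``.

    ``stop_condition`` receives the accepted-step time and height arrays
    and may end the run early (termination ``settled``); it is how the
    flat-wall validation detects a steady swimming height.
    """
    c0 = _clearance(state0.centre, config)
    if c0 <= config.stop_clearance:
        raise ParameterError("initial clearance must exceed stop_clearance")

    B1, beta = state0.B1, state0.beta

    def fun(t, y):
        state = SquirmerState(centre=y[:3], orientation=y[3:], B1=B1, beta=beta)
        U, dn = rhs(state, config)
        return np.concatenate([U, dn])

    y0 = np.concatenate([state0.centre, state0.orientation])
    stepper = RK45(fun, 0.0, y0, config.max_time, rtol=config.rtol, atol=config.atol)

    step_times = [0.0]
    step_z = [float(state0.centre[2])]
    samples = [(0.0, state0.centre.copy(), state0.orientation.copy(), c0)]
    next_sample = config.output_stride
    termination = "max_time"
    t_end = config.max_time

    while stepper.status == "running":
        try:
            message = stepper.step()
        except Exception as exc:  # pragma: no cover - scipy internal failure
            raise IntegrationError(str(exc), last_state=stepper.y, last_time=stepper.t)
        if stepper.status == "failed":
            raise IntegrationError(
                f"step-size underflow at t={stepper.t:.6g}: {message}",
                last_state=stepper.y,
                last_time=stepper.t,
            )
        stepper.y[3:] /= np.linalg.norm(stepper.y[3:])
        t = stepper.t
        step_times.append(t)
        step_z.append(float(stepper.y[2]))

        # stride sampling via the dense interpolant of the accepted step
        dense = stepper.dense_output()
        while next_sample <= t:
            ys = dense(next_sample)
            nvec = ys[3:] / np.linalg.norm(ys[3:])
            samples.append(
                (next_sample, ys[:3].copy(), nvec, _clearance(ys[:3], config))
            )
            next_sample += config.output_stride

        clearance = _clearance(stepper.y[:3], config)
        if clearance <= config.stop_clearance:
            termination, t_end = "contact_stop", t
            break
        if (
            clearance <= config.stall_clearance
            and stepper.step_size is not None
            and stepper.step_size < config.stall_step
        ):
            termination, t_end = "contact_stop", t
            break
        if stepper.y[2] >= config.escape_height:
            termination, t_end = "escaped", t
            break
        if stop_condition is not None and stop_condition(
            np.asarray(step_times), np.asarray(step_z)
        ):
            termination, t_end = "settled", t
            break
    else:
        t_end = stepper.t

    # always include the final accepted state
    if samples[-1][0] < step_times[-1]:
        yf = stepper.y
        samples.append(
            (step_times[-1], yf[:3].copy(), yf[3:] / np.linalg.norm(yf[3:]),
             _clearance(yf[:3], config))
        )

    times = np.array([s[0] for s in samples])
    return Trajectory(
        times=times,
        positions=np.array([s[1] for s in samples]),
        orientations=np.array([s[2] for s in samples]),
        clearances=np.array([s[3] for s in samples]),
        termination=termination,
        termination_time=float(t_end),
        config=config,
    )


def oscillation_metrics(traj: Trajectory, window: float) -> tuple:
    """(z_amplitude, z_wavelength) over the final ``window`` time units.

    Amplitude is half the peak-to-peak z excursion.  The wavelength is
    the mean spacing, in horizontal arc length, between successive peaks
    of z; it is ``nan`` when z is essentially constant or fewer than two
    peaks fall inside the window.
    """
    t_end = traj.times[-1]
    if window > t_end - traj.times[0]:
        raise AnalysisError("analysis window longer than the trajectory")
    mask = traj.times >= t_end - window
    z = traj.z_series[mask]
    xy = traj.positions[mask, :2]
    amplitude = 0.5 * (z.max() - z.min())
    if amplitude < 1e-9:
        return float(amplitude), float("nan")

    # horizontal arc length parametrisation
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] < 1e-9:
        return float(amplitude), float("nan")
    s_uniform = np.linspace(0.0, s[-1], 512)
    z_uniform = np.interp(s_uniform, s, z)
    peaks, _ = find_peaks(z_uniform, prominence=0.2 * amplitude)
    if len(peaks) < 2:
        return float(amplitude), float("nan")
    spacing = np.diff(s_uniform[peaks]).mean()
    return float(amplitude), float(spacing)
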