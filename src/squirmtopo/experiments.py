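"""Reproduction scenarios: speed table, flat-wall validation, topography sweeps.

Scenario defaults follow the reference study conditions: B1 = 3/2 (unit
free-space speed), puller strength beta = 7, topography amplitude
A = 0.1, initial centre (0, 0, 1.2) with attack angle theta = -0.17 pi,
and in-plane headings phi swept over {0, 0.05 pi, ..., 0.5 pi}.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .dynamics import SimulationConfig, Trajectory, oscillation_metrics, simulate
from .geometry import Topography, WallPatchSpec
from .kernels import KernelSpec
from .solver import MobilityProblem, solve_mobility
from .squirmer import SquirmerState

__all__ = [
    "Scenario",
    "SCENARIOS",
    "run_speed_table",
    "run_flat_wall_validation",
    "run_topography_scenario",
    "TABLE_GRID",
    "DEFAULTS",
]

logger = logging.getLogger(__name__)

DEFAULTS = {
    "B1": 1.5,
    "beta": 7.0,
    "amplitude": 0.1,
    "z0": 1.2,
    "theta0": -0.17 * np.pi,
    "epsilon": 1e-3,
    "n_s": 4,
    "N_s": 18,
}

#: (n_s, N_s) grid of the free-space speed validation table
TABLE_GRID = [
    (4, 10), (4, 12), (4, 14), (4, 16), (4, 18),
    (5, 10), (5, 12), (5, 14), (5, 16),
]

PHI_SWEEP = tuple(np.linspace(0.0, 0.5, 11) * np.pi)


def run_speed_table(
    epsilon: float = 1e-3,
    grid=None,
    B1: float = 1.5,
    beta: float = 0.0,
) -> pd.DataFrame:
    """Free-space swimming speed for each (n_s, N_s) refinement pair.

    One mobility solve per entry; the exact speed is (2/3) B1, so the
    relative error column measures pure discretisation error.
    """
    grid = list(grid) if grid is not None else list(TABLE_GRID)
    if not grid:
        raise ValueError("refinement grid must be non-empty")
    exact = (2.0 / 3.0) * abs(B1)
    rows = []
    for n_s, N_s in grid:
        state = SquirmerState(
            centre=np.zeros(3), orientation=[0.0, 0.0, 1.0], B1=B1, beta=beta
        )
        tic = time.perf_counter()
        sol = solve_mobility(
            MobilityProblem.build(state, KernelSpec("reg_stokeslet", epsilon), n_s, N_s)
        )
        speed = float(np.linalg.norm(sol.U))
        logger.info(
            "speed table n_s=%d N_s=%d |U|=%.6f (%.2fs)",
            n_s, N_s, speed, time.perf_counter() - tic,
        )
        rows.append(
            {
                "epsilon": epsilon,
                "n_s": n_s,
                "N_s": N_s,
                "speed": speed,
                "rel_error": abs(speed - exact) / exact if exact else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _settled(times: np.ndarray, z: np.ndarray, tol: float, window: float = 1.0) -> bool:
    """True when the height drift rate over the trailing window is below
    ``tol``: the total z excursion across one window of unit duration is
    less than tol * window."""
    if times[-1] < 2.0 * window or len(times) < 4:
        return False
    # near the fixed point accepted steps can exceed the window; widen to
    # at least three points (a longer span only makes the check stricter)
    i0 = min(np.searchsorted(times, times[-1] - window), len(times) - 3)
    zw = z[i0:]
    return bool(zw.max() - zw.min() < tol * window)


def run_flat_wall_validation(
    mode: str = "blakelet",
    beta: float = 7.0,
    z0: float = 1.15,
    theta0: float = -0.17 * np.pi,
    settle_tol: float = 1e-4,
    max_time: float = 60.0,
    config: Optional[SimulationConfig] = None,
) -> dict:
    """Integrate above a flat wall until the swimming height settles.

    Starts from (0, 0, z0) pitched towards the wall and reports the
    settled height and pitch (means over the final unit-time window), a
    convergence flag, and the trajectory.  ``mode`` is ``"blakelet"`` or
    ``"patch"`` (explicit rescaled flat wall).
    """
    if config is None:
        if mode == "blakelet":
            config = SimulationConfig(
                topography=Topography("flat", 0.0, 1.0),
                kernel=KernelSpec("reg_blakelet", DEFAULTS["epsilon"]),
                wall="blakelet",
                max_time=max_time,
            )
        elif mode == "patch":
            config = SimulationConfig(
                topography=Topography("flat", 0.0, 1.0),
                kernel=KernelSpec("reg_stokeslet", DEFAULTS["epsilon"]),
                wall=WallPatchSpec(),
                max_time=max_time,
            )
        else:
            raise ValueError("mode must be 'blakelet' or 'patch'")
    state0 = SquirmerState.from_angles(
        [0.0, 0.0, z0], theta0, 0.5 * np.pi, B1=DEFAULTS["B1"], beta=beta
    )
    traj = simulate(
        state0, config, stop_condition=lambda t, z: _settled(t, z, settle_tol)
    )
    i0 = np.searchsorted(traj.times, traj.times[-1] - 1.0)
    return {
        "settled_height": float(traj.z_series[i0:].mean()),
        "settled_theta": float(traj.theta_series[i0:].mean()),
        "converged": traj.termination == "settled",
        "termination": traj.termination,
        "trajectory": traj,
    }


@dataclass
class Scenario:
    """A named list of (run label, config, initial state) triples."""

    name: str
    runs: List[Tuple[str, SimulationConfig, SquirmerState]] = field(default_factory=list)


def _patch_config(
    topo: Topography,
    max_time: float,
    wall: Optional[WallPatchSpec] = None,
    n_s: Optional[int] = None,
    N_s: Optional[int] = None,
) -> SimulationConfig:
    return SimulationConfig(
        topography=topo,
        kernel=KernelSpec("reg_stokeslet", DEFAULTS["epsilon"]),
        wall=wall if wall is not None else WallPatchSpec(),
        n_s=n_s or DEFAULTS["n_s"],
        N_s=N_s or DEFAULTS["N_s"],
        max_time=max_time,
    )


def _state(phi: float, y0: float = 0.0, beta: Optional[float] = None) -> SquirmerState:
    return SquirmerState.from_angles(
        [0.0, y0, DEFAULTS["z0"]],
        DEFAULTS["theta0"],
        phi,
        B1=DEFAULTS["B1"],
        beta=DEFAULTS["beta"] if beta is None else beta,
    )


def _sin1d_wavelengths(max_time: float = 30.0, wall=None, **kw) -> Scenario:
    """Heading along the wave vector (phi = pi/2) over sin1d, lambda sweep."""
    runs = []
    for lam in (1.0, 2.0, 4.0, 8.0):
        topo = Topography("sin1d", DEFAULTS["amplitude"], lam)
        runs.append(
            (f"lam{lam:g}", _patch_config(topo, max_time, wall, **kw), _state(0.5 * np.pi))
        )
    return Scenario("sin1d_wavelengths", runs)


def _sin1d_orientation_sweep(max_time: float = 30.0, wall=None, **kw) -> Scenario:
    runs = []
    for lam in (1.0, 2.0, 4.0, 8.0):
        topo = Topography("sin1d", DEFAULTS["amplitude"], lam)
        for phi in PHI_SWEEP:
            runs.append(
                (
                    f"lam{lam:g}_phi{phi / np.pi:.2f}pi",
                    _patch_config(topo, max_time, wall, **kw),
                    _state(phi),
                )
            )
    return Scenario("sin1d_orientation_sweep", runs)


def _sin2d_orientation_sweep(max_time: float = 30.0, wall=None, **kw) -> Scenario:
    """Doubly periodic sinusoid; the first run of each wavelength starts at
    y = lambda/4 heading along -x, the rest sweep phi from y = 0."""
    runs = []
    for lam in (1.0, 2.0, 4.0, 8.0):
        topo = Topography("sin2d", DEFAULTS["amplitude"], lam)
        runs.append(
            (
                f"lam{lam:g}_ycrest",
                _patch_config(topo, max_time, wall, **kw),
                _state(0.5 * np.pi, y0=lam / 4.0),
            )
        )
        for phi in PHI_SWEEP:
            runs.append(
                (
                    f"lam{lam:g}_phi{phi / np.pi:.2f}pi",
                    _patch_config(topo, max_time, wall, **kw),
                    _state(phi),
                )
            )
    return Scenario("sin2d_orientation_sweep", runs)


def _peaks_orientation_sweep(max_time: float = 30.0, wall=None, **kw) -> Scenario:
    """Doubly periodic peaks; lambda parameter doubled so the inter-peak
    wavelength matches the other scenarios."""
    runs = []
    for lam in (2.0, 4.0, 8.0, 16.0):
        topo = Topography("peaks2d", DEFAULTS["amplitude"], lam)
        for phi in PHI_SWEEP:
            runs.append(
                (
                    f"lam{lam:g}_phi{phi / np.pi:.2f}pi",
                    _patch_config(topo, max_time, wall, **kw),
                    _state(phi),
                )
            )
    return Scenario("peaks_orientation_sweep", runs)


def _flat_wall(max_time: float = 40.0, wall=None, **kw) -> Scenario:
    topo = Topography("flat", 0.0, 1.0)
    runs = [
        (
            "blakelet",
            SimulationConfig(
                topography=topo,
                kernel=KernelSpec("reg_blakelet", DEFAULTS["epsilon"]),
                wall="blakelet",
                max_time=max_time,
            ),
            _state(0.5 * np.pi),
        ),
        ("patch_rescaled", _patch_config(topo, max_time, wall, **kw), _state(0.5 * np.pi)),
    ]
    return Scenario("flat_wall", runs)


def _speed_table_scenario(**kw) -> pd.DataFrame:
    return run_speed_table()


#: Registry of named reproduction scenarios.  ``speed_table`` is a table
#: computation; the others build trajectory sweeps.
SCENARIOS: Dict[str, Callable] = {
    "speed_table": _speed_table_scenario,
    "flat_wall": _flat_wall,
    "sin1d_wavelengths": _sin1d_wavelengths,
    "sin1d_orientation_sweep": _sin1d_orientation_sweep,
    "sin2d_orientation_sweep": _sin2d_orientation_sweep,
    "peaks_orientation_sweep": _peaks_orientation_sweep,
}


def _drift_angle(traj: Trajectory, window: float) -> float:
    """Unsigned angle between the final-window horizontal displacement and
    the horizontal projection of the final orientation."""
    mask = traj.times >= traj.times[-1] - window
    disp = traj.positions[mask][-1, :2] - traj.positions[mask][0, :2]
    head = traj.orientations[-1, :2]
    if np.linalg.norm(disp) < 1e-9 or np.linalg.norm(head) < 1e-9:
        return float("nan")
    cosang = np.dot(disp, head) / (np.linalg.norm(disp) * np.linalg.norm(head))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def run_topography_scenario(
    scenario: Scenario,
    outdir=None,
    window: float = 8.0,
) -> tuple:
    """Execute every run of a scenario; failures are logged, not fatal.

    Returns ``(trajectories, summary)`` where the summary table records
    per-run termination, final heading, drift angle and the steady
    z-oscillation amplitude and wavelength over the final window.
    """
    outpath = Path(outdir) if outdir is not None else None
    if outpath is not None:
        outpath.mkdir(parents=True, exist_ok=True)
    trajectories = {}
    rows = []
    for label, config, state0 in scenario.runs:
        tic = time.perf_counter()
        try:
            traj = simulate(state0, config)
        except Exception:
            logger.exception("run %s/%s failed", scenario.name, label)
            rows.append({"run": label, "termination": "error"})
            continue
        w = min(window, 0.5 * (traj.times[-1] - traj.times[0]))
        amp, wav = oscillation_metrics(traj, w) if w > 0 else (np.nan, np.nan)
        rows.append(
            {
                "run": label,
                "termination": traj.termination,
                "t_end": traj.termination_time,
                "final_phi": float(traj.phi_series[-1]),
                "drift_angle": _drift_angle(traj, w) if w > 0 else np.nan,
                "z_amplitude": amp,
                "z_wavelength": wav,
            }
        )
        trajectories[label] = traj
        logger.info(
            "run %s/%s: %s at t=%.2f (%.1fs wall)",
            scenario.name, label, traj.termination, traj.termination_time,
            time.perf_counter() - tic,
        )
        if outpath is not None:
            traj.to_csv(outpath / f"{scenario.name}_{label}.csv")
            traj.write_metadata(outpath / f"{scenario.name}_{label}.json")
    summary = pd.DataFrame(rows)
    if outpath is not None:
        summary.to_csv(outpath / f"{scenario.name}_summary.csv", index=False)
    return trajectories, summary
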