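"""Assembly and direct solution of the discretised mobility problem.

The single-layer boundary integral

    u_j(x) = -(1/8 pi) int_{S u W} S^eps_ij(x, y) f_i(y) dS(y)

is discretised on two node levels: tractions g[n] live on coarse nodes
x[n] (n = 1..N) while the kernel is integrated over fine nodes x[q]
(q = 1..Q), connected by the nearest-neighbour interpolation matrix
nu[q, n] (one per body).  Collocating the no-slip conditions at the N
coarse nodes — v = U + Omega x (x - X) + u_s on the swimmer, u = 0 on the
wall — and adding the six force/torque balance rows over the swimmer
surface yields a square dense system of size 3N + 6 in the tractions and
the rigid-body velocities (U, Omega), solved by LU with partial
pivoting.  The single-layer gauge freedom (f -> f + alpha * normal) does
not survive discretisation, so no extra constraint is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg
import scipy.sparse
from scipy.spatial.distance import cdist

from .errors import AssemblyError, SolverError
from .geometry import (
    NodeSet,
    Topography,
    WallPatchSpec,
    concatenate_node_sets,
    sphere_surface_nodes,
    wall_patch_nodes,
)
from ._assembly import stokeslet_aggregate
from .kernels import KernelSpec, kernel_matrix
from .squirmer import SquirmerState, slip_velocity

__all__ = [
    "MobilityProblem",
    "MobilitySolution",
    "nearest_neighbour_matrix",
    "assemble_mobility_system",
    "solve_mobility",
    "solve_resistance",
]


def _skew(v: np.ndarray) -> np.ndarray:
    """Matrix such that _skew(v) @ w = v x w."""
    return np.array(
        [
            [0.0, -v[2], v[1]],
            [v[2], 0.0, -v[0]],
            [-v[1], v[0], 0.0],
        ]
    )


@dataclass
class MobilityProblem:
    """Node sets, kernel and swimmer state for one instantaneous solve.

    Wall node sets are ``None`` in free space and in the Blakelet variant
    (where the plane wall lives inside the kernel instead).
    """

    state: SquirmerState
    kernel: KernelSpec
    swimmer_coarse: NodeSet
    swimmer_fine: NodeSet
    wall_coarse: Optional[NodeSet] = None
    wall_fine: Optional[NodeSet] = None

    @classmethod
    def build(
        cls,
        state: SquirmerState,
        kernel: KernelSpec,
        n_s: int = 4,
        N_s: int = 18,
        wall_spec: Optional[WallPatchSpec] = None,
        topography: Optional[Topography] = None,
        rescale: bool = True,
    ) -> "MobilityProblem":
        """Construct node sets for the current state.

        With a ``wall_spec`` the patch is centred under the squirmer and
        lifted onto ``topography`` (flat if omitted).
        """
        sc = sphere_surface_nodes(n_s, state.centre, level="coarse")
        sf = sphere_surface_nodes(N_s, state.centre, level="fine")
        wc = wf = None
        if wall_spec is not None:
            topo = topography if topography is not None else Topography("flat", 0.0, 1.0)
            spec = wall_spec.recentred(state.centre[0], state.centre[1])
            wc = wall_patch_nodes(spec, topo, level="coarse", rescale=rescale)
            wf = wall_patch_nodes(spec, topo, level="fine", rescale=rescale)
        return cls(state, kernel, sc, sf, wc, wf)

    @property
    def coarse(self) -> NodeSet:
        if self.wall_coarse is not None:
            return concatenate_node_sets(self.swimmer_coarse, self.wall_coarse)
        return self.swimmer_coarse

    @property
    def fine(self) -> NodeSet:
        if self.wall_fine is not None:
            return concatenate_node_sets(self.swimmer_fine, self.wall_fine)
        return self.swimmer_fine


@dataclass
class MobilitySolution:
    """Rigid-body velocities, tractions and a posteriori balance residuals."""

    U: np.ndarray
    Omega: np.ndarray
    tractions: np.ndarray
    force_residual: np.ndarray
    torque_residual: np.ndarray
    n_coarse: int
    n_fine: int
    condition_estimate: Optional[float] = None


def _nn_indices(coarse: NodeSet, fine: NodeSet) -> np.ndarray:
    """For each fine node, the index of the nearest coarse node of the
    same body; ties break to the lowest coarse index.

    Matching uses each set's ``nn_coords`` — body-local coordinates with
    the surface translation removed (planar for wall patches).  This
    keeps the assignment bitwise identical as the surface moves: with
    absolute coordinates, fine nodes that are equidistant between two
    coarse nodes (the central row of an odd wall grid, exactly) would
    flip allegiance with floating-point rounding of the patch centre,
    making the discretised right-hand side discontinuous in the swimmer
    position and stalling adaptive time integration.
    """
    if coarse.count == 0 or fine.count == 0:
        raise AssemblyError("nearest-neighbour map needs non-empty node sets")
    idx = np.full(fine.count, -1, dtype=int)
    for body in np.unique(fine.bodies):
        cmask = np.flatnonzero(coarse.bodies == body)
        fmask = np.flatnonzero(fine.bodies == body)
        if cmask.size == 0:
            raise AssemblyError(f"fine nodes of body {body!r} have no coarse nodes")
        d = cdist(fine.nn_coords[fmask], coarse.nn_coords[cmask])
        idx[fmask] = cmask[np.argmin(d, axis=1)]
    return idx


def nearest_neighbour_matrix(coarse: NodeSet, fine: NodeSet) -> scipy.sparse.csr_matrix:
    """Sparse 0/1 interpolation matrix nu[q, n]: each fine-node row selects
    its nearest same-body coarse node (rows sum to one; cross-body
    entries vanish)."""
    idx = _nn_indices(coarse, fine)
    Q = fine.count
    return scipy.sparse.csr_matrix(
        (np.ones(Q), (np.arange(Q), idx)), shape=(Q, coarse.count)
    )


@dataclass
class AssembledSystem:
    """Dense (3N + 6) mobility system plus the aggregated balance data."""

    matrix: np.ndarray
    rhs: np.ndarray
    coarse: NodeSet
    nn_index: np.ndarray
    areas: np.ndarray      # per coarse node: sum of mapped fine areas
    moments: np.ndarray    # per coarse node: sum of fine area * (x_q - X)
    n_swimmer: int


def _aggregated_kernel(problem: MobilityProblem) -> tuple:
    """Coarse-coarse kernel blocks with fine-node quadrature folded in.

    Returns (K, coarse, nn, areas, moments) where K[n', n] is the 3x3
    block sum_q S^eps(x[n'], x_q) nu[q, n] dA[q].
    """
    coarse = problem.coarse
    fine = problem.fine
    nn = _nn_indices(coarse, fine)

    # reject duplicated collocation points (singular system otherwise)
    d = cdist(coarse.positions, coarse.positions)
    np.fill_diagonal(d, np.inf)
    if d.min() < 1e-12:
        raise AssemblyError("duplicate collocation points detected")

    if np.any(np.bincount(nn, minlength=coarse.count) == 0):
        raise AssemblyError("a coarse node received no fine quadrature nodes")
    if problem.kernel.kind == "reg_stokeslet":
        # hot path: fused accumulation, shape (N, 3, N, 3)
        Kagg = stokeslet_aggregate(
            coarse.positions, fine.positions, fine.weights, nn, problem.kernel.epsilon
        )
    else:
        K = kernel_matrix(
            coarse.positions, fine.positions, problem.kernel, weights=fine.weights
        )
        order = np.argsort(nn, kind="stable")
        bounds = np.searchsorted(nn[order], np.arange(coarse.count))
        Kagg = np.add.reduceat(K[:, order], bounds, axis=1).transpose(0, 2, 1, 3)

    # swimmer-only aggregated areas and moments for the balance rows
    X = problem.state.centre
    sw_fine = problem.swimmer_fine
    areas = np.zeros(coarse.count)
    moments = np.zeros((coarse.count, 3))
    nsf = sw_fine.count
    np.add.at(areas, nn[:nsf], sw_fine.weights)
    np.add.at(moments, nn[:nsf], sw_fine.weights[:, None] * (sw_fine.positions - X))
    return Kagg, coarse, nn, areas, moments


def assemble_mobility_system(
    problem: MobilityProblem,
    external_force=None,
    external_torque=None,
) -> AssembledSystem:
    """Build the dense (3N + 6) x (3N + 6) system and its right-hand side.

    Unknown ordering: tractions g[0..N-1] (3 each), then U, then Omega.
    Swimmer collocation rows read
    -(1/8 pi) sum_n K[n', n] g[n] - U - Omega x (x[n'] - X) = u_s(x[n']);
    wall rows have zero boundary velocity and no rigid-body coupling.  The
    last six rows impose the (optionally non-zero) force and torque
    balance over the swimmer surface.
    """
    Kagg, coarse, nn, areas, moments = _aggregated_kernel(problem)
    N = coarse.count
    ns = problem.swimmer_coarse.count
    X = problem.state.centre

    size = 3 * N + 6
    M = np.zeros((size, size))
    M[: 3 * N, : 3 * N] = (-1.0 / (8.0 * np.pi)) * Kagg.reshape(3 * N, 3 * N)
    eye = np.eye(3)
    for i in range(ns):
        rows = slice(3 * i, 3 * i + 3)
        M[rows, 3 * N : 3 * N + 3] = -eye
        M[rows, 3 * N + 3 :] = _skew(coarse.positions[i] - X)
    for n in range(N):
        cols = slice(3 * n, 3 * n + 3)
        M[3 * N : 3 * N + 3, cols] = areas[n] * eye
        M[3 * N + 3 :, cols] = _skew(moments[n])

    rhs = np.zeros(size)
    rhs[: 3 * ns] = slip_velocity(
        problem.swimmer_coarse.positions, problem.state
    ).ravel()
    # the traction of this single-layer convention is the fluid-on-body
    # stress, so balancing an applied body force F requires int f dS = -F
    if external_force is not None:
        rhs[3 * N : 3 * N + 3] = -np.asarray(external_force, dtype=float)
    if external_torque is not None:
        rhs[3 * N + 3 :] = -np.asarray(external_torque, dtype=float)
    return AssembledSystem(M, rhs, coarse, nn, areas, moments, ns)


def _direct_solve(M: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    try:
        sol = scipy.linalg.solve(M, rhs)
    except scipy.linalg.LinAlgError as exc:
        raise SolverError(
            f"singular mobility system (condition estimate {np.linalg.cond(M):.3e})"
        ) from exc
    if not np.all(np.isfinite(sol)):
        raise SolverError(
            f"non-finite solution (condition estimate {np.linalg.cond(M):.3e})"
        )
    return sol


def solve_mobility(
    problem: MobilityProblem,
    external_force=None,
    external_torque=None,
) -> MobilitySolution:
    """Solve for tractions and rigid-body velocities; residuals of the
    discrete force/torque balance are recomputed from the returned
    tractions as a consistency check."""
    system = assemble_mobility_system(problem, external_force, external_torque)
    N = system.coarse.count
    sol = _direct_solve(system.matrix, system.rhs)
    g = sol[: 3 * N].reshape(N, 3)
    U = sol[3 * N : 3 * N + 3]
    Omega = sol[3 * N + 3 :]

    F = system.areas[:, None] * g
    force_res = F.sum(axis=0) - system.rhs[3 * N : 3 * N + 3]
    torque_res = np.cross(system.moments, g).sum(axis=0) - system.rhs[3 * N + 3 :]
    return MobilitySolution(
        U=U,
        Omega=Omega,
        tractions=g,
        force_residual=force_res,
        torque_residual=torque_res,
        n_coarse=N,
        n_fine=problem.fine.count,
    )


def solve_resistance(problem: MobilityProblem, U_given, Omega_given) -> tuple:
    """Prescribed rigid-body motion, no slip: returns the fluid-on-body
    force and torque integrals of the resulting traction field (the body
    must exert their negatives).  Requires a passive sphere (B1 = 0)."""
    if problem.state.B1 != 0.0:
        raise ValueError("resistance problem requires a passive sphere (B1 = 0)")
    Kagg, coarse, nn, areas, moments = _aggregated_kernel(problem)
    N = coarse.count
    ns = problem.swimmer_coarse.count
    X = problem.state.centre
    U_given = np.asarray(U_given, dtype=float)
    Omega_given = np.asarray(Omega_given, dtype=float)

    M = (-1.0 / (8.0 * np.pi)) * Kagg.reshape(3 * N, 3 * N)
    rhs = np.zeros(3 * N)
    for i in range(ns):
        d = coarse.positions[i] - X
        rhs[3 * i : 3 * i + 3] = U_given + np.cross(Omega_given, d)
    g = _direct_solve(M, rhs).reshape(N, 3)
    F = (areas[:, None] * g).sum(axis=0)
    T = np.cross(moments, g).sum(axis=0)
    return F, T
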