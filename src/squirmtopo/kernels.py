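"""Regularised Stokes-flow kernels.

The free-space kernel is the regularised Stokeslet

    S^eps_ij(x, y) = [(r^2 + 2 eps^2) delta_ij + r_i r_j] (r^2 + eps^2)^(-3/2),

with r = x - y: the exact (divergence-free) Stokes solution for a point
force smoothed over a blob of width eps.  The conventional -1/(8 pi)
prefactor of the single-layer boundary integral is applied during system
assembly, not here.

The half-space kernel ("regularised Blakelet") augments the Stokeslet
with an image system below the no-slip plane — mirror Stokeslet plus
potential-dipole and Stokeslet-doublet corrections — built by applying
Blake's image operator to the regularised kernel family.  Its velocity on
the plane vanishes as eps -> 0 (the residual is O(eps^2) at wall
distances of order one) and it reduces to the free-space kernel far from
the plane.

The pairwise ``*_matrix`` functions optionally fold per-source quadrature
weights into the kernel scalars, which keeps boundary-integral assembly
away from any (N, Q, 3, 3)-sized elementwise multiply.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import GeometryError, ParameterError

__all__ = [
    "KernelSpec",
    "regularised_stokeslet",
    "regularised_blakelet",
    "stokeslet_matrix",
    "blakelet_matrix",
    "kernel_matrix",
]

KERNEL_KINDS = ("reg_stokeslet", "reg_blakelet")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel selection: kind, blob width eps and (for the Blakelet) the
    height of the no-slip plane z = wall_plane_height."""

    kind: str = "reg_stokeslet"
    epsilon: float = 1e-3
    wall_plane_height: float = 0.0

    def __post_init__(self):
        if self.kind not in KERNEL_KINDS:
            raise ParameterError(f"unknown kernel kind {self.kind!r}")
        if self.epsilon <= 0:
            raise ParameterError("regularisation parameter epsilon must be > 0")


def _pair_geometry(X, Y, eps: float):
    r = X[:, None, :] - Y[None, :, :]
    r2 = r[..., 0] ** 2 + r[..., 1] ** 2 + r[..., 2] ** 2
    inv = 1.0 / (r2 + eps * eps)
    s3 = inv * np.sqrt(inv)
    return r, r2, s3, inv


def _stokeslet_accumulate(out, r, r2, s3, eps: float, sign: float = 1.0) -> None:
    """Add sign * [(r^2 + 2 eps^2) delta_ij + r_i r_j] s3 into out."""
    diag = (r2 + 2.0 * eps * eps) * s3
    for i in range(3):
        ri_s3 = (sign * s3) * r[..., i]
        for j in range(i, 3):
            v = ri_s3 * r[..., j]
            out[..., i, j] += v
            if j > i:
                out[..., j, i] += v
        out[..., i, i] += sign * diag


def stokeslet_matrix(X, Y, eps: float, weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Pairwise regularised Stokeslet blocks, shape (len(X), len(Y), 3, 3).

    Entry [a, b, i, j] is the i-th velocity component at X[a] induced by a
    unit force in direction j at Y[b] (up to the assembly prefactor).
    ``weights`` scales each source column, turning the blocks into
    quadrature contributions.
    """
    if eps <= 0:
        raise ParameterError("regularisation parameter epsilon must be > 0")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    r, r2, s3, _ = _pair_geometry(X, Y, eps)
    if weights is not None:
        s3 = s3 * np.asarray(weights, dtype=float)[None, :]
    out = np.zeros((X.shape[0], Y.shape[0], 3, 3))
    _stokeslet_accumulate(out, r, r2, s3, eps)
    return out


def regularised_stokeslet(x, y, eps: float) -> np.ndarray:
    """Single-pair regularised Stokeslet, a symmetric 3x3 tensor; finite
    for all separations including x = y (value (2/eps) * identity)."""
    return stokeslet_matrix([x], [y], eps)[0, 0]


# Mirror signs Delta = diag(1, 1, -1) acting on the force index of the
# image corrections.
_MIRROR = np.array([1.0, 1.0, -1.0])


def blakelet_matrix(
    X, Y, eps: float, wall_plane_height: float = 0.0,
    weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Pairwise regularised Blakelet blocks above the plane z = const.

    Sources (rows of Y) must lie strictly above the plane; evaluation
    points may lie on it (that is where the no-slip property is checked)
    but not below.
    """
    if eps <= 0:
        raise ParameterError("regularisation parameter epsilon must be > 0")
    X = np.atleast_2d(np.asarray(X, dtype=float)).copy()
    Y = np.atleast_2d(np.asarray(Y, dtype=float)).copy()
    X[:, 2] -= wall_plane_height
    Y[:, 2] -= wall_plane_height
    if np.any(Y[:, 2] <= 0):
        raise GeometryError("Blakelet source point on or below the no-slip plane")
    if np.any(X[:, 2] < 0):
        raise GeometryError("Blakelet evaluation point below the no-slip plane")

    w = None if weights is None else np.asarray(weights, dtype=float)[None, :]
    h = Y[:, 2]
    Ystar = Y.copy()
    Ystar[:, 2] = -h

    out = np.zeros((X.shape[0], Y.shape[0], 3, 3))
    r, r2, s3, _ = _pair_geometry(X, Y, eps)
    if w is not None:
        s3 = s3 * w
    _stokeslet_accumulate(out, r, r2, s3, eps, sign=+1.0)

    R, R2, S3, inv = _pair_geometry(X, Ystar, eps)
    if w is not None:
        S3 = S3 * w
    _stokeslet_accumulate(out, R, R2, S3, eps, sign=-1.0)
    S5 = S3 * inv

    # image corrections: 2 h Delta_j [ h * d/dR_j (R_i / s^3)
    #                                  - d/dR_j S^eps_i3(R) ]
    hb = h[None, :]
    R3 = R[..., 2]
    for j in range(3):
        fac = (2.0 * _MIRROR[j]) * hb
        # potential-dipole derivative: delta_ij S3 - 3 R_i R_j S5
        pd3 = -3.0 * R[..., j] * S5
        # Stokeslet-z derivative pieces shared across i
        dz_diag = 2.0 * R[..., j] * S3 - 3.0 * R[..., j] * (R2 + 2.0 * eps * eps) * S5
        for i in range(3):
            term = hb * R[..., i] * pd3
            if i == j:
                term = term + hb * S3
            # minus d/dR_j S^eps_i3
            dSz = R[..., i] * pd3 * R3
            if i == 2:
                dSz = dSz + dz_diag
            if i == j:
                dSz = dSz + R3 * S3
            if j == 2:
                dSz = dSz + R[..., i] * S3
            out[..., i, j] += fac * (term - dSz)
    return out


def regularised_blakelet(x, y, eps: float, wall_plane_height: float = 0.0) -> np.ndarray:
    """Single-pair regularised Blakelet tensor."""
    return blakelet_matrix([x], [y], eps, wall_plane_height)[0, 0]


def kernel_matrix(X, Y, spec: KernelSpec, weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Pairwise kernel blocks for the selected kernel."""
    if spec.kind == "reg_stokeslet":
        return stokeslet_matrix(X, Y, spec.epsilon, weights=weights)
    return blakelet_matrix(X, Y, spec.epsilon, spec.wall_plane_height, weights=weights)
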