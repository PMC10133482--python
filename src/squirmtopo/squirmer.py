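"""The spherical tangential squirmer: state, slip profile, free-space speed.

The swimmer is a rigid unit sphere that self-propels through a prescribed
axisymmetric tangential surface velocity

    u_s(Theta) = sum_n B_n V_n(cos Theta),
    V_n(cos Theta) = (2 / (n (n + 1))) sin(Theta) P_n'(cos Theta),

where Theta is the polar angle from the orientation vector n and P_n the
Legendre polynomial.  The expansion is truncated at two modes: B1 sets
the free-space speed U = (2/3) B1 n, and beta = B2/B1 distinguishes
pushers (beta < 0), pullers (beta > 0) and neutral swimmers (beta = 0).

Orientation angles follow a single fixed convention: theta = arcsin(n_z)
is the pitch relative to the wall midplane, and phi = atan2(n_x, n_y) is
the heading of the horizontal projection measured from the +y axis,
positive towards +x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import lpmv

from .errors import GeometryError

__all__ = [
    "SquirmerState",
    "orientation_from_angles",
    "orientation_angles",
    "slip_speed",
    "slip_speed_modes",
    "slip_velocity",
    "free_space_velocity",
]


def orientation_from_angles(theta: float, phi: float) -> np.ndarray:
    """Unit orientation (cos th sin ph, cos th cos ph, sin th)."""
    return np.array(
        [
            np.cos(theta) * np.sin(phi),
            np.cos(theta) * np.cos(phi),
            np.sin(theta),
        ]
    )


def orientation_angles(n) -> tuple:
    """(theta, phi) for a unit vector; at the poles phi defaults to 0."""
    n = np.asarray(n, dtype=float)
    theta = float(np.arcsin(np.clip(n[2], -1.0, 1.0)))
    if abs(n[0]) < 1e-300 and abs(n[1]) < 1e-300:
        return theta, 0.0
    return theta, float(np.arctan2(n[0], n[1]))


@dataclass
class SquirmerState:
    """Rigid-body state: centre X, unit orientation n and slip modes."""

    centre: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    B1: float = 1.5
    beta: float = 0.0

    def __post_init__(self):
        self.centre = np.asarray(self.centre, dtype=float).copy()
        self.orientation = np.asarray(self.orientation, dtype=float).copy()
        norm = np.linalg.norm(self.orientation)
        if norm < 1e-12:
            raise GeometryError("orientation vector must be non-zero")
        self.orientation /= norm

    @classmethod
    def from_angles(cls, centre, theta, phi, B1=1.5, beta=0.0) -> "SquirmerState":
        return cls(centre=centre, orientation=orientation_from_angles(theta, phi), B1=B1, beta=beta)

    @property
    def angles(self) -> tuple:
        return orientation_angles(self.orientation)


def slip_speed_modes(Theta, modes) -> np.ndarray:
    """General slip speed sum_n B_n V_n(cos Theta) for a mode list.

    Uses sin(Theta) P_n'(cos Theta) = -P_n^1(cos Theta) via the associated
    Legendre function (Condon-Shortley phase).
    """
    Theta = np.asarray(Theta, dtype=float)
    x = np.cos(Theta)
    total = np.zeros(Theta.shape)
    for n, Bn in enumerate(modes, start=1):
        if Bn == 0.0:
            continue
        total += Bn * (-2.0 / (n * (n + 1))) * lpmv(1, n, x)
    return total[()]


def slip_speed(Theta, B1: float, beta: float):
    """Two-mode tangential slip B1 sin(Theta) (1 + beta cos(Theta))."""
    return slip_speed_modes(Theta, [B1, B1 * beta])


def slip_velocity(point, state: SquirmerState, tol: float = 1e-8) -> np.ndarray:
    """Slip velocity vector(s) at surface point(s), tangent to the sphere.

    With m = point - X (unit) and cos Theta = n . m, the slip acts along
    the unit tangent t = (cos Theta m - n) / sin Theta (the direction of
    increasing Theta) and vanishes at both poles.  Points further than
    ``tol`` from the unit sphere raise :class:`GeometryError`.
    """
    point = np.asarray(point, dtype=float)
    single = point.ndim == 1
    pts = np.atleast_2d(point)
    m = pts - state.centre
    radii = np.linalg.norm(m, axis=1)
    if np.any(np.abs(radii - 1.0) > tol):
        raise GeometryError("slip velocity requested off the unit sphere")
    m = m / radii[:, None]
    n = state.orientation
    ct = m @ n
    # u_s * t_hat = B1 (1 + beta ct) * (ct m - n); the sin(Theta) of the
    # slip magnitude cancels the tangent normalisation, so poles give 0.
    u = (state.B1 * (1.0 + state.beta * ct))[:, None] * (ct[:, None] * m - n[None, :])
    return u[0] if single else u


def free_space_velocity(state: SquirmerState) -> np.ndarray:
    """Exact unbounded-fluid swimming velocity U = (2/3) B1 n."""
    return (2.0 / 3.0) * state.B1 * state.orientation
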