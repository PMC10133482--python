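"""Surface discretisations and topography geometry.

All lengths are measured in squirmer radii (the swimmer radius is a = 1).
The wall midplane is z = 0 and a topography assigns a height z = h(x, y)
to every horizontal position; the swimmer centre must stay above the
surface.

Two node-set levels appear throughout: a *coarse* set carrying the unknown
surface traction and a *fine* set used purely as a quadrature rule for the
boundary integral.  Sphere meshes are cube-projected grids with 6 n^2
nodes; wall patches are truncated squares of side L that follow the
swimmer horizontally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .errors import GeometryError

__all__ = [
    "Topography",
    "NodeSet",
    "WallPatchSpec",
    "sphere_surface_nodes",
    "topography_height",
    "topography_gradient",
    "rescale_map",
    "inverse_rescale_map",
    "wall_patch_nodes",
    "min_clearance",
    "concatenate_node_sets",
]

TOPOGRAPHY_KINDS = ("flat", "sin1d", "sin2d", "peaks2d")


@dataclass(frozen=True)
class Topography:
    """A periodic surface topography z = h(x, y).

    Parameters
    ----------
    kind:
        One of ``flat``, ``sin1d`` (one-dimensional sinusoid A sin(kx)),
        ``sin2d`` (doubly periodic sinusoid A sin(kx) sin(ky)) or
        ``peaks2d`` (doubly periodic peaks A (2 sin^2(kx) sin^2(ky) - 1)).
    amplitude:
        Peak height A >= 0; every kind satisfies -A <= h <= A.
    wave_parameter:
        The length parameter lambda > 0 with wavenumber k = 2 pi / lambda.
        For ``peaks2d`` the actual spatial period is lambda / 2 because
        the sinusoids are squared.
    """

    kind: str
    amplitude: float = 0.1
    wave_parameter: float = 2.0

    def __post_init__(self):
        if self.kind not in TOPOGRAPHY_KINDS:
            raise GeometryError(f"unknown topography kind {self.kind!r}")
        if self.amplitude < 0:
            raise GeometryError("topography amplitude must be >= 0")
        if self.wave_parameter <= 0:
            raise GeometryError("topography wave parameter must be > 0")

    @property
    def wavenumber(self) -> float:
        return 2.0 * np.pi / self.wave_parameter

    def height(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        k = self.wavenumber
        A = self.amplitude
        if self.kind == "flat":
            return np.zeros(np.broadcast(x, y).shape)[()]
        if self.kind == "sin1d":
            return (A * np.sin(k * x) + 0.0 * y)[()]
        if self.kind == "sin2d":
            return (A * np.sin(k * x) * np.sin(k * y))[()]
        # peaks2d
        return (A * (2.0 * np.sin(k * x) ** 2 * np.sin(k * y) ** 2 - 1.0))[()]

    def gradient(self, x, y):
        """Analytic (dh/dx, dh/dy)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        k = self.wavenumber
        A = self.amplitude
        zero = np.zeros(np.broadcast(x, y).shape)
        if self.kind == "flat":
            return zero[()], zero.copy()[()]
        if self.kind == "sin1d":
            return (A * k * np.cos(k * x) + zero)[()], zero.copy()[()]
        if self.kind == "sin2d":
            return (
                (A * k * np.cos(k * x) * np.sin(k * y))[()],
                (A * k * np.sin(k * x) * np.cos(k * y))[()],
            )
        gx = 4.0 * A * k * np.sin(k * x) * np.cos(k * x) * np.sin(k * y) ** 2
        gy = 4.0 * A * k * np.sin(k * x) ** 2 * np.sin(k * y) * np.cos(k * y)
        return gx[()], gy[()]


def topography_height(topo: Topography, x, y):
    """Height h(x, y) of the surface above the midplane."""
    return topo.height(x, y)


def topography_gradient(topo: Topography, x, y):
    """Analytic surface gradient (dh/dx, dh/dy)."""
    return topo.gradient(x, y)


@dataclass
class NodeSet:
    """A quadrature discretisation of a surface.

    ``positions`` is (count, 3); ``weights`` holds the per-node surface
    area; ``body`` labels the owning surface (``swimmer`` or ``wall``,
    ``mixed`` after concatenation) and ``bodies`` gives the per-node label
    used by the nearest-neighbour interpolation; ``level`` records whether
    the set discretises the traction (coarse) or the kernel quadrature
    (fine).
    """

    positions: np.ndarray
    weights: np.ndarray
    body: str
    level: str
    bodies: np.ndarray = field(default=None)
    #: coordinates used for nearest-neighbour matching; body-local (the
    #: translation of the surface removed) so the coarse-fine assignment
    #: is bitwise-reproducible as the surface moves.  Defaults to the
    #: absolute positions.
    nn_coords: np.ndarray = field(default=None)

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.positions.shape[0] != self.weights.shape[0]:
            raise GeometryError("positions and weights must have equal length")
        if np.any(self.weights < 0):
            raise GeometryError("node weights must be non-negative")
        if self.bodies is None:
            self.bodies = np.full(self.positions.shape[0], self.body, dtype=object)
        else:
            self.bodies = np.asarray(self.bodies, dtype=object)
        if self.nn_coords is None:
            self.nn_coords = self.positions.copy()
        else:
            self.nn_coords = np.atleast_2d(np.asarray(self.nn_coords, dtype=float))

    @property
    def count(self) -> int:
        return self.positions.shape[0]

    def to_text(self, path) -> None:
        """Write a four-column ``x y z weight`` table with a header comment."""
        data = np.column_stack([self.positions, self.weights])
        header = (
            f"surface node set: body={self.body} level={self.level} "
            f"count={self.count}\ncolumns: x y z weight"
        )
        np.savetxt(path, data, header=header)

    @classmethod
    def from_text(cls, path, body="swimmer", level="coarse") -> "NodeSet":
        data = np.atleast_2d(np.loadtxt(path))
        return cls(positions=data[:, :3], weights=data[:, 3], body=body, level=level)


def concatenate_node_sets(*sets: NodeSet) -> NodeSet:
    """Stack node sets, keeping per-node body labels for interpolation."""
    if not sets:
        raise GeometryError("cannot concatenate zero node sets")
    level = sets[0].level
    return NodeSet(
        positions=np.concatenate([s.positions for s in sets]),
        weights=np.concatenate([s.weights for s in sets]),
        body="mixed" if len({s.body for s in sets}) > 1 else sets[0].body,
        level=level,
        bodies=np.concatenate([s.bodies for s in sets]),
        nn_coords=np.concatenate([s.nn_coords for s in sets]),
    )


def sphere_surface_nodes(n: int, centre=(0.0, 0.0, 0.0), level: str = "coarse") -> NodeSet:
    """Cube-projected unit-sphere mesh with 6 n^2 nodes.

    Each face of the circumscribing cube is divided into an n x n grid of
    equal cells; one node sits at each cell centre, projected radially
    onto the sphere.  Weights are uniform, 4 pi / (6 n^2): the placement
    that reproduces the reference free-space speed table.  Cell-centre
    grids of different refinement never share a node, so coarse and fine
    discretisations are automatically disjoint.
    """
    if int(n) != n or n < 2:
        raise GeometryError(f"sphere refinement must be an integer >= 2, got {n!r}")
    n = int(n)
    centre = np.asarray(centre, dtype=float)
    edges = np.linspace(-1.0, 1.0, n + 1)
    c = 0.5 * (edges[:-1] + edges[1:])
    A, B = np.meshgrid(c, c, indexing="ij")
    faces = []
    for axis in range(3):
        for sign in (+1.0, -1.0):
            p = np.empty((n * n, 3))
            p[:, axis] = sign
            others = [i for i in range(3) if i != axis]
            p[:, others[0]] = A.ravel()
            p[:, others[1]] = B.ravel()
            faces.append(p)
    pts = np.concatenate(faces)
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    weights = np.full(len(pts), 4.0 * np.pi / len(pts))
    return NodeSet(
        positions=pts + centre,
        weights=weights,
        body="swimmer",
        level=level,
        nn_coords=pts,
    )


@dataclass(frozen=True)
class WallPatchSpec:
    """A truncated square wall patch of side ``side_length`` (symbol L).

    The patch is centred at ``centre_xy`` — in a simulation, the
    projection of the squirmer centre onto z = 0 — and discretised with
    ``coarse_per_side`` (n_w) or ``fine_per_side`` (N_w) points per side;
    the fine count must exceed the coarse count.  The default pair
    (12, 32) satisfies n_w (2i + 1) != 2 N_w k for all integers, which
    guarantees that no fine node coincides with a coarse node (the
    regularised kernel's O(1/eps) self-value would pollute the
    quadrature) and that no fine node is exactly equidistant between two
    coarse nodes (an asymmetrically broken tie exerts a spurious lateral
    force on the swimmer).
    """

    side_length: float = 8.0
    coarse_per_side: int = 12
    fine_per_side: int = 32
    centre_xy: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.side_length <= 0:
            raise GeometryError("wall patch side length must be > 0")
        if self.fine_per_side <= self.coarse_per_side:
            raise GeometryError("fine_per_side must exceed coarse_per_side")

    def recentred(self, x: float, y: float) -> "WallPatchSpec":
        return replace(self, centre_xy=(float(x), float(y)))


def rescale_map(x):
    """Node-concentrating map (1/2) tan(pi x / 2) on [-1/2, 1/2].

    Strictly increasing and odd with fixed endpoints; it crowds wall
    nodes towards the patch centre, where the swimmer-wall interaction
    needs resolving, at the expense of the remote patch edge.
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 0.5 + 1e-12):
        raise GeometryError("rescale_map argument must lie in [-1/2, 1/2]")
    return (0.5 * np.tan(0.5 * np.pi * np.clip(x, -0.5, 0.5)))[()]


def inverse_rescale_map(y):
    """Inverse of :func:`rescale_map`: (2/pi) arctan(2 y)."""
    y = np.asarray(y, dtype=float)
    return ((2.0 / np.pi) * np.arctan(2.0 * y))[()]


def wall_patch_nodes(
    spec: WallPatchSpec,
    topo: Topography,
    level: str = "coarse",
    rescale: bool = True,
) -> NodeSet:
    """Square grid of wall nodes lifted onto the topography.

    An equally spaced cell-centre grid on the unit square is (optionally)
    mapped componentwise by :func:`rescale_map`, dilated by L, translated
    to the patch centre and lifted to z = h(x, y).  Each weight is the
    exact mapped cell area times the surface metric sqrt(1 + |grad h|^2),
    so for a flat wall the weights tile L^2 exactly.
    """
    n = spec.coarse_per_side if level == "coarse" else spec.fine_per_side
    edges = np.linspace(-0.5, 0.5, n + 1)
    if rescale:
        edges = rescale_map(edges)
    edges = spec.side_length * edges
    centres = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    X, Y = np.meshgrid(centres, centres, indexing="ij")
    WX, WY = np.meshgrid(widths, widths, indexing="ij")
    x = X.ravel() + spec.centre_xy[0]
    y = Y.ravel() + spec.centre_xy[1]
    z = np.broadcast_to(topo.height(x, y), x.shape)
    gx, gy = topo.gradient(x, y)
    metric = np.sqrt(1.0 + np.broadcast_to(gx, x.shape) ** 2 + np.broadcast_to(gy, x.shape) ** 2)
    weights = (WX * WY).ravel() * metric
    positions = np.column_stack([x, y, z])
    # patch-local planar coordinates: coarse-fine matching stays fixed
    # (and flat-wall-equivalent) as the patch translates over topography
    local = np.column_stack([X.ravel(), Y.ravel(), np.zeros(x.shape)])
    return NodeSet(
        positions=positions, weights=weights, body="wall", level=level, nn_coords=local
    )


def _clearance_point(centre, topo, x, y):
    dz = centre[2] - topo.height(x, y)
    return np.sqrt((centre[0] - x) ** 2 + (centre[1] - y) ** 2 + dz**2)


def min_clearance(state, topo: Topography) -> float:
    """Smallest gap between the unit sphere and the wall surface.

    Returns min over the surface of |centre - surface point| - 1; a
    non-positive value signals contact/overlap rather than raising.  The
    flat (or zero-amplitude) case is the exact vertical gap z - 1; the
    periodic cases use a coarse grid search over a 3 lambda window under
    the centre followed by local refinement.
    """
    centre = np.asarray(getattr(state, "centre", state), dtype=float)
    if topo.kind == "flat" or topo.amplitude == 0.0:
        return float(centre[2] - 1.0)
    lam = topo.wave_parameter
    half = 1.5 * lam
    g = np.linspace(-half, half, 61)
    U, V = np.meshgrid(centre[0] + g, centre[1] + g, indexing="ij")
    d = _clearance_point(centre, topo, U, V)
    i = np.unravel_index(np.argmin(d), d.shape)
    x0 = np.array([U[i], V[i]])

    res = minimize(
        lambda p: _clearance_point(centre, topo, p[0], p[1]),
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10},
    )
    best = min(float(res.fun), float(d[i]))
    return best - 1.0
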