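# Methods

## Physical model

The swimmer is a spherical *tangential squirmer*: a rigid sphere of
radius a = 1 that self-propels through a prescribed axisymmetric
tangential slip velocity on its surface,

    u_s(Theta) = B1 V1(cos Theta) + B2 V2(cos Theta),
    V_n(cos Theta) = (2 / (n (n+1))) sin(Theta) P_n'(cos Theta),

with Theta the polar angle from the orientation vector **n** and P_n the
Legendre polynomials.  Higher modes are truncated.  B1 fixes the
free-space swimming velocity U = (2/3) B1 **n** (B1 = 3/2 gives unit
speed, the package default); beta = B2/B1 is the squirmer parameter
(beta < 0 pusher, beta > 0 puller, beta = 0 neutral).  The slip
evaluator internally accepts an arbitrary mode list (via associated
Legendre functions), which the tests exploit to cross-check the
two-mode closed form against a symbolic evaluation.

The fluid satisfies the incompressible Stokes equations, with no-slip
conditions on the wall surface and on the swimmer (surface velocity
U + Omega x (x - X) + u_s), and zero net force and torque on the
swimmer.  All lengths are in swimmer radii and time in a/U units; the
viscosity is scaled out.

Walls are either an infinite no-slip plane z = 0 (handled by an
image-system kernel) or a surface z = h(x, y) with one of four
topographies: flat; a one-dimensional sinusoid A sin(kx); a doubly
periodic sinusoid A sin(kx) sin(ky); or doubly periodic peaks
A (2 sin^2(kx) sin^2(ky) - 1), whose spatial period is lambda/2 rather
than lambda because the sinusoids are squared.  All four stay within
[-A, +A].

Short-range physics (steric contact, electrostatics, lubrication below
the mesh scale) is deliberately outside the model: simulations stop
when the surface clearance falls to `stop_clearance` before such
effects could dominate.

## Numerical method

**Boundary integral.**  The flow is represented by a single-layer
potential u_j(x) = -(1/8 pi) ∫ S^eps_ij(x, y) f_i(y) dS over swimmer
plus wall, with the regularised Stokeslet kernel

    S^eps_ij = [(r^2 + 2 eps^2) delta_ij + r_i r_j] (r^2 + eps^2)^(-3/2).

The regularisation error is O(eps); the default blob width is
eps = 1e-3 radii.

**Two-level (nearest-neighbour) quadrature.**  Tractions live on a
coarse node set (N nodes); the kernel is integrated over a finer set (Q
nodes).  Each fine node inherits the traction of its nearest coarse
node of the same body, with nearness measured in body-local
coordinates (sphere nodes relative to the centre; wall nodes in the
planar patch grid) and ties broken to the lowest coarse index.  Local
coordinates make the assignment independent of where the body sits:
matching in absolute coordinates would let exactly-equidistant nodes
(the central row of an odd wall grid) flip allegiance with the
floating-point rounding of the patch centre, which renders the
discretised right-hand side of the dynamics discontinuous in the
swimmer position and collapses the adaptive step size.  The discretised
integral reads

    sum_n g[n] sum_q S^eps(x, x_q) nu[q, n] dA[q],

with dA[q] the fine-node area.  Keeping the two sets disjoint means the
quadrature never evaluates the kernel at zero separation, and the
system size depends only on N.  Velocity boundary conditions are
collocated at the coarse nodes; together with the six balance equations
this gives a square dense system of size 3N + 6 in the tractions and
(U, Omega), solved by LAPACK LU with partial pivoting.  The continuum
gauge freedom f -> f + alpha * normal does not survive discretisation,
so no auxiliary constraint is added; a gauge perturbation re-substituted
through the balance rows shifts the computed force/torque by orders of
magnitude less than the perturbation (tested with alpha = 1e-6).

**Sphere meshes.**  Each face of the circumscribing cube is divided
into n x n equal cells; a node sits at each cell centre, projected
radially, giving 6 n^2 nodes.  Weights are uniform, 4 pi / (6 n^2):
this is the convention that reproduces the tabulated free-space speeds
of the validation table to all printed decimals (exact projected-cell
areas were also tried and shift the (4, 18) speed by ~0.3%).
Cell-centre grids at different refinements provably never share a node.
Defaults (n_s, N_s) = (4, 18), i.e. 96 traction and 1944 quadrature
nodes, giving free-space speed errors below ~1.5% across the table and
0.48% at the default pair.

**Wall patches.**  The infinite wall is truncated to a square of side
L = 8 centred under the swimmer (re-centred at *every* right-hand-side
evaluation, so the truncation error is independent of horizontal
position).  An equally spaced cell-centre grid on the unit square is
mapped componentwise by x -> (1/2) tan(pi x / 2), which concentrates
nodes under the swimmer, then dilated by L and lifted onto the
topography.  Weights are exact mapped cell areas times the surface
metric sqrt(1 + |grad h|^2).  Defaults are 12 (coarse) and 32 (fine)
points per side, a pair chosen so that n_w (2i + 1) = 2 N_w k has no
integer solutions: no fine node then coincides with a coarse node
(which would inject the O(1/eps) kernel self-value into the
quadrature), and no fine node is exactly equidistant between two
coarse nodes (a tie broken to one side exerts a spurious lateral force
of order 1e-3 on the swimmer that integrates into an O(1) heading
drift over tens of radii; with the tie-free pair, mirror-symmetric
configurations keep their symmetry to machine precision).  Among
tie-free pairs up to 24/64, 12/32 also agrees best with the
image-system kernel (translational velocity within 1.3% at the
flat-wall reference state) at the lowest cost.  Force/torque balance
rows run over the swimmer surface only.

**Flat-wall image kernel.**  For flat walls the package can instead use
a regularised Blakelet: free-space regularised Stokeslet plus an image
system (mirror Stokeslet, potential dipole, Stokeslet doublet) obtained
by applying Blake's image operator to the regularised kernel family.
The defining contract is behavioural and is enforced by tests: the
velocity on the plane is O(eps^2) at order-one wall distances
(~1e-7 at eps = 1e-3), the tensor converges to the classical Blake
image system as eps -> 0, and it reduces to the free-space kernel far
from the wall.

**Time integration.**  dX/dt = U, dn/dt = Omega x n, integrated with
adaptive RK45 (defaults rtol 1e-6, atol 1e-8); the orientation is
renormalised after every accepted step.  Runs end at `max_time`, on
wall contact (clearance <= stop_clearance, default 0.02 radii = 20
eps — above the regularisation scale, below every steady swimming gap
observed, including the ~0.05 crest clearance of the short-wavelength
topography orbits), on
upward escape, or when an optional settling predicate fires.  A run
whose step size has collapsed below `stall_step` (default 1e-3) while
the clearance sits below `stall_clearance` (default 0.06, under a
third of the central wall node spacing) is also terminated as contact:
trial steps are then penetrating a gap the wall mesh cannot resolve,
and the integrator cannot make progress there.
The flat-wall validation declares the height settled when the total z
excursion across a trailing unit-time window falls below 1e-4 (i.e.
the time-averaged |dz/dt| is below 1e-4).

**Clearance.**  The swimmer-surface gap is the minimum of
|centre - surface point| - 1.  For flat walls this is z - 1 exactly;
for periodic topographies a 61 x 61 grid search over a 3 lambda window
under the centre seeds a Nelder-Mead refinement (tolerance well below
1e-6; h is smooth and slowly varying).

**Oscillation metrics.**  The steady z-oscillation amplitude is half
the peak-to-peak excursion over a trailing window; the wavelength is
the mean spacing of z-peaks in horizontal arc length (512-point uniform
resampling, peak prominence 20% of the amplitude).  Half peak-to-peak
is the conservative reading of "oscillation amplitude" when comparing
against the topography amplitude A.

## Study conditions and reproduction scenarios

The scenario registry fixes the reference conditions: B1 = 3/2,
beta = 7 (a puller that swims stably near a flat wall), topography
amplitude A = 0.1, initial centre (0, 0, 1.2) (1.15 for the flat-wall
validation), attack angle theta = -0.17 pi, and in-plane headings phi
swept over {0, 0.05 pi, ..., 0.5 pi} (11 values; the sweep grids are
not tabulated in the source material, so this uniform grid covering the
plotted range is declared here).  The doubly periodic sinusoid sweep
additionally starts one run per wavelength from y = lambda/4 heading
along -x.  Default sweep durations aim at ~30 radii of horizontal
travel.  The phi sign convention (phi measured from +y, positive toward
+x) is declared here as the single authoritative convention; the
mirror-image convention would produce trajectories reflected in x.

## Problem sizes used by the tests and the acceptance script

The acceptance script runs the default discretisation ((n_s, N_s) =
(4, 18), wall 12/32 per side, L = 8) at rtol 1e-6; the flat-wall
settling runs to at most t = 80 and the peaks-topography run to t = 25
with an 8-unit analysis window.  The pytest trajectory checks use the
same discretisation at rtol 1e-5 with horizons of 12-25 time units; at
these settings the verified bounds hold with wide margins (the
short-wavelength z-amplitudes are 0.019 and 0.024 against a bound of
0.1, the trough-aligned peaks amplitude 0.03 against 0.05).  The swimmer
fine grid is never reduced below N_s = 14: the near-wall physics is
controlled by the sphere quadrature, and N_s <= 12 qualitatively
corrupts the wall interaction (the stable height disappears) even
though the free-space speed error stays ~1%.

## What the simulations do and do not show

The generator of all inputs is the configuration itself — there is no
external data and no randomness anywhere in the pipeline (reruns are
bit-identical).  Passing tests demonstrate the internal consistency of
the hydrodynamic model at the stated discretisations and its agreement
with the tabulated free-space speeds, the flat-wall stable height, and
the qualitative topography-guidance regimes.  They do not validate
behaviour within a clearance of ~0.02 radii of the surface (runs stop
there; no steric or lubrication model), prolate or pusher swimmers near
walls (spherical pushers have no stable swimming height), swirl modes,
Brownian motion, or truly infinite periodic walls (the patch is a
truncated, re-centred square; doubling L moves the flat-wall stable
height by well under 1%).

## Known limitations

- The basin of attraction of trough-aligned swimming is
  discretisation-sensitive: over the lambda = 2 sinusoid, initial
  headings up to 0.10 pi from the trough axis are captured, while
  0.15 pi drifts slowly away at the default wall resolution.  Whether
  a given marginal heading is captured should not be over-interpreted;
  the existence of the capture regime (and its absence at lambda = 8)
  is the robust prediction.

- At topography wavelengths well above the swimmer diameter (the 1-D
  sinusoid at lambda = 8) the vertical oscillation locks to the
  topography wavelength, but whether it saturates or keeps growing
  until the swimmer reaches the surface is sensitive to the wall
  discretisation: the default patch sustains a steady
  oscillation over tens of radii, while some finer pairs (e.g. 16/45)
  grow into contact after about two periods.  Long-horizon behaviour in this
  regime should be treated as qualitative.

- Accuracy near the wall is limited by the sphere fine grid and blob
  width before the wall grid; configurations with clearance comparable
  to eps or the fine mesh spacing are outside the validated regime.
- The rigid-body angular velocity above a discretised wall converges
  slowly with wall resolution (~20% at defaults relative to the image
  -system kernel, on an Omega that is itself small); trajectory-level
  quantities (stable height, oscillation amplitudes) are far less
  sensitive.
- The dense direct solver scales as O((3N+6)^3); the implementation is
  intended for single-swimmer studies, not suspensions.
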