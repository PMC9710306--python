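"""Constrained local geometry optimization and relaxed coordinate scans.

Minimization runs on the backend energy with internal-coordinate equality
constraints enforced exactly (SLSQP with analytic constraint gradients);
unconstrained problems use L-BFGS-B.  The returned frame energy is always
the bare backend energy at a geometry that satisfies every constraint to
``ctol``, which is what lets relaxed scans of separable potentials match
their closed-form profiles.

A relaxed scan steps one coordinate through an ordered list of target
values, warm-starting each constrained minimum from the previous frame;
``stitch`` joins a backward scan (activated value -> equilibrium) with a
forward scan (activated value -> maximum) into one reactant-to-product
ordered trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .backends import BackendError, EnergyGradient
from .chemsys import (
    Geometry,
    InternalCoordinate,
    coordinate_gradient,
    measure,
    superpose_rmsd,
    wrap_delta,
)

#: default convergence thresholds (Hartree/A gradient; A / degrees constraint)
GTOL = 5e-4
CTOL_DISTANCE = 0.01
CTOL_ANGLE = 0.5
MAXITER = 500


@dataclass(frozen=True)
class Constraint:
    """Hold an internal coordinate at ``target``.

    ``force_constant`` (Hartree/A^2 or Hartree/rad^2) is only used by the
    restraint-based MD integrator; the optimizer enforces the target as an
    exact equality constraint.
    """

    coordinate: InternalCoordinate
    target: float
    force_constant: float = 1.0

    def __post_init__(self):
        if self.force_constant <= 0:
            raise ValueError("force_constant must be positive")

    @property
    def ctol(self) -> float:
        return CTOL_DISTANCE if self.coordinate.kind == "distance" else CTOL_ANGLE

    def delta(self, geom: Geometry) -> float:
        """Signed deviation measure-target (A or degrees, wrapped)."""
        return wrap_delta(measure(geom, self.coordinate), self.target, self.coordinate)

    def restraint_energy_gradient(self, geom: Geometry) -> EnergyGradient:
        """Harmonic restraint 1/2 k delta^2 (delta in A or radians) + gradient."""
        d = self.delta(geom)
        dgrad = coordinate_gradient(geom, self.coordinate)
        if self.coordinate.kind != "distance":
            # coordinate_gradient is in degrees/A; restraint works in radians
            d = np.radians(d)
            dgrad = np.radians(dgrad)
        return EnergyGradient(
            energy=0.5 * self.force_constant * d * d,
            gradient=self.force_constant * d * dgrad,
        )


@dataclass
class MinimizeResult:
    """Outcome of a (constrained) minimization.

    ``geometry.energy`` is the backend energy (no penalty terms);
    ``converged`` requires both the projected-gradient and the constraint
    tolerance to be met.
    """

    geometry: Geometry
    converged: bool
    constraint_ok: bool
    grad_max: float
    n_iter: int


@dataclass
class Trajectory:
    """Ordered, energy-tagged frames with per-frame activating-coordinate values."""

    frames: list[Geometry]
    q_values: list[float]
    provenance: dict = field(default_factory=dict)
    flags: list[bool] = field(default_factory=list)  # True = frame converged

    def __post_init__(self):
        if len(self.q_values) != len(self.frames):
            raise ValueError("q_values and frames length mismatch")
        if not self.flags:
            self.flags = [True] * len(self.frames)
        if any(f.energy is None for f in self.frames):
            raise ValueError("all trajectory frames must carry energies")

    @property
    def energies(self) -> np.ndarray:
        return np.array([f.energy for f in self.frames])

    def __len__(self) -> int:
        return len(self.frames)


def _project_out(grad: np.ndarray, constraints: Sequence[Constraint], geom: Geometry) -> np.ndarray:
    """Remove the constraint-normal components from a gradient (for reporting)."""
    g = grad.ravel().copy()
    for con in constraints:
        n = coordinate_gradient(geom, con.coordinate).ravel()
        nn = n @ n
        if nn > 1e-14:
            g -= (g @ n) / nn * n
    return g.reshape(grad.shape)


def constrained_minimize(
    geom: Geometry,
    constraints: Sequence[Constraint],
    backend,
    gtol: float = GTOL,
    maxiter: int = MAXITER,
    frozen_mask: np.ndarray | None = None,
) -> MinimizeResult:
    """Minimize the backend energy subject to internal-coordinate constraints.

    ``frozen_mask`` (N x 3 boolean, True = frozen) pins individual Cartesian
    components, which is how test functions with fixed coordinates are
    handled.  Raises :class:`BackendError` on NaN energies; an exhausted
    iteration cap returns a flagged, non-converged result.
    """
    shape = geom.coords.shape
    x0 = np.array(geom.coords)
    free = (
        np.ones(shape, dtype=bool) if frozen_mask is None else ~np.asarray(frozen_mask, bool)
    )
    idx_free = np.flatnonzero(free.ravel())

    def unpack(v: np.ndarray) -> Geometry:
        x = x0.ravel().copy()
        x[idx_free] = v
        return geom.with_coords(x.reshape(shape))

    def objective(v: np.ndarray):
        g = unpack(v)
        res = backend.evaluate(g)
        if np.isnan(res.energy):
            raise BackendError("NaN energy during minimization")
        return res.energy, res.gradient.ravel()[idx_free]

    cons = []
    for con in constraints:
        def c_fun(v, con=con):
            return con.delta(unpack(v))

        def c_jac(v, con=con):
            g = unpack(v)
            return coordinate_gradient(g, con.coordinate).ravel()[idx_free]

        cons.append({"type": "eq", "fun": c_fun, "jac": c_jac})

    v0 = x0.ravel()[idx_free]
    if cons:
        res = _scipy_minimize(
            objective, v0, jac=True, method="SLSQP", constraints=cons,
            options={"maxiter": maxiter, "ftol": 1e-12},
        )
    else:
        res = _scipy_minimize(
            objective, v0, jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-14},
        )
    final = unpack(res.x)
    eg = backend.evaluate(final)
    final = final.with_energy(eg.energy)
    proj = _project_out(eg.gradient, constraints, final)
    proj[~free] = 0.0
    grad_max = float(np.abs(proj).max()) if proj.size else 0.0
    constraint_ok = all(abs(con.delta(final)) <= con.ctol for con in constraints)
    converged = bool(constraint_ok and grad_max <= gtol)
    return MinimizeResult(
        geometry=final,
        converged=converged,
        constraint_ok=constraint_ok,
        grad_max=grad_max,
        n_iter=int(res.get("nit", 0)),
    )


def _displace_to_target(geom: Geometry, coord: InternalCoordinate, target: float) -> Geometry:
    """Warm-start helper: move a distance coordinate rigidly onto its target."""
    if coord.kind != "distance":
        return geom
    i, j = coord.atoms
    x = np.array(geom.coords)
    d = x[i] - x[j]
    r = np.linalg.norm(d)
    if r < 1e-10:
        return geom
    shift = 0.5 * (target - r) * d / r
    x[i] += shift
    x[j] -= shift
    return geom.with_coords(x)


def relaxed_scan(
    geom: Geometry,
    coordinate: InternalCoordinate,
    values: Sequence[float],
    backend,
    provenance: dict | None = None,
    gtol: float = GTOL,
    maxiter: int = MAXITER,
) -> Trajectory:
    """Scan ``coordinate`` through ``values``, constrained-minimizing at each.

    Each frame is warm-started from the previous one (displaced onto the new
    target for distances).  Non-converged frames are kept but flagged so that
    post-processing can exclude their transition-structure candidates.
    """
    values = [float(v) for v in values]
    diffs = np.diff(values)
    if len(values) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("scan values must be strictly monotone")
    frames: list[Geometry] = []
    qs: list[float] = []
    flags: list[bool] = []
    current = geom
    for v in values:
        start = _displace_to_target(current, coordinate, v)
        result = constrained_minimize(
            start, [Constraint(coordinate, v)], backend, gtol=gtol, maxiter=maxiter
        )
        current = result.geometry
        frames.append(current)
        qs.append(measure(current, coordinate))
        flags.append(result.converged)
    return Trajectory(frames=frames, q_values=qs, provenance=provenance or {}, flags=flags)


def stitch(backward: Trajectory, forward: Trajectory, junction_rmsd_tol: float = 0.05) -> Trajectory:
    """Join a backward scan (q_i -> q_0) and a forward scan (q_i -> q_N).

    Both scans must originate from the same activated conformer; the
    duplicate junction frame is dropped and the result is ordered
    reactant -> product (q_0 ... q_N).
    """
    if not backward.frames or not forward.frames:
        raise ValueError("cannot stitch empty trajectories")
    rmsd, _, _ = superpose_rmsd(backward.frames[0], forward.frames[0])
    if rmsd > junction_rmsd_tol:
        raise ValueError(
            f"junction mismatch: backward/forward scans start {rmsd:.3f} A apart "
            f"(tolerance {junction_rmsd_tol} A)"
        )
    frames = list(reversed(backward.frames)) + list(forward.frames[1:])
    qs = list(reversed(backward.q_values)) + list(forward.q_values[1:])
    flags = list(reversed(backward.flags)) + list(forward.flags[1:])
    prov = {"backward": backward.provenance, "forward": forward.provenance}
    return Trajectory(frames=frames, q_values=qs, provenance=prov, flags=flags)
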