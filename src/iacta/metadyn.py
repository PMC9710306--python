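"""Constrained metadynamics for activated-conformer generation.

Molecular dynamics with a history-dependent bias built from Gaussian
kernels in RMSD space,

    V_bias(x) = sum_i k * exp(-alpha * Delta_i^2),

where ``Delta_i`` is the minimum rigid-body-superposed RMSD between the
current structure and the i-th stored snapshot.  The repulsive kernels push
the dynamics away from previously visited conformations, while a harmonic
restraint holds the activating coordinate near its scheduled value so that
only the orthogonal conformational space is explored.

Integration is velocity Verlet with a Berendsen thermostat.  All randomness
(Maxwell-Boltzmann initial velocities) flows from the seed in
:class:`MDParams`, so identical inputs reproduce identical snapshot lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .backends import EnergyGradient
from .chemsys import Geometry, rmsd_gradient, superpose_rmsd
from .optimize import Constraint
from .units import ACCEL_FACTOR, KB_HARTREE

#: runaway guard: abort when the potential rises this far above the start (Hartree)
ENERGY_SANITY_BOUND = 10.0


@dataclass(frozen=True)
class BiasParams:
    """Metadynamics kernel parameters.

    ``k`` is the kernel height in Hartree; with ``per_atom=True`` (the
    default) it is multiplied by the atom count, following common practice
    for system-size-independent push strength.  ``alpha`` is the kernel
    width in 1/A^2.  A snapshot is added to the bias every
    ``snapshot_interval`` fs up to ``max_snapshots`` kernels (sampling
    continues; the bias simply stops growing).
    """

    k: float = 0.002
    per_atom: bool = True
    alpha: float = 0.8
    snapshot_interval: float = 50.0
    max_snapshots: int = 100
    heavy_only: bool = False

    def __post_init__(self):
        if self.k <= 0 or self.alpha <= 0 or self.snapshot_interval <= 0:
            raise ValueError("k, alpha and snapshot_interval must be positive")
        if self.max_snapshots < 1:
            raise ValueError("max_snapshots must be >= 1")

    def height(self, natoms: int) -> float:
        return self.k * natoms if self.per_atom else self.k


@dataclass(frozen=True)
class MDParams:
    """Molecular-dynamics parameters (fs, K, ps).

    ``wall_radius`` (A), when set, applies a quartic confining wall about
    the initial centroid — the standard trick for keeping loosely bound
    fragments of a reactive complex together during conformer generation.
    ``temperature = 0`` disables the thermostat and starts from rest.
    """

    timestep: float = 0.5
    temperature: float = 300.0
    total_time: float = 1.0
    thermostat_tau: float = 50.0
    seed: int = 0
    wall_radius: float | None = None
    wall_k: float = 0.1

    def __post_init__(self):
        if self.timestep <= 0 or self.total_time <= 0 or self.thermostat_tau <= 0:
            raise ValueError("timestep, total_time and thermostat_tau must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")


@dataclass
class BiasState:
    """Ordered snapshot geometries whose kernels make up the bias."""

    snapshots: list[Geometry] = field(default_factory=list)

    def add(self, geom: Geometry):
        if self.snapshots and self.snapshots[0].elements != geom.elements:
            raise ValueError("snapshot element sequence mismatch")
        self.snapshots.append(geom)


def bias_energy_gradient(geom: Geometry, state: BiasState, params: BiasParams) -> EnergyGradient:
    """Bias energy and gradient from the stored kernels.

    Empty history gives exactly zero; a snapshot identical to the current
    geometry contributes exactly ``k`` (Delta = 0).  The gradient flows
    through the analytic RMSD gradient by the chain rule; at Delta = 0 both
    the RMSD gradient and the ``2 alpha Delta`` prefactor vanish.
    """
    k = params.height(geom.natoms)
    energy = 0.0
    grad = np.zeros_like(geom.coords)
    for snap in state.snapshots:
        delta, _, _ = superpose_rmsd(geom, snap, heavy_only=params.heavy_only)
        w = k * math.exp(-params.alpha * delta * delta)
        energy += w
        if delta > 0.0:
            grad += w * (-2.0 * params.alpha * delta) * rmsd_gradient(
                geom, snap, heavy_only=params.heavy_only
            )
    return EnergyGradient(energy=energy, gradient=grad)


def _wall_energy_gradient(coords: np.ndarray, center: np.ndarray, radius: float, k: float):
    d = np.linalg.norm(coords - center, axis=1)
    over = np.maximum(d - radius, 0.0)
    energy = float(k * (over**4).sum())
    grad = np.zeros_like(coords)
    mask = over > 0
    if mask.any():
        grad[mask] = (4.0 * k * over[mask] ** 3 / d[mask])[:, None] * (coords[mask] - center)
    return energy, grad


@dataclass
class MetadynamicsResult:
    """Snapshots sampled along the biased run plus diagnostics."""

    snapshots: list[Geometry]
    bias_state: BiasState
    truncated: bool = False
    #: (step, n_kernels, bias energy) rows for debugging
    bias_log: list[tuple[int, int, float]] = field(default_factory=list)


def run_metadynamics(
    start: Geometry,
    constraint: Constraint | None,
    md: MDParams,
    bias: BiasParams,
    backend,
    trajectory_out: list | None = None,
) -> MetadynamicsResult:
    """Propagate RMSD-biased, restrained MD and harvest snapshots.

    The first kernel is deposited at the starting structure; further
    snapshots are appended every ``bias.snapshot_interval`` fs.  On an
    energy explosion (non-finite or far above the initial energy) the run
    truncates and returns the snapshots collected so far, flagged.
    """
    rng = np.random.default_rng(md.seed)
    x = np.array(start.coords)
    masses = start.masses[:, None]
    dt = md.timestep
    nsteps = int(round(md.total_time * 1000.0 / dt))
    snap_every = max(1, int(round(bias.snapshot_interval / dt)))

    if md.temperature > 0:
        sigma = np.sqrt(KB_HARTREE * md.temperature / masses * ACCEL_FACTOR)  # A/fs
        v = rng.normal(size=x.shape) * sigma
        v -= (masses * v).sum(axis=0) / masses.sum()  # remove COM drift
    else:
        v = np.zeros_like(x)

    center = x.mean(axis=0)
    state = BiasState()
    state.add(start)
    snapshots: list[Geometry] = []
    truncated = False
    bias_log: list[tuple[int, int, float]] = []
    ndof = max(1, 3 * start.natoms - 3)

    def forces(geom: Geometry):
        eg = backend.evaluate(geom)
        total_e = eg.energy
        total_g = np.array(eg.gradient)
        beg = bias_energy_gradient(geom, state, bias)
        total_g += beg.gradient
        if constraint is not None:
            reg = constraint.restraint_energy_gradient(geom)
            total_g += reg.gradient
        if md.wall_radius is not None:
            we, wg = _wall_energy_gradient(geom.coords, center, md.wall_radius, md.wall_k)
            total_g += wg
        return eg.energy, beg.energy, total_g

    geom = start
    e_pot, e_bias, g = forces(geom)
    e_start = e_pot
    a = -g / masses * ACCEL_FACTOR  # A/fs^2

    for step in range(1, nsteps + 1):
        v_half = v + 0.5 * dt * a
        x = x + dt * v_half
        geom = start.with_coords(x)
        e_pot, e_bias, g = forces(geom)
        if not np.isfinite(e_pot) or e_pot > e_start + ENERGY_SANITY_BOUND:
            truncated = True
            break
        a = -g / masses * ACCEL_FACTOR
        v = v_half + 0.5 * dt * a
        if md.temperature > 0:
            ekin = 0.5 * (masses * v * v).sum() / ACCEL_FACTOR  # Hartree
            t_inst = 2.0 * ekin / (ndof * KB_HARTREE)
            if t_inst > 1e-12:
                lam = math.sqrt(
                    max(0.0, 1.0 + dt / md.thermostat_tau * (md.temperature / t_inst - 1.0))
                )
                v *= lam
        if trajectory_out is not None:
            trajectory_out.append(geom.with_energy(e_pot))
        if step % snap_every == 0:
            snap = geom.with_energy(e_pot)
            snapshots.append(snap)
            if len(state.snapshots) < bias.max_snapshots:
                state.add(snap)
            bias_log.append((step, len(state.snapshots), e_bias))

    return MetadynamicsResult(
        snapshots=snapshots, bias_state=state, truncated=truncated, bias_log=bias_log
    )
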