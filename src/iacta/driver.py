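"""Workflow orchestration: the four-step imposed-activation search.

1. Optimize the input, measure the activating coordinate's equilibrium
   value q0, and build the reactant conformer ensemble by constrained
   metadynamics at q0 (the activation-energy reference).
2. For each activated value q_i, drive a relaxed scan q0 -> q_i and run a
   shorter constrained metadynamics at q_i.
3. From every pruned activated conformer, scan forward to the maximal
   value qN and backward to q0, and stitch the scans into one
   reactant -> product trajectory.
4. Re-optimize trajectory minima, detect SMILES changes, and aggregate all
   events into a reaction table with transition-structure guesses and
   estimated barriers.

The scheduled metadynamics time is proportional to the atom count, and all
randomness flows from the run seed through a documented per-trajectory
derivation, so trajectories are reproducible and embarrassingly parallel.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .backends import BackendError
from .chemsys import ActivationSchedule, Geometry, InternalCoordinate, measure, write_xyz
from .ensemble import ConformerEnsemble, PruneThresholds, optimize_and_prune
from .metadyn import BiasParams, MDParams, run_metadynamics
from .optimize import Constraint, Trajectory, constrained_minimize, relaxed_scan, stitch
from .reactions import ReactionTable, aggregate, extract_reactions

log = logging.getLogger(__name__)

_SEED_MOD = 2**31 - 1


def derive_seed(base: int, qi_index: int, conformer_index: int) -> int:
    """Deterministic per-trajectory seed (parallel-safe, documented)."""
    return (base * 1_000_003 + (qi_index + 1) * 8191 + (conformer_index + 1) * 127) % _SEED_MOD


@dataclass
class RunConfig:
    """Everything a reaction search needs.

    The activated values default to multiplicative stretch factors of the
    equilibrium value (``qi_values`` overrides with absolute values), and
    the scheduled metadynamics time is ``md_time_per_atom_ps`` times the
    atom count.  ``trajectory_budget`` caps the number of stitched
    trajectories over the whole run.
    """

    geometry: Geometry
    coordinate: InternalCoordinate
    backend: object
    stretch_factors: tuple[float, ...] = (1.1, 1.2, 1.3, 1.5)
    qi_values: tuple[float, ...] | None = None
    qmax_factor: float = 2.5
    qmax: float | None = None
    scan_step: float = 0.1
    md: MDParams = field(default_factory=MDParams)
    md_time_per_atom_ps: float = 0.3
    #: harmonic restraint stiffness holding q-dagger during MD (Hartree/A^2);
    #: stiffer than the generic default so snapshots stay near the target
    #: even on the steep slope of a stretched bond
    md_restraint_k: float = 8.0
    bias: BiasParams = field(default_factory=BiasParams)
    prune: PruneThresholds = field(default_factory=PruneThresholds)
    trajectory_budget: int = 100
    max_conformers_per_qi: int | None = None
    drop_metals: bool = False
    seed: int = 42
    out_dir: str | None = None

    def validate(self):
        if self.trajectory_budget < 1:
            raise ValueError("trajectory_budget must be >= 1")
        if self.scan_step <= 0:
            raise ValueError("scan_step must be positive")
        if self.qi_values is None and not self.stretch_factors:
            raise ValueError("need stretch_factors or explicit qi_values")
        # trips index errors before any backend work
        measure(self.geometry, self.coordinate)

    def echo(self) -> dict:
        d = {
            "coordinate": {"kind": self.coordinate.kind, "atoms": self.coordinate.atoms},
            "stretch_factors": list(self.stretch_factors),
            "qi_values": list(self.qi_values) if self.qi_values else None,
            "qmax_factor": self.qmax_factor,
            "qmax": self.qmax,
            "scan_step": self.scan_step,
            "md": dataclasses.asdict(self.md),
            "md_time_per_atom_ps": self.md_time_per_atom_ps,
            "bias": dataclasses.asdict(self.bias),
            "prune": dataclasses.asdict(self.prune),
            "md_restraint_k": self.md_restraint_k,
            "trajectory_budget": self.trajectory_budget,
            "max_conformers_per_qi": self.max_conformers_per_qi,
            "drop_metals": self.drop_metals,
            "seed": self.seed,
            "backend": type(self.backend).__name__,
            "natoms": self.geometry.natoms,
            "charge": self.geometry.charge,
            "multiplicity": self.geometry.multiplicity,
        }
        return d


@dataclass
class Step1Result:
    equilibrium: Geometry
    q0: float
    reactant_ensemble: ConformerEnsemble


@dataclass
class RunReport:
    """Reaction table plus the run's bookkeeping.

    The trajectory ledger satisfies launched = completed + flagged + failed;
    flagged trajectories completed but contain non-converged frames or a
    truncated metadynamics stage.
    """

    table: ReactionTable
    q0: float
    qN: float
    qi_values: list[float]
    ensemble_sizes: dict
    ledger: dict
    config: dict
    wall_time_s: float


def _scan_values(q_from: float, q_to: float, step: float) -> list[float]:
    """Monotone ladder q_from -> q_to inclusive with spacing <= step."""
    span = q_to - q_from
    if abs(span) < 1e-12:
        return [q_from]
    n = max(1, int(np.ceil(abs(span) / step)))
    return list(np.linspace(q_from, q_to, n + 1))


def _md_with(md: MDParams, total_time: float, seed: int) -> MDParams:
    return dataclasses.replace(md, total_time=total_time, seed=seed)


def step1_initialize(config: RunConfig) -> Step1Result:
    """Optimize the input, measure q0, and build the reactant ensemble."""
    config.validate()
    try:
        probe = config.backend.evaluate(config.geometry)
    except BackendError as exc:
        raise BackendError(f"backend probe evaluation failed: {exc}") from exc
    if not np.isfinite(probe.energy):
        raise BackendError("backend probe returned non-finite energy")

    relaxed = constrained_minimize(config.geometry, [], config.backend).geometry
    q0 = measure(relaxed, config.coordinate)
    constraint = Constraint(config.coordinate, q0, force_constant=config.md_restraint_k)
    total_time = config.md_time_per_atom_ps * config.geometry.natoms
    mdres = run_metadynamics(
        relaxed, constraint,
        _md_with(config.md, total_time, derive_seed(config.seed, -1, -1)),
        config.bias, config.backend,
    )
    snapshots = [relaxed] + mdres.snapshots
    ensemble = optimize_and_prune(snapshots, constraint, config.backend, config.prune)
    if not ensemble.members:
        # the optimized input is always a valid reactant conformer
        ensemble = ConformerEnsemble(members=[relaxed], constraint=constraint)
    return Step1Result(equilibrium=relaxed, q0=q0, reactant_ensemble=ensemble)


def run_iacta(config: RunConfig) -> RunReport:
    """Execute the full four-step search and aggregate the reaction table.

    Individual trajectory failures are recorded in the ledger and skipped;
    the run raises only if no trajectory completes at all.
    """
    t0 = time.perf_counter()
    config.validate()
    step1 = step1_initialize(config)
    q0 = step1.q0
    qN = config.qmax if config.qmax is not None else config.qmax_factor * q0
    qi_values = (
        list(config.qi_values)
        if config.qi_values is not None
        else [f * q0 for f in config.stretch_factors]
    )
    # the schedule type validates monotonicity of q0 < q_i < ... < qN
    schedule = ActivationSchedule(
        coordinate=config.coordinate, q0=q0, intermediates=tuple(qi_values),
        qN=qN, scan_step=config.scan_step,
    )
    best_reactant = step1.reactant_ensemble.members[0]
    total_md_time = config.md_time_per_atom_ps * config.geometry.natoms

    ledger = {"launched": 0, "completed": 0, "flagged": 0, "failed": 0}
    ensemble_sizes: dict[str, int] = {}
    events = []
    trajectories: list[Trajectory] = []
    budget_left = config.trajectory_budget

    for iq, qi in enumerate(qi_values):
        if budget_left <= 0:
            break
        # step 2 prep: drive the best reactant conformer out to q_i
        approach = relaxed_scan(
            best_reactant, config.coordinate, _scan_values(q0, qi, config.scan_step),
            config.backend, provenance={"stage": "approach", "qi": qi},
        )
        activated_start = approach.frames[-1]
        constraint = Constraint(config.coordinate, qi, force_constant=config.md_restraint_k)
        mdres = run_metadynamics(
            activated_start, constraint,
            _md_with(config.md, total_md_time, derive_seed(config.seed, iq, -1)),
            config.bias, config.backend,
        )
        snapshots = [activated_start] + mdres.snapshots
        ensemble = optimize_and_prune(snapshots, constraint, config.backend, config.prune)
        members = ensemble.members
        if config.max_conformers_per_qi is not None:
            members = members[: config.max_conformers_per_qi]
        ensemble_sizes[f"{qi:.4f}"] = len(members)

        for ic, conformer in enumerate(members):
            if budget_left <= 0:
                break
            ledger["launched"] += 1
            budget_left -= 1
            tid = f"q{iq}_c{ic}"
            try:
                forward = relaxed_scan(
                    conformer, config.coordinate, _scan_values(qi, qN, config.scan_step),
                    config.backend, provenance={"id": tid + "_fwd"},
                )
                backward = relaxed_scan(
                    conformer, config.coordinate, _scan_values(qi, q0, config.scan_step),
                    config.backend, provenance={"id": tid + "_bwd"},
                )
                traj = stitch(backward, forward)
                traj.provenance = {"id": tid, "qi": qi, "seed": derive_seed(config.seed, iq, ic)}
                trajectories.append(traj)
                events.extend(
                    extract_reactions(traj, config.backend, drop_metals=config.drop_metals)
                )
            except (BackendError, ValueError) as exc:
                log.warning("trajectory %s failed: %s", tid, exc)
                ledger["failed"] += 1
                continue
            if mdres.truncated or not all(traj.flags):
                ledger["flagged"] += 1
            else:
                ledger["completed"] += 1

    if ledger["completed"] + ledger["flagged"] == 0:
        raise RuntimeError("no trajectory completed; see ledger and logs")

    table = aggregate(events, step1.reactant_ensemble)
    report = RunReport(
        table=table,
        q0=q0,
        qN=qN,
        qi_values=qi_values,
        ensemble_sizes={"reactant": len(step1.reactant_ensemble), **ensemble_sizes},
        ledger=ledger,
        config=config.echo(),
        wall_time_s=time.perf_counter() - t0,
    )
    if config.out_dir is not None:
        _write_outputs(config, report, step1, trajectories)
    return report


def _write_outputs(config: RunConfig, report: RunReport, step1: Step1Result,
                   trajectories: list[Trajectory]):
    out = Path(config.out_dir)
    (out / "ts").mkdir(parents=True, exist_ok=True)
    (out / "ensembles").mkdir(exist_ok=True)
    (out / "trajectories").mkdir(exist_ok=True)
    for i, row in enumerate(report.table.rows):
        path = out / "ts" / f"reaction_{i:03d}.xyz"
        write_xyz(path, row.best_ts)
        row.ts_xyz_path = str(path.relative_to(out))
    report.table.to_csv(out / "reactions.csv")
    report.table.to_json(out / "reactions.json")
    write_xyz(out / "ensembles" / "reactant.xyz", step1.reactant_ensemble.members)
    for traj in trajectories:
        tid = traj.provenance.get("id", "traj")
        comments = [f"q={q:.6f}" for q in traj.q_values]
        write_xyz(out / "trajectories" / f"{tid}.xyz", traj.frames, comments=comments)
    with open(out / "report.json", "w") as fh:
        json.dump(
            {
                "q0": report.q0,
                "qN": report.qN,
                "qi_values": report.qi_values,
                "ensemble_sizes": report.ensemble_sizes,
                "ledger": report.ledger,
                "config": report.config,
                "wall_time_s": report.wall_time_s,
                "n_reactions": len(report.table),
            },
            fh, indent=1,
        )
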