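"""Pruning of metadynamics snapshots into a distinct-conformer ensemble.

Snapshots are first constrained-minimized, then deduplicated: two conformers
are the same iff their superposed RMSD, energy gap, and (finite) rotational
constants are all within their thresholds.  The lower-energy member of a
duplicate pair is kept (ties break to the earlier snapshot).  Finally,
members lying more than ``ewin`` above the ensemble best are discarded.
Comparison happens after re-optimization, so the thresholds act on relaxed
structures.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .backends import BackendError
from .chemsys import Geometry, rotational_constants, superpose_rmsd
from .optimize import Constraint, constrained_minimize
from .units import HARTREE_TO_KCAL

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PruneThresholds:
    """Duplicate-detection and energy-window thresholds.

    rmsd_thr: A; energy_thr: kcal/mol (duplicate window); rotconst_rel_thr:
    relative fraction on finite rotational constants; ewin: kcal/mol above
    the best member beyond which conformers are dropped.
    """

    rmsd_thr: float = 0.125
    energy_thr: float = 0.05
    rotconst_rel_thr: float = 0.01
    ewin: float = 35.0

    def __post_init__(self):
        if min(self.rmsd_thr, self.energy_thr, self.rotconst_rel_thr, self.ewin) <= 0:
            raise ValueError("all pruning thresholds must be positive")


@dataclass
class ConformerEnsemble:
    """Distinct conformers sorted ascending by energy, sharing one constraint."""

    members: list[Geometry]
    constraint: Constraint | None = None

    @property
    def best_energy(self) -> float | None:
        return self.members[0].energy if self.members else None

    def __len__(self) -> int:
        return len(self.members)


def _same_rotconsts(ca: np.ndarray, cb: np.ndarray, rel_thr: float) -> bool:
    fa = ca[np.isfinite(ca)]
    fb = cb[np.isfinite(cb)]
    if len(fa) != len(fb) or np.isfinite(ca).sum() != np.isfinite(cb).sum():
        return False
    denom = np.maximum(np.abs(fa), np.abs(fb))
    denom[denom == 0] = 1.0
    return bool(np.all(np.abs(fa - fb) <= rel_thr * denom))


def _is_duplicate(a: Geometry, b: Geometry, ca, cb, thr: PruneThresholds) -> bool:
    de_kcal = abs(a.energy - b.energy) * HARTREE_TO_KCAL
    if de_kcal >= thr.energy_thr:
        return False
    rmsd, _, _ = superpose_rmsd(a, b)
    if rmsd >= thr.rmsd_thr:
        return False
    return _same_rotconsts(ca, cb, thr.rotconst_rel_thr)


def optimize_and_prune(
    snapshots: list[Geometry],
    constraint: Constraint | None,
    backend,
    thr: PruneThresholds = PruneThresholds(),
    report_path=None,
    **opt_kwargs,
) -> ConformerEnsemble:
    """Constrained-minimize snapshots and prune to distinct conformers.

    Non-converging snapshots are dropped (with a warning); if nothing
    optimizes, an empty ensemble is returned rather than raising.  An
    optional CSV pruning report records the fate of every snapshot.
    """
    if not snapshots:
        raise ValueError("no snapshots to prune")
    cons = [constraint] if constraint is not None else []
    optimized: list[tuple[int, Geometry]] = []
    report: list[tuple[int, str, str]] = []
    for idx, snap in enumerate(snapshots):
        try:
            result = constrained_minimize(snap, cons, backend, **opt_kwargs)
        except BackendError as exc:
            report.append((idx, "dropped", f"optimization error: {exc}"))
            continue
        if not result.converged:
            report.append((idx, "dropped", "not converged"))
            continue
        optimized.append((idx, result.geometry))
    if not optimized:
        log.warning("all %d snapshots failed optimization; empty ensemble", len(snapshots))
        _write_report(report_path, report)
        return ConformerEnsemble(members=[], constraint=constraint)

    # ascending energy, ties broken by original snapshot order
    optimized.sort(key=lambda t: (t[1].energy, t[0]))
    rotconsts = {idx: rotational_constants(g) if g.natoms > 1 else np.array([])
                 for idx, g in optimized}
    kept: list[tuple[int, Geometry]] = []
    for idx, g in optimized:
        dup_of = None
        for kidx, kg in kept:
            if _is_duplicate(g, kg, rotconsts[idx], rotconsts[kidx], thr):
                dup_of = kidx
                break
        if dup_of is None:
            kept.append((idx, g))
            report.append((idx, "kept", ""))
        else:
            report.append((idx, "dropped", f"duplicate of snapshot {dup_of}"))

    best = kept[0][1].energy
    members: list[Geometry] = []
    for idx, g in kept:
        if (g.energy - best) * HARTREE_TO_KCAL > thr.ewin:
            report.append((idx, "dropped", "above energy window"))
        else:
            members.append(g)
    _write_report(report_path, report)
    return ConformerEnsemble(members=members, constraint=constraint)


def _write_report(path, rows):
    if path is None:
        return
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["snapshot_index", "fate", "reason"])
        w.writerows(rows)
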