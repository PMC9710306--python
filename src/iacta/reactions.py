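"""Trajectory post-processing: from frames to a ranked reaction table.

Bonds are perceived geometrically (distance <= scale * sum of covalent
radii), the resulting single-bond molecular graph is converted to canonical
SMILES (fragments sorted lexicographically and dot-joined), and a reaction
event is recorded wherever two consecutive energy minima of a trajectory
map to different SMILES.  The transition-structure guess of an event is the
highest-energy frame strictly between its two minima; aggregation over all
trajectories keeps, per reaction, the lowest-energy transition structure
and reports the estimated activation energy relative to the most stable
reactant conformer found.

Bond orders are not perceived: every bond enters the graph as a single
bond, with formal charges and unpaired electrons assigned by a valence-rule
pass.  Constitution changes — what the reaction detector compares — are
insensitive to this; fragments whose valence pattern cannot be sanitized
fall back to a charge-annotated formula string (deterministic, logged).
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .chemsys import Geometry, covalent_radius, element_symbol
from .ensemble import ConformerEnsemble
from .optimize import Trajectory, constrained_minimize
from .units import HARTREE_TO_KCAL

log = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

#: d-block elements removed before SMILES conversion when ``drop_metals`` is
#: set (the metal centre of a complex would otherwise report spurious bond
#: changes on every ligand rearrangement).
DEFAULT_METALS = frozenset(range(21, 31)) | frozenset(range(39, 49)) | frozenset(range(72, 81))

BOND_SCALE = 1.2

_DEFAULT_VALENCE = {
    1: 1, 2: 0, 5: 3, 6: 4, 7: 3, 8: 2, 9: 1, 10: 0,
    13: 3, 14: 4, 15: 3, 16: 2, 17: 1, 18: 0, 35: 1, 36: 0, 53: 1, 54: 0,
}

# priority for distributing residual negative / positive charge
_ANION_PRIORITY = [8, 16, 9, 17, 35, 53, 7, 15, 6, 14, 5, 1]
_CATION_PRIORITY = [7, 15, 16, 8, 6, 14, 5, 1]


def perceive_bonds(geom: Geometry, scale: float = BOND_SCALE) -> nx.Graph:
    """Geometric bond perception into an undirected molecular graph.

    An edge joins atoms i, j iff their distance is <= ``scale`` times the
    sum of their covalent radii.  Node attributes carry the element; the
    graph attribute ``charge`` carries the total charge.
    """
    g = nx.Graph(charge=geom.charge, multiplicity=geom.multiplicity)
    radii = [covalent_radius(z) for z in geom.elements]
    for i, z in enumerate(geom.elements):
        g.add_node(i, element=z, symbol=element_symbol(z))
    x = geom.coords
    for i in range(geom.natoms):
        for j in range(i + 1, geom.natoms):
            r = float(np.linalg.norm(x[i] - x[j]))
            if r <= scale * (radii[i] + radii[j]):
                g.add_edge(i, j, length=r)
    return g


def _effective_valence(z: int, charge: int) -> int:
    val = _DEFAULT_VALENCE.get(z)
    if val is None:
        raise KeyError(z)
    if charge == 0:
        return val
    if z in (6, 14):  # group 14: both cation and anion lose a bond
        return val - abs(charge)
    return val + charge  # N+ -> 4, O- -> 1, etc.


def _assign_charges(graph: nx.Graph, atoms: list[int], total_charge: int) -> dict[int, int]:
    """Distribute the total charge over atoms by simple valence rules."""
    charges = {a: 0 for a in atoms}
    # step 1: over-valent electronegative atoms take positive charge (R3O+, R4N+)
    for a in atoms:
        z = graph.nodes[a]["element"]
        val = _DEFAULT_VALENCE.get(z)
        if val is None:
            raise KeyError(z)
        dv = graph.degree(a) - val
        if dv > 0 and z in (7, 8, 15, 16, 9, 17, 35, 53):
            charges[a] = dv
    residual = total_charge - sum(charges.values())

    def deficient(a: int) -> bool:
        z = graph.nodes[a]["element"]
        return graph.degree(a) < _effective_valence(z, charges[a])

    priority = _ANION_PRIORITY if residual < 0 else _CATION_PRIORITY
    step = -1 if residual < 0 else 1
    guard = 0
    while residual != 0 and guard < 64:
        guard += 1
        placed = False
        for z_want in priority:
            for a in atoms:
                if graph.nodes[a]["element"] == z_want and deficient(a):
                    charges[a] += step
                    residual -= step
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise ValueError("cannot place residual charge")
    if residual != 0:
        raise ValueError("cannot place residual charge")
    return charges


def _fragment_formula(graph: nx.Graph, atoms: list[int], charge: int) -> str:
    counts = Counter(graph.nodes[a]["symbol"] for a in atoms)
    formula = "".join(
        f"{s}{counts[s] if counts[s] > 1 else ''}" for s in sorted(counts)
    )
    return f"!{formula}{charge:+d}" if charge else f"!{formula}"


def _fragment_smiles(graph: nx.Graph, atoms: list[int], charges: dict[int, int]) -> str:
    mol = Chem.RWMol()
    index = {}
    for a in atoms:
        atom = Chem.Atom(int(graph.nodes[a]["element"]))
        atom.SetFormalCharge(charges[a])
        atom.SetNoImplicit(True)
        z = graph.nodes[a]["element"]
        rad = _effective_valence(z, charges[a]) - graph.degree(a)
        if rad < 0:
            raise ValueError(f"over-valent atom Z={z} with degree {graph.degree(a)}")
        atom.SetNumRadicalElectrons(rad)
        index[a] = mol.AddAtom(atom)
    for i, j in graph.subgraph(atoms).edges:
        mol.AddBond(index[i], index[j], Chem.BondType.SINGLE)
    m = mol.GetMol()
    Chem.SanitizeMol(m)
    m = Chem.RemoveHs(m, sanitize=True)
    return Chem.MolToSmiles(m)


def to_canonical_smiles(
    geom: Geometry,
    drop_metals: bool = False,
    scale: float = BOND_SCALE,
    metals: frozenset = DEFAULT_METALS,
) -> str:
    """Canonical, fragment-sorted SMILES of a 3-D structure.

    Fragments (connected components of the perceived bond graph) are
    canonicalized independently, sorted lexicographically, and dot-joined,
    so bimolecular complexes compare equal regardless of atom order.  With
    ``drop_metals``, atoms in ``metals`` are deleted before perception.
    Fragments that cannot be canonicalized yield a deterministic
    ``!``-prefixed formula sentinel (logged), never an exception.
    """
    if drop_metals and any(z in metals for z in geom.elements):
        keep = [i for i, z in enumerate(geom.elements) if z not in metals]
        geom = Geometry(
            tuple(geom.elements[i] for i in keep),
            geom.coords[keep],
            charge=geom.charge,
            multiplicity=geom.multiplicity,
        )
    graph = perceive_bonds(geom, scale=scale)
    components = [sorted(c) for c in nx.connected_components(graph)]
    try:
        charges = _assign_charges(graph, sorted(graph.nodes), geom.charge)
    except (ValueError, KeyError) as exc:
        log.info("charge assignment failed (%s); formula fallback for all fragments", exc)
        charges = None
    pieces = []
    for atoms in components:
        if charges is None:
            pieces.append(_fragment_formula(graph, atoms, 0))
            continue
        frag_charge = sum(charges[a] for a in atoms)
        try:
            pieces.append(_fragment_smiles(graph, atoms, charges))
        except (ValueError, RuntimeError, Chem.rdchem.MolSanitizeException) as exc:
            log.info("SMILES fallback for fragment %s: %s", atoms, exc)
            pieces.append(_fragment_formula(graph, atoms, frag_charge))
    return ".".join(sorted(pieces))


# ---------------------------------------------------------------------------
# trajectory parsing


def locate_minima(traj: Trajectory | list[float]) -> list[int]:
    """Indices of local minima of the frame-energy sequence.

    Endpoints count as minima when the profile rises (or stays level) away
    from them; interior plateaus are not minima unless they dip below a
    neighbour on at least one side.  A constant profile yields the two
    endpoints only.
    """
    e = traj.energies if isinstance(traj, Trajectory) else np.asarray(traj, float)
    n = len(e)
    if n < 2:
        raise ValueError("need at least two frames with energies")
    minima = []
    for i in range(n):
        left = e[i - 1] if i > 0 else None
        right = e[i + 1] if i < n - 1 else None
        if left is None:
            if right >= e[i]:
                minima.append(i)
        elif right is None:
            if left >= e[i]:
                minima.append(i)
        else:
            if left >= e[i] and right >= e[i] and (left > e[i] or right > e[i]):
                minima.append(i)
    return minima


@dataclass
class ReactionEvent:
    """One reactive segment of a trajectory: minimum -> barrier -> minimum."""

    reactant_smiles: str
    product_smiles: str
    trajectory_id: str
    reactant_frame_index: int
    product_frame_index: int
    ts_frame_index: int
    ts_geometry: Geometry
    ts_energy: float
    reactant_energy: float
    product_energy: float
    ts_converged: bool = True


def extract_reactions(
    traj: Trajectory,
    backend,
    drop_metals: bool = False,
    scale: float = BOND_SCALE,
    **opt_kwargs,
) -> list[ReactionEvent]:
    """Parse a stitched reactant->product trajectory into reaction events.

    Every trajectory minimum is first re-optimized without constraints (a
    stability check: a minimum that relaxes to a different species is
    re-labelled with the relaxed species and logged).  Consecutive minima
    with different SMILES yield one event whose transition-structure guess
    is the highest-energy frame strictly between them (tie -> earliest).
    """
    minima = locate_minima(traj)
    relaxed: list[tuple[int, Geometry, str]] = []
    for idx in minima:
        result = constrained_minimize(traj.frames[idx], [], backend, **opt_kwargs)
        smi = to_canonical_smiles(result.geometry, drop_metals=drop_metals, scale=scale)
        raw_smi = to_canonical_smiles(traj.frames[idx], drop_metals=drop_metals, scale=scale)
        if smi != raw_smi:
            log.info(
                "unstable intermediate at frame %d: %s relaxed to %s", idx, raw_smi, smi
            )
        relaxed.append((idx, result.geometry, smi))

    tid = _trajectory_id(traj)
    energies = traj.energies
    events: list[ReactionEvent] = []
    for (i1, g1, s1), (i2, g2, s2) in zip(relaxed, relaxed[1:]):
        if s1 == s2:
            continue
        lo, hi = (i1 + 1, i2) if i2 > i1 + 1 else (i1, i2 + 1)
        seg = energies[lo:hi]
        ts_idx = lo + int(np.argmax(seg))  # argmax returns the earliest tie
        events.append(
            ReactionEvent(
                reactant_smiles=s1,
                product_smiles=s2,
                trajectory_id=tid,
                reactant_frame_index=i1,
                product_frame_index=i2,
                ts_frame_index=ts_idx,
                ts_geometry=traj.frames[ts_idx],
                ts_energy=float(energies[ts_idx]),
                reactant_energy=float(g1.energy),
                product_energy=float(g2.energy),
                ts_converged=bool(traj.flags[ts_idx]),
            )
        )
    return events


def _trajectory_id(traj: Trajectory) -> str:
    prov = traj.provenance or {}
    if "id" in prov:
        return str(prov["id"])
    return json.dumps(prov, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# aggregation


@dataclass
class ReactionRow:
    reactant_smiles: str
    product_smiles: str
    count: int
    dE_act_kcal: float
    dE_rxn_kcal: float
    best_ts: Geometry
    approximate: bool = False
    ts_xyz_path: str = ""


@dataclass
class ReactionTable:
    """Reactions keyed by (reactant, product) SMILES with barrier estimates.

    ``dE_act_kcal`` is the energy of the lowest transition structure over
    all of the reaction's trajectories minus the energy of the most stable
    reactant conformer in the step-1 ensemble; ``dE_rxn_kcal`` uses the best
    re-optimized product conformer seen, against the same reference.
    """

    rows: list[ReactionRow]
    reference_energy: float

    def filtered(self, max_barrier_kcal: float = 35.0) -> "ReactionTable":
        """The feasible subset: rows with estimated barriers below a cap."""
        return ReactionTable(
            rows=[r for r in self.rows if r.dE_act_kcal <= max_barrier_kcal],
            reference_energy=self.reference_energy,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "reactant_smiles": r.reactant_smiles,
                    "product_smiles": r.product_smiles,
                    "count": r.count,
                    "dE_act_kcal": r.dE_act_kcal,
                    "dE_rxn_kcal": r.dE_rxn_kcal,
                    "approximate": r.approximate,
                    "ts_xyz_path": r.ts_xyz_path,
                }
                for r in self.rows
            ],
            columns=[
                "reactant_smiles", "product_smiles", "count",
                "dE_act_kcal", "dE_rxn_kcal", "approximate", "ts_xyz_path",
            ],
        )

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")

    def to_json(self, path):
        df = self.to_dataframe()
        with open(path, "w") as fh:
            json.dump(json.loads(df.to_json(orient="records")), fh, indent=1)

    def __len__(self) -> int:
        return len(self.rows)


def aggregate(events: list[ReactionEvent], reactant_ensemble: ConformerEnsemble) -> ReactionTable:
    """Aggregate reaction events over all trajectories into a table.

    The activation-energy reference is the most stable conformer of the
    step-1 reactant ensemble.  Rows whose best transition structure came
    from a non-converged scan frame are kept but marked approximate.
    """
    if not reactant_ensemble.members:
        raise ValueError("reactant ensemble must be non-empty (barrier reference)")
    ref = min(m.energy for m in reactant_ensemble.members)
    grouped: dict[tuple[str, str], list[ReactionEvent]] = {}
    for ev in events:
        grouped.setdefault((ev.reactant_smiles, ev.product_smiles), []).append(ev)
    rows = []
    for (rs, ps), evs in grouped.items():
        best = min(evs, key=lambda e: e.ts_energy)
        best_product = min(e.product_energy for e in evs)
        rows.append(
            ReactionRow(
                reactant_smiles=rs,
                product_smiles=ps,
                count=len(evs),
                dE_act_kcal=(best.ts_energy - ref) * HARTREE_TO_KCAL,
                dE_rxn_kcal=(best_product - ref) * HARTREE_TO_KCAL,
                best_ts=best.ts_geometry,
                approximate=not best.ts_converged,
            )
        )
    rows.sort(key=lambda r: (r.dE_act_kcal, r.reactant_smiles, r.product_smiles))
    return ReactionTable(rows=rows, reference_energy=ref)
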