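"""Bond perception, canonical SMILES, trajectory parsing, table aggregation."""

import numpy as np
import pytest

from iacta import (
    ConformerEnsemble,
    Geometry,
    aggregate,
    locate_minima,
    perceive_bonds,
    to_canonical_smiles,
)
from iacta.optimize import Trajectory
from iacta.reactions import ReactionEvent
from iacta.units import HARTREE_TO_KCAL

# idealized small molecules (angstrom)
METHANE = Geometry.from_symbols(
    ["C", "H", "H", "H", "H"],
    [[0.0, 0.0, 0.0], [0.629, 0.629, 0.629], [-0.629, -0.629, 0.629],
     [-0.629, 0.629, -0.629], [0.629, -0.629, -0.629]],
)
WATER = Geometry.from_symbols(
    ["O", "H", "H"],
    [[0.0, 0.0, 0.117], [0.0, 0.757, -0.469], [0.0, -0.757, -0.469]],
)


class TestPerceiveBonds:
    def test_h2_bonded(self):
        g = Geometry((1, 1), [[0, 0, 0], [0, 0, 0.70]])
        assert perceive_bonds(g).number_of_edges() == 1

    def test_distant_helium_atoms_unbonded(self):
        g = Geometry((2, 2), [[0, 0, 0], [0, 0, 5.0]])
        assert perceive_bonds(g).number_of_edges() == 0

    def test_water_two_oh_bonds(self):
        graph = perceive_bonds(WATER)
        assert graph.number_of_edges() == 2
        assert sorted(graph.edges) == [(0, 1), (0, 2)]  # no H-H bond


class TestCanonicalSmiles:
    def test_methane(self):
        assert to_canonical_smiles(METHANE) == "C"

    def test_atom_permutation_invariance(self):
        perm = [2, 0, 4, 1, 3]
        permuted = Geometry(
            tuple(METHANE.elements[i] for i in perm), METHANE.coords[perm]
        )
        assert to_canonical_smiles(permuted) == to_canonical_smiles(METHANE)

    def test_drop_metals_removes_palladium(self):
        # Pd 'complex' with two loosely held ligand fragments
        atoms = list(WATER.symbols) + ["Pd"] + list(METHANE.symbols)
        coords = np.vstack([
            WATER.coords + np.array([0.0, 0.0, 2.2]),
            [[0.0, 0.0, 0.0]],
            METHANE.coords + np.array([0.0, 0.0, -2.4]),
        ])
        complex_geom = Geometry.from_symbols(atoms, coords)
        smi = to_canonical_smiles(complex_geom, drop_metals=True)
        assert "Pd" not in smi
        assert smi == "C.O"

    def test_fragment_sorting_stable_across_order(self):
        a = np.vstack([WATER.coords, METHANE.coords + 10.0])
        b = np.vstack([METHANE.coords, WATER.coords + 10.0])
        ga = Geometry.from_symbols(list(WATER.symbols) + list(METHANE.symbols), a)
        gb = Geometry.from_symbols(list(METHANE.symbols) + list(WATER.symbols), b)
        assert to_canonical_smiles(ga) == to_canonical_smiles(gb) == "C.O"

    def test_unsanitizable_fragment_falls_back_to_formula(self):
        # 5-coordinate carbon cannot be canonicalized; deterministic sentinel
        coords = [[0, 0, 0], [1.0, 0, 0], [-0.5, 0.87, 0], [-0.5, -0.87, 0],
                  [0, 0, 1.0], [0, 0, -1.0]]
        g = Geometry.from_symbols(["C", "H", "H", "H", "H", "H"], coords)
        assert to_canonical_smiles(g) == "!CH5"

    def test_cation_charge_assignment(self):
        coords = [[0, 0, 0], [0.96, 0, 0], [-0.32, 0.9, 0], [-0.32, -0.45, 0.78]]
        hydronium = Geometry.from_symbols(["O", "H", "H", "H"], coords, charge=1)
        assert to_canonical_smiles(hydronium) == "[OH3+]"

    def test_anion_charge_assignment(self):
        # ethoxide-like fragment: O with one bond and total charge -1
        ethoxide = Geometry.from_symbols(
            ["C", "C", "O", "H", "H", "H", "H", "H"],
            [[0.0, 0.0, 0.0], [1.52, 0.0, 0.0], [-0.70, 1.20, 0.0],
             [-0.40, -0.95, 0.0], [1.90, 0.50, 0.88], [1.90, 0.50, -0.88],
             [1.88, -1.02, 0.0], [-0.36, -0.50, 1.90]],
            charge=-1,
        )
        smi = to_canonical_smiles(ethoxide)
        assert "[O-]" in smi


class TestLocateMinima:
    @pytest.mark.parametrize(
        "energies,expected",
        [
            ([0.0, 1.0, 0.0], [0, 2]),
            ([0.0, 1.0, 2.0, 3.0], [0]),
            ([3.0, 1.0, 2.0, 0.0, 4.0], [1, 3]),
            ([5.0, 5.0, 5.0], [0, 2]),
            ([4.0, 3.0, 2.0], [2]),
        ],
    )
    def test_examples(self, energies, expected):
        assert locate_minima(energies) == expected

    def test_exhaustive_agreement_with_direct_scan(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            e = rng.normal(size=9)
            got = set(locate_minima(list(e)))
            # brute check: every reported index is a (weak) local minimum
            for i in got:
                if i > 0:
                    assert e[i - 1] >= e[i]
                if i < len(e) - 1:
                    assert e[i + 1] >= e[i]


def synthetic_two_species_trajectory(exchange_spec):
    """Frames 0-3 reactant complex, 4-9 product complex, barrier at frame 4."""
    spec = exchange_spec
    rw = spec.oracle.reactant_well[0]
    pw = spec.oracle.product_well[0]
    sp = spec.oracle.saddle_point

    def geom(r1, r2, e):
        g = Geometry(
            spec.elements,
            np.array([[0, 0, 0.0], [0, 0, r1], [0, 0, r1 + r2]]),
            multiplicity=2,
        )
        return g.with_energy(e)

    frames = [
        geom(*rw, -0.19), geom(rw[0] + 0.05, rw[1] - 0.1, -0.185),
        geom(rw[0] + 0.1, rw[1] - 0.2, -0.18), geom(rw[0] + 0.2, rw[1] - 0.4, -0.177),
        geom(*sp, -0.17),  # the barrier frame
        geom(pw[0] - 0.2, pw[1] + 0.1, -0.178), geom(pw[0] - 0.1, pw[1] + 0.05, -0.182),
        geom(*pw, -0.19), geom(pw[0] + 0.05, pw[1], -0.1895), geom(*pw, -0.1905),
    ]
    qs = [float(f.coords[1, 2]) for f in frames]
    return Trajectory(frames=frames, q_values=qs, provenance={"id": "synthetic"})


class TestExtractReactions:
    def test_unreactive_trajectory_empty(self, exchange_spec):
        from iacta import extract_reactions

        spec = exchange_spec
        rw = spec.oracle.reactant_well[0]
        g = Geometry(
            spec.elements,
            np.array([[0, 0, 0.0], [0, 0, rw[0]], [0, 0, rw[0] + rw[1]]]),
            multiplicity=2,
        )
        frames = [g.with_energy(-0.19), g.with_energy(-0.18), g.with_energy(-0.19)]
        traj = Trajectory(frames=frames, q_values=[1.0, 1.1, 1.2])
        assert extract_reactions(traj, spec.backend()) == []

    def test_constructed_event_and_ts_index(self, exchange_spec):
        from iacta import extract_reactions

        traj = synthetic_two_species_trajectory(exchange_spec)
        events = extract_reactions(traj, exchange_spec.backend())
        assert len(events) == 1
        ev = events[0]
        assert ev.ts_frame_index == 4
        assert ev.reactant_smiles == exchange_spec.reactant_smiles
        assert ev.product_smiles == exchange_spec.product_smiles
        assert ev.reactant_frame_index < ev.ts_frame_index <= ev.product_frame_index


def _event(r, p, ts_e, prod_e=-0.2, tid="t0", ts_ok=True):
    g = Geometry((1, 1), [[0, 0, 0], [0, 0, 1.0]], energy=ts_e)
    return ReactionEvent(
        reactant_smiles=r, product_smiles=p, trajectory_id=tid,
        reactant_frame_index=0, product_frame_index=4, ts_frame_index=2,
        ts_geometry=g, ts_energy=ts_e, reactant_energy=-0.25,
        product_energy=prod_e, ts_converged=ts_ok,
    )


class TestAggregate:
    def _ensemble(self, energies):
        members = [
            Geometry((1, 1), [[0, 0, 0], [0, 0, 1.0]], energy=e) for e in sorted(energies)
        ]
        return ConformerEnsemble(members=members)

    def test_min_ts_rule_and_count(self):
        ref = 0.0
        ens = self._ensemble([ref])
        kcal = 1.0 / HARTREE_TO_KCAL
        events = [_event("A", "B", 5 * kcal), _event("A", "B", 3 * kcal, tid="t1")]
        table = aggregate(events, ens)
        assert len(table) == 1
        row = table.rows[0]
        assert row.count == 2
        assert row.dE_act_kcal == pytest.approx(3.0)

    def test_reference_is_best_reactant_conformer(self):
        kcal = 1.0 / HARTREE_TO_KCAL
        ens = self._ensemble([-12 * kcal, -10 * kcal])
        table = aggregate([_event("A", "B", 0.0)], ens)
        assert table.rows[0].dE_act_kcal == pytest.approx(12.0)

    def test_reaction_energy_uses_best_product(self):
        kcal = 1.0 / HARTREE_TO_KCAL
        ens = self._ensemble([0.0])
        events = [
            _event("A", "B", 5 * kcal, prod_e=-2 * kcal),
            _event("A", "B", 6 * kcal, prod_e=-4 * kcal, tid="t1"),
        ]
        table = aggregate(events, ens)
        assert table.rows[0].dE_rxn_kcal == pytest.approx(-4.0)

    def test_table_cells_reproduce_barrier_count_layout(self):
        # distinct reactions aggregate into separate (dE | count) cells
        kcal = 1.0 / HARTREE_TO_KCAL
        ens = self._ensemble([0.0])
        events = (
            [_event("A", "B", 8.7 * kcal, tid=f"a{i}") for i in range(20)]
            + [_event("A", "C", 11.2 * kcal, tid=f"b{i}") for i in range(8)]
        )
        table = aggregate(events, ens)
        cells = {(r.reactant_smiles, r.product_smiles): (round(r.dE_act_kcal, 1), r.count)
                 for r in table.rows}
        assert cells == {("A", "B"): (8.7, 20), ("A", "C"): (11.2, 8)}

    def test_nonconverged_ts_marks_row_approximate(self):
        ens = self._ensemble([0.0])
        table = aggregate([_event("A", "B", 0.01, ts_ok=False)], ens)
        assert table.rows[0].approximate

    def test_barrier_filter(self):
        kcal = 1.0 / HARTREE_TO_KCAL
        ens = self._ensemble([0.0])
        events = [_event("A", "B", 10 * kcal), _event("A", "C", 90 * kcal, tid="t1")]
        table = aggregate(events, ens)
        assert len(table) == 2
        assert len(table.filtered(35.0)) == 1

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            aggregate([_event("A", "B", 0.0)], ConformerEnsemble(members=[]))
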