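"""Geometry model: internal coordinates, RMSD, rotational constants, XYZ I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from iacta import (
    Geometry,
    InternalCoordinate,
    measure,
    read_xyz,
    rmsd_gradient,
    rotational_constants,
    superpose_rmsd,
    write_xyz,
)
from iacta.chemsys import (
    GeometryError,
    LINEAR_SENTINEL,
    XYZParseError,
    atomic_mass,
    coordinate_gradient,
)
from iacta.units import AMU_KG, C_LIGHT_CM, PLANCK


def rand_geometry(rng, n=5, elements=None):
    elements = elements or (6, 1, 8, 7, 1)[:n]
    return Geometry(elements, rng.normal(size=(n, 3)) * 1.5)


class TestMeasure:
    def test_distance_collinear(self):
        g = Geometry((1, 1), [[0, 0, 0], [0, 0, 1.5]])
        assert measure(g, InternalCoordinate("distance", (0, 1))) == pytest.approx(1.5)

    def test_straight_angle(self):
        g = Geometry((1, 6, 1), [[0, 0, -1], [0, 0, 0], [0, 0, 2]])
        assert measure(g, InternalCoordinate("angle", (0, 1, 2))) == pytest.approx(180.0)

    def test_cis_dihedral_is_zero(self):
        g = Geometry((1, 6, 6, 1), [[1, 1, 0], [0, 1, 0], [0, -1, 0], [1, -1, 0]])
        assert measure(g, InternalCoordinate("dihedral", (0, 1, 2, 3))) == pytest.approx(0.0)

    def test_coincident_atoms_raise_not_nan(self):
        g = Geometry((1, 6, 1), [[0, 0, 0], [0, 0, 0], [1, 0, 0]])
        with pytest.raises(GeometryError):
            measure(g, InternalCoordinate("angle", (0, 1, 2)))

    @pytest.mark.parametrize(
        "kind,atoms",
        [("distance", (0, 0)), ("angle", (0, 1)), ("dihedral", (0, 1, 2))],
    )
    def test_malformed_coordinates_rejected(self, kind, atoms):
        with pytest.raises(GeometryError):
            InternalCoordinate(kind, atoms)

    def test_coordinate_gradient_matches_differences(self):
        rng = np.random.default_rng(3)
        g = rand_geometry(rng, 4, (6, 6, 8, 1))
        h = 1e-6
        for coord in [
            InternalCoordinate("distance", (0, 2)),
            InternalCoordinate("angle", (0, 1, 2)),
            InternalCoordinate("dihedral", (0, 1, 2, 3)),
        ]:
            grad = coordinate_gradient(g, coord)
            x = np.array(g.coords)
            for a in coord.atoms:
                for c in range(3):
                    x[a, c] += h
                    up = measure(g.with_coords(x), coord)
                    x[a, c] -= 2 * h
                    dn = measure(g.with_coords(x), coord)
                    x[a, c] += h
                    assert grad[a, c] == pytest.approx((up - dn) / (2 * h), abs=1e-4)


class TestSuperposeRMSD:
    def test_identity_is_zero(self):
        rng = np.random.default_rng(0)
        g = rand_geometry(rng)
        rmsd, _, _ = superpose_rmsd(g, g)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        g = rand_geometry(rng)
        R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        moved = g.with_coords(g.coords @ R.T + np.array([1.0, -2.0, 0.5]))
        rmsd, _, _ = superpose_rmsd(g, moved)
        assert rmsd <= 1e-8

    def test_matches_brute_force_rotation_grid(self):
        # independent oracle: exhaustive search over a dense rotation grid
        a = Geometry((1, 1, 1), [[0, 0, 0], [1.2, 0, 0], [0, 1.2, 0]])
        b = Geometry((1, 1, 1), [[0, 0, 0], [1.2, 0, 0], [0, 1.2, 0.9]])
        rmsd, _, _ = superpose_rmsd(a, b)
        pa = a.coords - a.coords.mean(axis=0)
        pb = b.coords - b.coords.mean(axis=0)

        def resid(angles):
            R = Rotation.from_euler("zyz", angles).as_matrix()
            d = pa - pb @ R.T
            return np.sqrt((d * d).sum() / 3)

        best, best_ang = np.inf, None
        n = 24
        for ai in np.linspace(0, 2 * np.pi, n, endpoint=False):
            for bi in np.linspace(0, np.pi, n // 2):
                for ci in np.linspace(0, 2 * np.pi, n, endpoint=False):
                    v = resid([ai, bi, ci])
                    if v < best:
                        best, best_ang = v, (ai, bi, ci)
        # polish the exhaustive-grid winner locally (still Kabsch-free)
        from scipy.optimize import minimize as _min

        best = _min(resid, best_ang, method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-14}).fun
        assert rmsd == pytest.approx(best, abs=1e-6)
        assert rmsd <= best + 1e-9

    def test_mismatched_elements_raise(self):
        a = Geometry((1, 1), [[0, 0, 0], [0, 0, 1]])
        b = Geometry((1, 8), [[0, 0, 0], [0, 0, 1]])
        with pytest.raises(GeometryError):
            superpose_rmsd(a, b)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_alignment_bound(self, seed):
        rng = np.random.default_rng(seed)
        a = rand_geometry(rng)
        b = a.with_coords(a.coords + rng.normal(size=a.coords.shape) * 0.5)
        rab, _, _ = superpose_rmsd(a, b)
        rba, _, _ = superpose_rmsd(b, a)
        assert rab == pytest.approx(rba, abs=1e-8)
        unaligned = np.sqrt(((a.coords - b.coords) ** 2).sum() / a.natoms)
        assert rab <= unaligned + 1e-10


class TestRMSDGradient:
    def test_matches_central_differences(self):
        rng = np.random.default_rng(7)
        a = rand_geometry(rng)
        b = a.with_coords(a.coords + rng.normal(size=a.coords.shape) * 0.3)
        grad = rmsd_gradient(a, b)
        h = 1e-5
        for i in range(a.natoms):
            for c in range(3):
                x = np.array(a.coords)
                x[i, c] += h
                up, _, _ = superpose_rmsd(a.with_coords(x), b)
                x[i, c] -= 2 * h
                dn, _, _ = superpose_rmsd(a.with_coords(x), b)
                fd = (up - dn) / (2 * h)
                assert abs(grad[i, c] - fd) <= 1e-5 * max(1.0, abs(fd))

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        a = rand_geometry(rng)
        b = a.with_coords(a.coords + rng.normal(size=a.coords.shape) * 0.4)
        grad = rmsd_gradient(a, b)
        assert np.abs(grad.sum(axis=0)).max() <= 1e-10

    def test_single_atom_displacement_localized(self):
        base = np.array([[0.0, 0, 0], [2.0, 0, 0], [0, 2.0, 0], [0, 0, 2.0], [1, 1, 1.0]])
        shifted = base.copy()
        shifted[2, 2] += 0.4
        cur = Geometry((6, 6, 6, 6, 6), shifted)
        ref = Geometry((6, 6, 6, 6, 6), base)
        grad = rmsd_gradient(cur, ref)
        # dominant component: atom 2, z, pointing away from the reference
        assert np.argmax(np.abs(grad)) == 2 * 3 + 2
        assert grad[2, 2] > 0

    def test_zero_rmsd_returns_zero_gradient(self):
        g = Geometry((1, 1), [[0, 0, 0], [0, 0, 1]])
        assert np.all(rmsd_gradient(g, g) == 0.0)


class TestRotationalConstants:
    def test_diatomic_closed_form(self):
        r = 1.2
        g = Geometry((17, 17), [[0, 0, 0], [0, 0, r]])
        m = atomic_mass(17)
        mu = m / 2 * AMU_KG
        b_cm = PLANCK / (8 * math.pi**2 * C_LIGHT_CM * mu * (r * 1e-10) ** 2)
        consts = rotational_constants(g)
        assert consts[0] == LINEAR_SENTINEL
        assert consts[1] == pytest.approx(b_cm, rel=1e-8)
        assert consts[2] == pytest.approx(b_cm, rel=1e-8)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(2)
        g = rand_geometry(rng)
        R = Rotation.from_rotvec([1.0, 0.2, -0.4]).as_matrix()
        c1 = rotational_constants(g)
        c2 = rotational_constants(g.with_coords(g.coords @ R.T + 3.0))
        assert np.allclose(c1, c2, rtol=1e-8)

    def test_inverse_mass_scaling(self):
        # doubling every mass halves every finite constant: B ~ 1/I
        class DoubledMasses(Geometry):
            @property
            def masses(self):
                return 2.0 * super().masses

        rng = np.random.default_rng(5)
        coords = rng.normal(size=(4, 3))
        normal = rotational_constants(Geometry((6, 8, 1, 1), coords))
        heavy = rotational_constants(DoubledMasses((6, 8, 1, 1), coords))
        finite = np.isfinite(normal)
        assert np.allclose(heavy[finite], normal[finite] / 2.0, rtol=1e-10)

    def test_single_atom_rejected(self):
        with pytest.raises(GeometryError):
            rotational_constants(Geometry((6,), [[0, 0, 0]]))


class TestXYZ:
    def test_round_trip_three_frames(self, tmp_path):
        rng = np.random.default_rng(4)
        frames = [
            Geometry((6, 1, 8), rng.normal(size=(3, 3)), energy=-1.5 * (k + 1))
            for k in range(3)
        ]
        path = tmp_path / "t.xyz"
        write_xyz(path, frames)
        back = read_xyz(path)
        assert len(back) == 3
        for f, g in zip(frames, back):
            assert f.elements == g.elements
            assert np.abs(f.coords - g.coords).max() <= 1e-8
            assert g.energy == pytest.approx(f.energy)

    def test_energy_comment_parsed(self, tmp_path):
        path = tmp_path / "e.xyz"
        path.write_text("1\nE=-5.0\nH 0.0 0.0 0.0\n")
        assert read_xyz(path)[0].energy == pytest.approx(-5.0)

    def test_atom_count_mismatch_names_frame(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("3\nframe 0\nH 0 0 0\nH 0 0 1\n")
        with pytest.raises(XYZParseError, match="frame 0"):
            read_xyz(path)

    def test_non_numeric_coordinate_names_line(self, tmp_path):
        path = tmp_path / "bad2.xyz"
        path.write_text("1\n\nH 0 zero 0\n")
        with pytest.raises(XYZParseError, match="line 3"):
            read_xyz(path)
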