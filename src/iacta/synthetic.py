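"""Fixture generators and brute-force oracles.

Everything here is synthetic, desk-scale test infrastructure: a collinear
atom-exchange system on a pairwise-Morse surface whose saddle and wells are
located by exhaustive grid search (independent of the optimizer and the
sampler), and the Mueller-Brown two-dimensional test function.  The oracles
use only direct energy evaluation plus exhaustive search, so they can
verify the pipeline without sharing any code path with it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .backends import EnergyGradient, MorseBackend, MorseParams
from .chemsys import Geometry
from .units import HARTREE_TO_KCAL


class OracleError(RuntimeError):
    """The brute-force oracle could not certify the requested feature."""


@dataclass
class OracleResult:
    """Grid-search result on the collinear 2-D surface (energies in Hartree)."""

    saddle_energy: float
    saddle_point: tuple[float, float]  # (r_AB, r_BC) in A
    minima: list[tuple[tuple[float, float], float]]  # ((r_AB, r_BC), E), ascending E
    reactant_well: tuple[tuple[float, float], float]  # the well with A-B bonded
    product_well: tuple[tuple[float, float], float]

    @property
    def barrier_kcal(self) -> float:
        """Saddle height above the reactant well, kcal/mol."""
        return (self.saddle_energy - self.reactant_well[1]) * HARTREE_TO_KCAL

    @property
    def reaction_energy_kcal(self) -> float:
        """Product well minus reactant well, kcal/mol."""
        return (self.product_well[1] - self.reactant_well[1]) * HARTREE_TO_KCAL


@dataclass
class ToySystemSpec:
    """A three-atom exchange system A-B + C -> A + B-C with oracle data.

    The 2-D collinear surface over (r_AB, r_BC) has a reactant well
    (A-B bonded, C loosely attached), a product well, and one saddle.
    All known-outcome fields are populated by this module's own brute-force
    operations, never written by hand.
    """

    label: str
    elements: tuple[int, ...]
    geometry: Geometry
    params: MorseParams
    coordinate_atoms: tuple[int, int] = (0, 1)  # the A-B distance is q-dagger
    oracle: OracleResult | None = None
    reactant_smiles: str | None = None
    product_smiles: str | None = None

    def backend(self) -> MorseBackend:
        return MorseBackend(self.params)

    def collinear_energy(self, r_ab: float, r_bc: float) -> float:
        """Direct backend energy of the collinear arrangement (oracle probe)."""
        a, b, c = self.elements
        geom = Geometry(
            (a, b, c),
            np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r_ab], [0.0, 0.0, r_ab + r_bc]]),
            charge=self.geometry.charge,
            multiplicity=self.geometry.multiplicity,
        )
        return MorseBackend(self.params).evaluate(geom).energy


def make_collinear_exchange(
    D_e: float = 0.15,
    a: float = 1.8,
    r_e: float = 1.4,
    asymmetry: float = 0.0,
    elements: tuple[int, int, int] = (17, 1, 35),
    compute_oracle: bool = True,
    grid_resolution: int = 300,
) -> ToySystemSpec:
    """Three-atom exchange toy system on a pairwise-Morse surface.

    The A-B and B-C pairs share (``D_e``, ``a``, ``r_e``) except that the
    product bond is deepened by ``1 + asymmetry``; the A-C pair carries a
    soft long-range Morse that is net repulsive over the sampled region, so
    the collinear arrangement is the minimum-energy approach and a single
    saddle separates the two wells.  With ``compute_oracle`` the grid
    oracle locates the wells and the saddle and stores them on the spec
    (raising :class:`OracleError` if the parameter regime has no saddle).
    """
    if min(D_e, a, r_e) <= 0 or asymmetry < -0.9:
        raise ValueError("Morse parameters must be positive")
    za, zb, zc = elements
    if za == zc:
        raise ValueError(
            "A and C must be distinguishable elements (the exchange is otherwise "
            "invisible to SMILES-based detection); use equal Morse parameters for "
            "an energetically symmetric surface"
        )
    params = MorseParams(
        pairs={
            (za, zb): (D_e, a, r_e),
            (zb, zc): (D_e * (1.0 + asymmetry), a, r_e),
            (za, zc): (D_e / 6.0, a * 0.61, r_e * 3.286),
        },
        cutoff=8.0,
    )
    # start: A-B bonded at r_e, C approaching collinearly at a loose distance
    geometry = Geometry(
        (za, zb, zc),
        np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r_e], [0.0, 0.0, r_e + 2.0 * r_e]]),
        charge=0,
        multiplicity=2,  # odd electron count for three monovalent atoms
    )
    spec = ToySystemSpec(
        label=f"exchange_{'-'.join(map(str, elements))}_asym{asymmetry:g}",
        elements=(za, zb, zc),
        geometry=geometry,
        params=params,
    )
    if compute_oracle:
        spec.oracle = grid_saddle_oracle(spec, grid_resolution=grid_resolution)
        from .reactions import to_canonical_smiles  # late import: avoid cycle

        rw, pw = spec.oracle.reactant_well, spec.oracle.product_well
        spec.reactant_smiles = to_canonical_smiles(_collinear_geom(spec, *rw[0]))
        spec.product_smiles = to_canonical_smiles(_collinear_geom(spec, *pw[0]))
    return spec


def _collinear_geom(spec: ToySystemSpec, r_ab: float, r_bc: float) -> Geometry:
    return Geometry(
        spec.elements,
        np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r_ab], [0.0, 0.0, r_ab + r_bc]]),
        charge=spec.geometry.charge,
        multiplicity=spec.geometry.multiplicity,
    )


def _grid_local_minima(E: np.ndarray) -> list[tuple[int, int]]:
    n, m = E.shape
    out = []
    for i in range(n):
        for j in range(m):
            e = E[i, j]
            is_min = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < n and 0 <= jj < m and E[ii, jj] < e:
                        is_min = False
            if is_min:
                out.append((i, j))
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[rx] = ry


def grid_saddle_oracle(
    spec: ToySystemSpec,
    grid_resolution: int = 300,
    r_lo: float | None = None,
    r_hi: float | None = None,
    check_resolution: bool = False,
    resolution_tol_kcal: float = 0.1,
) -> OracleResult:
    """Exhaustive-search saddle and wells of the collinear 2-D surface.

    The surface is evaluated on a dense (r_AB, r_BC) grid; the saddle is the
    minimax barrier between the two lowest grid minima, found by adding grid
    cells in ascending energy order (union-find) until the wells' basins
    connect — exact on the grid graph.  Saddle and minima are then polished
    on the continuous surface (Nelder-Mead on the minima; Newton on the
    gradient for the saddle, via finite differences of the direct energy).

    Raises :class:`OracleError` when fewer than two distinct wells exist
    (e.g. a diatomic has no saddle) or, with ``check_resolution``, when a
    2x refinement moves the saddle by more than ``resolution_tol_kcal``.
    """
    if len(spec.elements) < 3:
        raise OracleError("a 1-D (diatomic) system has no saddle to locate")
    key = next(iter(spec.params.pairs))
    r_e = spec.params.pairs[(min(spec.elements[:2]), max(spec.elements[:2]))][2] \
        if (min(spec.elements[:2]), max(spec.elements[:2])) in spec.params.pairs \
        else spec.params.pairs[key][2]
    lo = r_lo if r_lo is not None else 0.65 * r_e
    hi = r_hi if r_hi is not None else 3.0 * r_e

    def solve(n: int):
        r = np.linspace(lo, hi, n)
        R1, R2 = np.meshgrid(r, r, indexing="ij")
        E = np.empty_like(R1)
        for i in range(n):
            for j in range(n):
                E[i, j] = spec.collinear_energy(R1[i, j], R2[i, j])
        mins = _grid_local_minima(E)
        mins.sort(key=lambda ij: E[ij])
        # merge grid minima that are the same basin corner duplicates
        distinct = []
        for ij in mins:
            if all(abs(r[ij[0]] - r[kl[0]]) > 0.2 * r_e or abs(r[ij[1]] - r[kl[1]]) > 0.2 * r_e
                   for kl in distinct):
                distinct.append(ij)
        if len(distinct) < 2:
            raise OracleError(
                f"surface has {len(distinct)} well(s); no saddle exists in this regime"
            )
        a_, b_ = distinct[0], distinct[1]
        flat = lambda ij: ij[0] * n + ij[1]
        uf = _UnionFind(n * n)
        added = np.zeros(n * n, dtype=bool)
        order = np.argsort(E, axis=None)
        saddle_ij = None
        for f in order:
            i, j = divmod(int(f), n)
            added[f] = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < n and 0 <= jj < n and added[ii * n + jj]:
                        uf.union(int(f), ii * n + jj)
            if uf.find(flat(a_)) == uf.find(flat(b_)):
                saddle_ij = (i, j)
                break
        if saddle_ij is None:  # pragma: no cover - wells always connect on a grid
            raise OracleError("wells never connected on the grid")
        return r, E, distinct[:2], saddle_ij

    r, E, wells_ij, saddle_ij = solve(grid_resolution)

    def f2(p):
        return spec.collinear_energy(p[0], p[1])

    wells = []
    for ij in wells_ij:
        res = _scipy_minimize(f2, [r[ij[0]], r[ij[1]]], method="Nelder-Mead",
                              options={"xatol": 1e-8, "fatol": 1e-12})
        wells.append(((float(res.x[0]), float(res.x[1])), float(res.fun)))
    wells.sort(key=lambda w: w[1])

    saddle_pt, saddle_e = _polish_saddle(f2, (r[saddle_ij[0]], r[saddle_ij[1]]))

    if check_resolution:
        _, E2, _, saddle2_ij = solve(2 * grid_resolution)
        r2 = np.linspace(lo, hi, 2 * grid_resolution)
        _, saddle2_e = _polish_saddle(f2, (r2[saddle2_ij[0]], r2[saddle2_ij[1]]))
        if abs(saddle2_e - saddle_e) * HARTREE_TO_KCAL > resolution_tol_kcal:
            raise OracleError(
                f"saddle unstable under grid refinement "
                f"({abs(saddle2_e - saddle_e) * HARTREE_TO_KCAL:.3f} kcal/mol shift)"
            )

    # label wells: reactant = A-B bonded (small r_AB)
    reactant = min(wells, key=lambda w: w[0][0])
    product = max(wells, key=lambda w: w[0][0])
    return OracleResult(
        saddle_energy=saddle_e,
        saddle_point=saddle_pt,
        minima=wells,
        reactant_well=reactant,
        product_well=product,
    )


def _polish_saddle(f2, p0, h: float = 1e-4, iters: int = 60):
    """Newton iterations on the 2-D gradient (finite differences) from p0."""
    p = np.array(p0, dtype=float)
    for _ in range(iters):
        g = np.array([
            (f2(p + [h, 0]) - f2(p - [h, 0])) / (2 * h),
            (f2(p + [0, h]) - f2(p - [0, h])) / (2 * h),
        ])
        H = np.empty((2, 2))
        H[0, 0] = (f2(p + [h, 0]) - 2 * f2(p) + f2(p - [h, 0])) / h**2
        H[1, 1] = (f2(p + [0, h]) - 2 * f2(p) + f2(p - [0, h])) / h**2
        cross = (
            f2(p + [h, h]) - f2(p + [h, -h]) - f2(p + [-h, h]) + f2(p + [-h, -h])
        ) / (4 * h**2)
        H[0, 1] = H[1, 0] = cross
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        if np.linalg.norm(step) > 0.2:
            step *= 0.2 / np.linalg.norm(step)
        p = p - step
        if np.linalg.norm(g) < 1e-10:
            break
    return (float(p[0]), float(p[1])), float(f2(p))


def make_torsional_chain() -> tuple[Geometry, MorseParams]:
    """A butane-like 4-atom chain with two degenerate torsional wells.

    Four distinct elements (C-N-O-F) so that every atom pair carries its own
    Morse parameters: stiff 1-2 bonds, softer 1-3 terms that hold the bend
    angles near tetrahedral, and a weak 1-4 term whose minimum sits at the
    gauche 1-4 distance.  The dihedral then has two mirror-image wells near
    +/-60 degrees separated by barriers at the syn and anti arrangements —
    the smallest system on which a conformer search has something to find.
    """
    r_bond, theta = 1.4, math.radians(109.5)
    r_13 = math.sqrt(2.0 * r_bond**2 * (1.0 - math.cos(theta)))

    def chain_coords(phi_deg: float) -> np.ndarray:
        # standard z-matrix placement: bond r, angle theta, dihedral phi
        phi = math.radians(phi_deg)
        p0 = np.array([0.0, 0.0, 0.0])
        p1 = np.array([0.0, 0.0, r_bond])
        p2 = p1 + r_bond * np.array([math.sin(theta), 0.0, -math.cos(theta)])
        # local frame at p2 along p2-p1
        bc = (p2 - p1) / np.linalg.norm(p2 - p1)
        n = np.cross(p1 - p0, bc)
        n /= np.linalg.norm(n)
        m = np.cross(n, bc)
        d = r_bond * (
            -bc * math.cos(theta) + m * math.sin(theta) * math.cos(phi)
            + n * math.sin(theta) * math.sin(phi)
        )
        return np.vstack([p0, p1, p2, p2 + d])

    gauche = chain_coords(60.0)
    r_14 = float(np.linalg.norm(gauche[3] - gauche[0]))
    params = MorseParams(
        pairs={
            (6, 7): (0.2, 2.0, r_bond),
            (7, 8): (0.2, 2.0, r_bond),
            (8, 9): (0.2, 2.0, r_bond),
            (6, 8): (0.05, 1.5, r_13),
            (7, 9): (0.05, 1.5, r_13),
            (6, 9): (0.01, 1.5, r_14),
        },
        cutoff=8.0,
    )
    geometry = Geometry((6, 7, 8, 9), gauche, charge=0, multiplicity=1)
    return geometry, params


# ---------------------------------------------------------------------------
# Mueller-Brown test function

_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])


def muller_brown():
    """The standard Mueller-Brown 2-D test surface.

    Returns ``(f, grad)`` with ``f(x, y) -> float`` and
    ``grad(x, y) -> (df/dx, df/dy)``.  Three minima, two saddles, at the
    literature-standard parameter values.
    """

    def f(x: float, y: float) -> float:
        dx, dy = x - _MB_x0, y - _MB_y0
        return float(np.sum(_MB_A * np.exp(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2)))

    def grad(x: float, y: float):
        dx, dy = x - _MB_x0, y - _MB_y0
        terms = _MB_A * np.exp(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2)
        gx = float(np.sum(terms * (2 * _MB_a * dx + _MB_b * dy)))
        gy = float(np.sum(terms * (_MB_b * dx + 2 * _MB_c * dy)))
        return gx, gy

    return f, grad


class MullerBrownBackend:
    """Backend wrapper: atom 0's (x, y) lives on the Mueller-Brown surface.

    Lets the optimizer and the MD integrator be exercised on a landscape
    with three known minima.  The z component is unused (zero gradient);
    any further atoms are free particles.
    """

    def __init__(self):
        self.f, self.grad = muller_brown()

    def evaluate(self, geom: Geometry) -> EnergyGradient:
        x, y = float(geom.coords[0, 0]), float(geom.coords[0, 1])
        gx, gy = self.grad(x, y)
        gradient = np.zeros_like(geom.coords)
        gradient[0, 0], gradient[0, 1] = gx, gy
        return EnergyGradient(energy=self.f(x, y), gradient=gradient)
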