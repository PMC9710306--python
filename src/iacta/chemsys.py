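"""Core molecular data model.

Geometries with charge/spin metadata, internal coordinates (distance, angle,
dihedral) and their Cartesian gradients, rigid-body superposition RMSD with
an analytic gradient, rigid-rotor rotational constants, and a multi-frame
XYZ dialect that stores the energy on the comment line as ``E=<Hartree>``.

Atom indices are 0-based everywhere in the library; the command-line layer
converts from the 1-based chemistry convention.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from scipy.spatial.transform import Rotation

from .units import AMU_KG, C_LIGHT_CM, PLANCK

_PT = Chem.GetPeriodicTable()

#: RMSD below this floor is treated as exactly zero; its gradient is singular
#: there and is returned as the zero vector (the metadynamics kernel's
#: chain-rule prefactor 2*alpha*Delta vanishes smoothly at the same point).
RMSD_FLOOR = 1e-6

#: Sentinel reported for the rotational constant about a zero-moment axis
#: (linear molecules).  Duplicate detection compares finite constants only.
LINEAR_SENTINEL = math.inf


class GeometryError(ValueError):
    """Invalid geometry or coordinate definition."""


class XYZParseError(ValueError):
    """Malformed XYZ input; message carries the offending line number."""


def atomic_number(symbol: str) -> int:
    z = _PT.GetAtomicNumber(symbol.capitalize())
    if z == 0:
        raise GeometryError(f"unknown element symbol {symbol!r}")
    return z


def element_symbol(z: int) -> str:
    return _PT.GetElementSymbol(int(z))


def atomic_mass(z: int) -> float:
    """Standard atomic weight in amu."""
    return _PT.GetAtomicWeight(int(z))


def covalent_radius(z: int) -> float:
    """Covalent radius in angstrom from the bundled periodic table."""
    r = _PT.GetRcovalent(int(z))
    if r <= 0.0:
        raise GeometryError(f"no covalent radius for element Z={z}")
    return float(r)


@dataclass(frozen=True)
class Geometry:
    """A molecular structure: elements, Cartesian coordinates, charge/spin.

    Parameters
    ----------
    elements:
        Atomic numbers, one per atom.
    coords:
        ``(N, 3)`` Cartesian positions in angstrom.
    charge:
        Total charge (electron-count offset).
    multiplicity:
        Spin multiplicity ``2S+1 >= 1``.
    energy:
        Optional potential energy in Hartree.
    """

    elements: tuple[int, ...]
    coords: np.ndarray
    charge: int = 0
    multiplicity: int = 1
    energy: float | None = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise GeometryError(f"coords must be (N, 3), got {coords.shape}")
        if len(self.elements) != coords.shape[0]:
            raise GeometryError(
                f"{len(self.elements)} elements but {coords.shape[0]} coordinate rows"
            )
        if self.multiplicity < 1:
            raise GeometryError("multiplicity must be >= 1")
        if self.energy is not None and not math.isfinite(self.energy):
            raise GeometryError("energy must be finite when present")
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(int(z) for z in self.elements))

    @property
    def natoms(self) -> int:
        return len(self.elements)

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(element_symbol(z) for z in self.elements)

    @property
    def masses(self) -> np.ndarray:
        return np.array([atomic_mass(z) for z in self.elements])

    def with_coords(self, coords: np.ndarray, energy: float | None = None) -> "Geometry":
        return replace(self, coords=np.array(coords, dtype=float), energy=energy)

    def with_energy(self, energy: float) -> "Geometry":
        return replace(self, energy=energy)

    @classmethod
    def from_symbols(cls, symbols: Sequence[str], coords, **kw) -> "Geometry":
        return cls(tuple(atomic_number(s) for s in symbols), np.asarray(coords, float), **kw)


@dataclass(frozen=True)
class InternalCoordinate:
    """A distance (A), bending angle or torsion (degrees) between atoms."""

    kind: str
    atoms: tuple[int, ...]

    _NATOMS = {"distance": 2, "angle": 3, "dihedral": 4}

    def __post_init__(self):
        if self.kind not in self._NATOMS:
            raise GeometryError(f"unknown coordinate kind {self.kind!r}")
        atoms = tuple(int(a) for a in self.atoms)
        if len(atoms) != self._NATOMS[self.kind]:
            raise GeometryError(
                f"{self.kind} needs {self._NATOMS[self.kind]} atoms, got {len(atoms)}"
            )
        if len(set(atoms)) != len(atoms):
            raise GeometryError(f"atom indices must be distinct, got {atoms}")
        if any(a < 0 for a in atoms):
            raise GeometryError("atom indices must be non-negative")
        object.__setattr__(self, "atoms", atoms)

    @property
    def is_periodic(self) -> bool:
        return self.kind == "dihedral"


@dataclass(frozen=True)
class ActivationSchedule:
    """The activating coordinate and the ladder of values it is driven over.

    ``q0`` is the equilibrium value, ``intermediates`` the activated values
    the conformer searches run at, and ``qN`` the maximal scanned value.
    The ladder must be strictly monotone (stretching or compression).
    """

    coordinate: InternalCoordinate
    q0: float
    intermediates: tuple[float, ...]
    qN: float
    scan_step: float = 0.1

    def __post_init__(self):
        object.__setattr__(self, "intermediates", tuple(float(q) for q in self.intermediates))
        ladder = (self.q0, *self.intermediates, self.qN)
        increasing = all(a < b for a, b in zip(ladder, ladder[1:]))
        decreasing = all(a > b for a, b in zip(ladder, ladder[1:]))
        if not (increasing or decreasing):
            raise GeometryError(f"schedule values must be strictly monotone: {ladder}")
        if self.scan_step <= 0:
            raise GeometryError("scan_step must be positive")


# ---------------------------------------------------------------------------
# internal-coordinate measurement


def _check_indices(geom: Geometry, coord: InternalCoordinate) -> None:
    if max(coord.atoms) >= geom.natoms:
        raise GeometryError(
            f"coordinate atoms {coord.atoms} out of range for {geom.natoms} atoms"
        )


def measure(geom: Geometry, coord: InternalCoordinate) -> float:
    """Value of an internal coordinate: A for distances, degrees otherwise.

    Angles lie in [0, 180]; dihedrals in (-180, 180].  Coincident defining
    atoms raise :class:`GeometryError` rather than returning NaN.
    """
    _check_indices(geom, coord)
    x = geom.coords
    if coord.kind == "distance":
        i, j = coord.atoms
        return float(np.linalg.norm(x[i] - x[j]))
    if coord.kind == "angle":
        i, j, k = coord.atoms
        u, v = x[i] - x[j], x[k] - x[j]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-10 or nv < 1e-10:
            raise GeometryError(f"degenerate angle: coincident atoms in {coord.atoms}")
        cosang = np.clip(u @ v / (nu * nv), -1.0, 1.0)
        return float(np.degrees(np.arccos(cosang)))
    # dihedral, atan2 convention
    i, j, k, l = coord.atoms
    b1, b2, b3 = x[j] - x[i], x[k] - x[j], x[l] - x[k]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10 or nb2 < 1e-10:
        raise GeometryError(f"degenerate dihedral: collinear/coincident atoms in {coord.atoms}")
    phi = math.degrees(math.atan2((np.cross(n1, n2) @ b2) / nb2, n1 @ n2))
    if phi <= -180.0:
        phi += 360.0
    return phi


def wrap_delta(value: float, target: float, coord: InternalCoordinate) -> float:
    """Signed deviation value-target, wrapped to (-180, 180] for dihedrals."""
    d = value - target
    if coord.is_periodic:
        d = (d + 180.0) % 360.0 - 180.0
        if d <= -180.0:
            d += 360.0
    return d


def coordinate_gradient(geom: Geometry, coord: InternalCoordinate) -> np.ndarray:
    """``(N, 3)`` gradient of the coordinate value w.r.t. Cartesians.

    Distances are analytic; angle and dihedral gradients are evaluated by
    central differences on the few defining atoms (periodicity-safe), which
    is exact to ~1e-7 degrees/A and only touches 3-4 atoms.
    """
    _check_indices(geom, coord)
    grad = np.zeros_like(geom.coords)
    if coord.kind == "distance":
        i, j = coord.atoms
        d = geom.coords[i] - geom.coords[j]
        r = np.linalg.norm(d)
        if r < 1e-10:
            raise GeometryError("coincident atoms in distance coordinate")
        grad[i] = d / r
        grad[j] = -d / r
        return grad
    h = 1e-6
    base = measure(geom, coord)
    x = np.array(geom.coords)
    for a in coord.atoms:
        for c in range(3):
            x[a, c] += h
            plus = measure(geom.with_coords(x), coord)
            x[a, c] -= 2 * h
            minus = measure(geom.with_coords(x), coord)
            x[a, c] += h
            dp = wrap_delta(plus, base, coord)
            dm = wrap_delta(minus, base, coord)
            grad[a, c] = (dp - dm) / (2 * h)
    return grad


# ---------------------------------------------------------------------------
# superposition / RMSD


def _atom_mask(geom: Geometry, heavy_only: bool) -> np.ndarray:
    if not heavy_only:
        return np.ones(geom.natoms, dtype=bool)
    mask = np.array([z > 1 for z in geom.elements])
    if not mask.any():
        # all-hydrogen system: fall back to all atoms
        return np.ones(geom.natoms, dtype=bool)
    return mask


def superpose_rmsd(
    a: Geometry, b: Geometry, heavy_only: bool = False
) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimum RMSD between two conformations over rigid-body superposition.

    Atoms are matched by input order (no permutation search) and weighted
    equally.  Returns ``(rmsd, R, t)`` with the proper rotation ``R`` and
    translation ``t`` such that ``b @ R.T + t`` best overlays ``a``.
    """
    if a.elements != b.elements:
        raise GeometryError("superposition requires identical element sequences")
    mask = _atom_mask(a, heavy_only)
    pa = a.coords[mask]
    pb = b.coords[mask]
    ca, cb = pa.mean(axis=0), pb.mean(axis=0)
    if len(pa) == 1:
        return 0.0, np.eye(3), ca - cb
    with warnings.catch_warnings():
        # collinear point sets leave a free rotation axis; RMSD is unaffected
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(pa - ca, pb - cb)
    R = rot.as_matrix()
    # recompute the residual directly: scipy's rssd loses precision near zero
    diff = (pa - ca) - (pb - cb) @ R.T
    rmsd = float(np.sqrt((diff * diff).sum() / len(pa)))
    return rmsd, R, ca - R @ cb


def rmsd_gradient(
    current: Geometry, reference: Geometry, heavy_only: bool = False
) -> np.ndarray:
    """Analytic ``(N, 3)`` gradient of the superposed RMSD w.r.t. ``current``.

    At the optimal superposition the derivative through the rotation and
    translation vanishes, leaving ``(x_c - R y_c) / (N * rmsd)`` per atom.
    Below :data:`RMSD_FLOOR` the gradient is singular and the zero vector is
    returned (documented contract).
    """
    rmsd, R, _ = superpose_rmsd(current, reference, heavy_only=heavy_only)
    grad = np.zeros_like(current.coords)
    if rmsd < RMSD_FLOOR:
        return grad
    mask = _atom_mask(current, heavy_only)
    pa = current.coords[mask]
    pb = reference.coords[mask]
    diff = (pa - pa.mean(axis=0)) - (pb - pb.mean(axis=0)) @ R.T
    grad[mask] = diff / (mask.sum() * rmsd)
    return grad


# ---------------------------------------------------------------------------
# rotational constants


def rotational_constants(geom: Geometry, unit: str = "cm-1") -> np.ndarray:
    """Principal rotational constants, sorted descending.

    Uses standard atomic masses and the rigid-rotor formula
    ``B = h / (8 pi^2 c I)``.  A zero principal moment (linear molecule)
    yields :data:`LINEAR_SENTINEL` for that axis.  ``unit`` is ``"cm-1"``
    or ``"MHz"``.
    """
    if geom.natoms < 2:
        raise GeometryError("rotational constants need at least 2 atoms")
    m = geom.masses
    x = geom.coords - np.average(geom.coords, axis=0, weights=m)
    inertia = np.zeros((3, 3))
    r2 = (x * x).sum(axis=1)
    for k in range(3):
        inertia[k, k] = (m * (r2 - x[:, k] ** 2)).sum()
    for k in range(3):
        for l in range(k + 1, 3):
            inertia[k, l] = inertia[l, k] = -(m * x[:, k] * x[:, l]).sum()
    moments = np.sort(np.linalg.eigvalsh(inertia))  # amu * A^2, ascending
    tol = max(moments[-1], 1.0) * 1e-10
    consts = np.empty(3)
    for idx, I in enumerate(moments):
        if I < tol:
            consts[idx] = LINEAR_SENTINEL
            continue
        I_si = I * AMU_KG * 1e-20  # kg m^2
        b_hz = PLANCK / (8 * math.pi**2 * I_si)
        if unit == "cm-1":
            consts[idx] = b_hz / C_LIGHT_CM
        elif unit == "MHz":
            consts[idx] = b_hz / 1e6
        else:
            raise ValueError(f"unknown unit {unit!r}")
    # ascending moments give descending constants (B ~ 1/I); sentinel first
    return consts


# ---------------------------------------------------------------------------
# multi-frame XYZ I/O

_ENERGY_RE = re.compile(r"E\s*=\s*([-+]?[0-9]*\.?[0-9]+(?:[eEdD][-+]?[0-9]+)?)")


def read_xyz(path, charge: int = 0, multiplicity: int = 1) -> list[Geometry]:
    """Read a (multi-frame) XYZ file.

    The comment line may carry the energy as ``E=<value>`` (Hartree).
    Malformed counts or coordinates raise :class:`XYZParseError` naming the
    line and frame.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames: list[Geometry] = []
    i = 0
    nframe = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(
                f"line {i + 1}: expected atom count for frame {nframe}, got {lines[i]!r}"
            )
        if natoms <= 0:
            raise XYZParseError(f"line {i + 1}: non-positive atom count in frame {nframe}")
        if i + 1 + natoms >= len(lines) + 1 and i + 1 + natoms > len(lines):
            raise XYZParseError(
                f"frame {nframe}: declared {natoms} atoms but file ends at line {len(lines)}"
            )
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        m = _ENERGY_RE.search(comment)
        energy = float(m.group(1).replace("D", "e").replace("d", "e")) if m else None
        symbols: list[str] = []
        coords = np.empty((natoms, 3))
        for a in range(natoms):
            ln = i + 2 + a
            if ln >= len(lines):
                raise XYZParseError(
                    f"frame {nframe}: declared {natoms} atoms but file ends at line {len(lines)}"
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise XYZParseError(f"line {ln + 1}: expected 'symbol x y z', got {lines[ln]!r}")
            symbols.append(parts[0])
            try:
                coords[a] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise XYZParseError(f"line {ln + 1}: non-numeric coordinate in {lines[ln]!r}")
        frames.append(
            Geometry.from_symbols(symbols, coords, charge=charge,
                                  multiplicity=multiplicity, energy=energy)
        )
        i += 2 + natoms
        nframe += 1
    if not frames:
        raise XYZParseError("no frames found")
    return frames


def write_xyz(path, geoms: Geometry | Iterable[Geometry], comments: list[str] | None = None):
    """Write one or more geometries as multi-frame XYZ (energy on comment)."""
    if isinstance(geoms, Geometry):
        geoms = [geoms]
    geoms = list(geoms)
    with open(path, "w") as fh:
        for idx, g in enumerate(geoms):
            fh.write(f"{g.natoms}\n")
            parts = []
            if g.energy is not None:
                parts.append(f"E={g.energy:.10f}")
            if comments is not None and idx < len(comments):
                parts.append(comments[idx])
            fh.write(" ".join(parts) + "\n")
            for s, xyz in zip(g.symbols, g.coords):
                fh.write(f"{s:<3s} {xyz[0]:18.10f} {xyz[1]:18.10f} {xyz[2]:18.10f}\n")
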