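"""Energy/gradient backends.

Every backend exposes ``evaluate(geom) -> EnergyGradient`` (energy in
Hartree, gradient in Hartree/A).  Two implementations live here:

* :class:`MorseBackend` — a pairwise Morse sum with a C1 switch to zero at a
  cutoff radius.  It supports bond breaking and forming, so LEPS-like
  reactive surfaces emerge for triatomics and every pipeline stage can be
  exercised against brute-force grid oracles at desk scale.
* :class:`ExternalEngineBackend` — a subprocess/file adapter for an external
  semi-empirical engine (GFN-xTB style).  The core stays dependency-free;
  the engine exchanges plain-text files and all engine files are retained
  for audit.

Backend calls are pure functions of the geometry; the external adapter
caches by a coordinate hash rounded to 1e-6 A.
"""

from __future__ import annotations

import hashlib
import shlex
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chemsys import Geometry, write_xyz


class BackendError(RuntimeError):
    """Backend could not evaluate the geometry (never a silent NaN)."""


class EngineFailure(BackendError):
    """External engine failed; carries exit code / stderr / diagnostics."""

    def __init__(self, message: str, returncode: int | None = None, stderr: str = ""):
        super().__init__(message)
        self.returncode = returncode
        self.stderr = stderr


@dataclass
class EnergyGradient:
    """Energy (Hartree) and gradient (Hartree/A) with an engine convergence flag."""

    energy: float
    gradient: np.ndarray
    converged: bool = True

    def __post_init__(self):
        self.gradient = np.asarray(self.gradient, dtype=float)
        if self.converged and not np.isfinite(self.energy):
            raise BackendError("converged result with non-finite energy")


def _pair_key(z1: int, z2: int) -> tuple[int, int]:
    return (z1, z2) if z1 <= z2 else (z2, z1)


@dataclass(frozen=True)
class MorseParams:
    """Per-element-pair Morse parameters and a global pair cutoff.

    ``pairs`` maps ``(Z1, Z2)`` (ordered, ``Z1 <= Z2``) to
    ``(D_e [Hartree], a [1/A], r_e [A])``.  Interactions are switched
    smoothly to zero between ``switch_fraction * cutoff`` and ``cutoff``.
    """

    pairs: dict
    cutoff: float = 8.0
    switch_fraction: float = 0.9

    def __post_init__(self):
        norm = {}
        for (z1, z2), (de, a, re_) in self.pairs.items():
            if de <= 0 or a <= 0 or re_ <= 0:
                raise ValueError(f"Morse parameters must be positive for pair ({z1},{z2})")
            norm[_pair_key(int(z1), int(z2))] = (float(de), float(a), float(re_))
        object.__setattr__(self, "pairs", norm)
        if not (0 < self.switch_fraction < 1):
            raise ValueError("switch_fraction must lie in (0, 1)")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


class MorseBackend:
    """Sum of pairwise Morse potentials with a C1 cutoff switch.

    Pair energy ``D_e * ((1 - exp(-a (r - r_e)))^2 - 1)`` multiplied by a
    cubic smoothstep that is exactly 1 below ``switch_fraction * cutoff``
    and falls to 0 (with zero slope) at the cutoff, so the bound-pair
    energy at ``r_e`` is exactly ``-D_e``.
    """

    def __init__(self, params: MorseParams):
        self.params = params

    def _pair(self, z1: int, z2: int, r: float) -> tuple[float, float]:
        """(energy, dE/dr) for one pair at separation r (within cutoff)."""
        key = _pair_key(z1, z2)
        try:
            de, a, re_ = self.params.pairs[key]
        except KeyError:
            raise BackendError(f"missing Morse parameters for element pair {key}")
        x = 1.0 - np.exp(-a * (r - re_))
        e = de * (x * x - 1.0)
        dedr = 2.0 * de * a * x * (1.0 - x)
        rc = self.params.cutoff
        r_on = self.params.switch_fraction * rc
        if r > r_on:
            t = (r - r_on) / (rc - r_on)
            s = 1.0 - t * t * (3.0 - 2.0 * t)
            dsdr = -6.0 * t * (1.0 - t) / (rc - r_on)
            e, dedr = e * s, dedr * s + e * dsdr
        return e, dedr

    def evaluate(self, geom: Geometry) -> EnergyGradient:
        x = geom.coords
        if not np.all(np.isfinite(x)):
            raise BackendError("non-finite coordinates")
        energy = 0.0
        grad = np.zeros_like(x)
        n = geom.natoms
        for i in range(n):
            for j in range(i + 1, n):
                d = x[i] - x[j]
                r = float(np.linalg.norm(d))
                if r >= self.params.cutoff:
                    continue
                if r < 1e-10:
                    raise BackendError(f"coincident atoms {i},{j}")
                e, dedr = self._pair(geom.elements[i], geom.elements[j], r)
                energy += e
                g = (dedr / r) * d
                grad[i] += g
                grad[j] -= g
        return EnergyGradient(energy=energy, gradient=grad)


def toy_reactive_ff(params: MorseParams) -> MorseBackend:
    """Build the toy reactive force field backend from Morse parameters."""
    return MorseBackend(params)


# ---------------------------------------------------------------------------
# external engine adapter


def _geometry_key(geom: Geometry) -> str:
    rounded = np.round(geom.coords, 6)
    h = hashlib.sha256()
    h.update(repr(geom.elements).encode())
    h.update(f"{geom.charge}/{geom.multiplicity}".encode())
    h.update(rounded.tobytes())
    return h.hexdigest()


class ExternalEngineBackend:
    """Subprocess adapter to an external engine.

    The ``command_template`` is formatted with ``{xyz}``, ``{charge}``,
    ``{mult}`` and run inside a fresh per-call directory under ``workdir``
    containing ``input.xyz``.  On success the engine must leave a plain-text
    file (default ``gradient.out``) of the form::

        energy <Hartree>
        gx gy gz        # one row per atom, Hartree/A

    Nonzero exit, unparsable output, or a non-convergence marker raise
    :class:`EngineFailure` with the engine diagnostics attached; callers at
    the pipeline level record and skip the trajectory rather than aborting.
    All engine files are retained under ``workdir`` for audit.
    """

    def __init__(self, command_template: str, workdir, output_name: str = "gradient.out",
                 timeout: float = 600.0):
        self.command_template = command_template
        self.workdir = Path(workdir)
        self.workdir.mkdir(parents=True, exist_ok=True)
        self.output_name = output_name
        self.timeout = timeout
        self._cache: dict[str, EnergyGradient] = {}
        self.n_invocations = 0

    def evaluate(self, geom: Geometry) -> EnergyGradient:
        key = _geometry_key(geom)
        if key in self._cache:
            return self._cache[key]
        calldir = self.workdir / f"call_{self.n_invocations:05d}"
        calldir.mkdir(parents=True, exist_ok=True)
        xyz_path = calldir / "input.xyz"
        write_xyz(xyz_path, geom)
        cmd = self.command_template.format(
            xyz=xyz_path.name, charge=geom.charge, mult=geom.multiplicity
        )
        self.n_invocations += 1
        try:
            proc = subprocess.run(
                shlex.split(cmd), cwd=calldir, capture_output=True, text=True,
                timeout=self.timeout,
            )
        except (OSError, subprocess.TimeoutExpired) as exc:
            raise EngineFailure(f"engine launch failed: {exc}")
        (calldir / "stdout.log").write_text(proc.stdout)
        (calldir / "stderr.log").write_text(proc.stderr)
        if proc.returncode != 0:
            raise EngineFailure(
                f"engine exited with status {proc.returncode}",
                returncode=proc.returncode, stderr=proc.stderr,
            )
        out = calldir / self.output_name
        if not out.exists():
            raise EngineFailure(f"engine produced no {self.output_name}", stderr=proc.stderr)
        result = self._parse(out.read_text(), geom.natoms)
        self._cache[key] = result
        return result

    @staticmethod
    def _parse(text: str, natoms: int) -> EnergyGradient:
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines or not lines[0].lower().startswith("energy"):
            raise EngineFailure("engine output missing 'energy' header line")
        try:
            energy = float(lines[0].split()[1])
        except (IndexError, ValueError):
            raise EngineFailure(f"unparsable energy line: {lines[0]!r}")
        rows = lines[1 : 1 + natoms]
        if len(rows) != natoms:
            raise EngineFailure(f"expected {natoms} gradient rows, found {len(rows)}")
        try:
            grad = np.array([[float(v) for v in row.split()[:3]] for row in rows])
        except ValueError:
            raise EngineFailure("non-numeric gradient entry in engine output")
        if grad.shape != (natoms, 3):
            raise EngineFailure("gradient rows must have three components")
        return EnergyGradient(energy=energy, gradient=grad)


def external_engine_adapter(command_template: str, workdir, **kw) -> ExternalEngineBackend:
    """Factory mirroring :func:`toy_reactive_ff` for external engines."""
    return ExternalEngineBackend(command_template, workdir, **kw)
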