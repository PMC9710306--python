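"""Shared fixtures: toy systems with brute-force oracle data.

Oracle computation (dense grid search) and full pipeline runs are the
expensive pieces, so they are session-scoped and shared across tests.
"""

import numpy as np
import pytest

from iacta import (
    Constraint,
    Geometry,
    InternalCoordinate,
    MorseBackend,
    MorseParams,
    RunConfig,
    constrained_minimize,
    make_collinear_exchange,
    run_iacta,
)
from iacta.metadyn import MDParams
from iacta.synthetic import make_torsional_chain


@pytest.fixture(scope="session")
def exchange_spec():
    """Symmetric collinear exchange system with oracle data."""
    return make_collinear_exchange()


@pytest.fixture(scope="session")
def exchange_specs_all(exchange_spec):
    """Symmetric plus two asymmetric exchange systems."""
    return [
        exchange_spec,
        make_collinear_exchange(asymmetry=0.15),
        make_collinear_exchange(asymmetry=0.30),
    ]


@pytest.fixture(scope="session")
def torsion_system():
    """(relaxed geometry, backend) for the two-well torsional chain."""
    geom, params = make_torsional_chain()
    backend = MorseBackend(params)
    relaxed = constrained_minimize(geom, [], backend).geometry
    return relaxed, backend


@pytest.fixture
def morse_diatomic():
    """(geometry, backend, (De, a, re)) for a single Morse bond."""
    de, a, re_ = 0.1, 1.9, 0.9
    params = MorseParams(pairs={(1, 1): (de, a, re_)})
    geom = Geometry((1, 1), np.array([[0.0, 0.0, 0.0], [0.0, 0.0, re_]]))
    return geom, MorseBackend(params), (de, a, re_)


def toy_run_config(spec, seed=7, budget=40, **overrides):
    """Standard study-condition configuration for toy exchange runs."""
    kwargs = dict(
        geometry=spec.geometry,
        coordinate=InternalCoordinate("distance", (0, 1)),
        backend=spec.backend(),
        scan_step=0.05,
        md=MDParams(timestep=0.5, temperature=300.0, wall_radius=4.0),
        md_time_per_atom_ps=0.3,
        trajectory_budget=budget,
        seed=seed,
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture(scope="session")
def exchange_run_reports(exchange_specs_all):
    """Full pipeline reports for the three exchange systems (shared)."""
    return [run_iacta(toy_run_config(spec)) for spec in exchange_specs_all]
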