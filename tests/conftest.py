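"""Shared fixtures: small designed genomes and session-scoped desk runs."""

from __future__ import annotations

import numpy as np
import pytest

from digevol.annotation import DEFAULT_PARAMS
from digevol.fixtures import FixtureSpec, GeneSpec, make_annotated_fixture
from digevol.phenotype import Evaluator, PhenotypicTarget


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def target():
    return PhenotypicTarget()


@pytest.fixture(scope="session")
def evaluator(target):
    return Evaluator(target)


@pytest.fixture(scope="session")
def one_gene_fixture():
    """A single strongly contributing gene plus inert, mutation-safe filler."""
    rng = np.random.default_rng(11)
    spec = FixtureSpec(
        genes=[GeneSpec(m_bits=(1, 0, 0, 0, 1), w_bits=(1,), h_bits=(1, 1))],
        d=0,
        filler_bp=80,
        filler="inert",
        mutation_safe=True,
    )
    return make_annotated_fixture(spec, rng), spec


@pytest.fixture(scope="session")
def two_gene_fixture():
    """Two transcription units with hairpin-free promoters (flip at 11).

    With the promoter's internal hairpin windows removed, losing a
    terminator lets the RNA run through to the next unit instead of
    being silently rescued, so terminator mutations can be non-neutral.
    """
    rng = np.random.default_rng(11)
    spec = FixtureSpec(
        genes=[
            GeneSpec(m_bits=(1, 0, 0, 0, 1), w_bits=(1,), h_bits=(1, 1)),
            GeneSpec(m_bits=(0, 1, 1, 0, 1), w_bits=(1, 1), h_bits=(1, 0, 1)),
        ],
        d=1,
        promoter_flips=(11,),
        filler_bp=100,
        filler="inert",
        mutation_safe=True,
    )
    return make_annotated_fixture(spec, rng), spec


# ---------------------------------------------------------------------------
# desk-scale experiment suite (shared by several acceptance tests)

N_CLONE_SEEDS = 5


@pytest.fixture(scope="session")
def desk_source():
    """Pre-evolved wild-type-like source population (desk scale)."""
    from digevol.experiments import make_preevolved_population

    return make_preevolved_population(seed=7)


@pytest.fixture(scope="session")
def mutator_outcomes(desk_source):
    """Five seeded mutator-clone propagations of the shared source."""
    from digevol.experiments import run_clone_protocol

    return [
        run_clone_protocol(desk_source, seed=300 + i, protocol="mutator")
        for i in range(N_CLONE_SEEDS)
    ]
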