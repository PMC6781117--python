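"""Shared fixtures: tiny hand-built genotype fixtures and simulated data."""

from __future__ import annotations

import numpy as np
import pytest

from matesel.simulate import GeneratorConfig, generate_dataset
from matesel.types import Dataset, Individual, MhcGenotype, MicrosatGenotype


def make_individual(
    ind_id: str,
    genotypes: list[tuple[str, int | None, int | None]],
    mhc: list[tuple[str, str | None, str | None]] = (),
    sex: str = "male",
    pond: str = "P1",
    motif: int = 2,
) -> Individual:
    return Individual(
        ind_id,
        sex,
        pond,
        [MicrosatGenotype(l, a, b, motif_length=motif) for l, a, b in genotypes],
        [MhcGenotype(l, a, b) for l, a, b in mhc],
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """A compact synthetic study (1 pond, 12+8 adults) with offspring."""
    config = GeneratorConfig(
        seed=7,
        ponds=((12, 8),),
        n_microsat_loci=5,
        n_clutches=10,
        clutch_lambda=6.0,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def study_scale_null():
    """One study-scale dataset (3 ponds, 182 adults) under uniform choice."""
    return generate_dataset(GeneratorConfig(seed=11), include_offspring=False)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
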