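"""Shared fixtures: a small synthetic world exercising every pipeline stage."""

import numpy as np
import pytest

from genediv.simulate import (
    GeneLengthModel,
    SetDefinition,
    SyntheticSpec,
    simulate_annotation,
    simulate_genome,
)


@pytest.fixture(scope="session")
def tiny_spec():
    """A ~1.2 Mb world with elevated MHC-like and null innate-like sets."""
    return SyntheticSpec(
        seed=7,
        chrom_length=1_200_000,
        n_background_genes=20,
        gene_length=GeneLengthModel(mean_core=6_000, sigma_log=0.3, min_core=1_500),
        heterozygosity=1.0e-3,
        divergence=1.2e-2,
        set_definitions=(
            SetDefinition("mhc_like", 5, multiplier=8.0, go_marker="GO:MHC0001"),
            SetDefinition("innate_like", 8, multiplier=1.0, go_marker="GO:INN0001"),
        ),
    )


@pytest.fixture(scope="session")
def tiny_annotation(tiny_spec):
    return simulate_annotation(tiny_spec)


@pytest.fixture(scope="session")
def tiny_ds(tiny_spec, tiny_annotation):
    return simulate_genome(
        tiny_spec, individual_ids=["ind1", "ind2", "ind3"], annotation=tiny_annotation
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
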