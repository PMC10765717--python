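"""Shared fixtures: one small synthetic study generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from seedregnet import (
    GeneratorConfig,
    counts_to_tpm,
    extract_promoters,
    full_design,
    generate_expression,
    generate_genome,
    generate_metabolome,
    seed_design,
)


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    return GeneratorConfig(
        n_genes=40, n_tfs=6, n_metabolites=30, n_contigs=2, rng_seed=3
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    """Genome, annotation, motifs and truth for the small study."""
    genome, annotation, pwms, truth = generate_genome(small_cfg)
    return dict(genome=genome, annotation=annotation, pwms=pwms, truth=truth)


@pytest.fixture(scope="session")
def small_promoters(small_bundle):
    return extract_promoters(small_bundle["annotation"], small_bundle["genome"])


@pytest.fixture(scope="session")
def small_counts(small_cfg, small_bundle):
    return generate_expression(small_cfg, full_design(), small_bundle["truth"])


@pytest.fixture(scope="session")
def small_tpm(small_counts):
    return counts_to_tpm(small_counts)


@pytest.fixture(scope="session")
def small_metabolome(small_cfg, small_bundle):
    return generate_metabolome(small_cfg, seed_design(), small_bundle["truth"])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
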