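"""Shared fixtures: small synthetic worlds and fast harmonization configs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import refharm as rh


@pytest.fixture(scope="session")
def small_config() -> rh.SyntheticStudyConfig:
    """A desk-scale study world: 300 genes, 2 platforms, 2 replicates."""
    return rh.SyntheticStudyConfig(
        n_genes=300,
        platforms=(
            rh.PlatformSpec("chipA", scale_factor=1.0),
            rh.PlatformSpec("chipB", scale_factor=5.0),
        ),
        n_replicates_per_type=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config) -> rh.SyntheticStudy:
    return rh.generate_study(small_config)


@pytest.fixture(scope="session")
def small_references(small_config):
    return rh.generate_reference_sets(small_config)


@pytest.fixture(scope="session")
def fast_harmonization_config() -> rh.HarmonizationConfig:
    """Few clusters/repeats: keeps single-profile tests in milliseconds."""
    return rh.HarmonizationConfig(
        K=8, L=6, n_repeats=3, n_restarts=1, seed=7
    )


@pytest.fixture(scope="session")
def small_bundle(small_references, fast_harmonization_config):
    P0, Q = small_references
    return rh.build_bundle(P0, Q, fast_harmonization_config)


def make_matrix(values, gene_ids=None, sample_ids=None, scale="linear", **kw):
    """Convenience constructor for literal test matrices."""
    values = np.asarray(values, dtype=float)
    genes = gene_ids or [f"G{i}" for i in range(values.shape[0])]
    samples = sample_ids or [f"S{j}" for j in range(values.shape[1])]
    return rh.ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale=scale, **kw
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
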