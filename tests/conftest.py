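"""Shared synthetic fixtures: one small cohort reused across test modules."""

import numpy as np
import pytest

import rfuwas as rw


@pytest.fixture(scope="session")
def small_cfg():
    return rw.SimulationConfig(
        n_individuals=80,
        n_rfus=15,
        n_variants_per_locus={"TRB": 40, "HLA": 25},
        repertoire_size_range=(300, 600),
        latent_noise_sd=0.1,
        seed=11,
    )


@pytest.fixture(scope="session")
def genotypes(small_cfg):
    return rw.simulate_genotypes(small_cfg)


@pytest.fixture(scope="session")
def effects(small_cfg, genotypes):
    return rw.simulate_rfu_effects(small_cfg, genotypes)


@pytest.fixture(scope="session")
def centroids_templates(small_cfg):
    return rw.simulate_centroids(small_cfg)


@pytest.fixture(scope="session")
def repertoires(small_cfg, genotypes, effects, centroids_templates):
    centroids, templates = centroids_templates
    return rw.simulate_repertoires(genotypes, effects, centroids, small_cfg, templates)


@pytest.fixture(scope="session")
def abundance(repertoires, centroids_templates):
    centroids, _ = centroids_templates
    return rw.RFUAssigner().fit(centroids).transform(repertoires)


@pytest.fixture(scope="session")
def covariates(small_cfg, abundance):
    return rw.simulate_covariates(small_cfg, abundance.individual_ids)


@pytest.fixture(scope="session")
def residual_traits(abundance, covariates):
    filtered = rw.filter_rfus(abundance)
    return rw.normalize_pipeline(filtered, covariates, n_hidden_factors=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
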