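"""Shared fixtures: compact synthetic studies reused across the suite."""

import warnings

import pytest
from hypothesis import settings

from trophiq import GeneratorConfig, generate_study

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def small_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """A compact study: 7 sites, 2 primers x 2 replicates, full noise model."""
    kw = dict(
        seed=seed,
        n_sites_allopatric_a=2, n_sites_allopatric_b=2,
        n_sites_allotopic_a=1, n_sites_allotopic_b=1, n_sites_syntopic=1,
        samples_per_site=3,
        n_bins_total=150, pool_size=50, pool_overlap=0.5,
        availability_extra_bins=20, n_sweep_samples_per_site=2,
        n_contaminants=4, batch_size=10,
    )
    kw.update(overrides)
    return GeneratorConfig(**kw)


def recovery_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Noiseless recovery fixture: sparse per-sample composition (the regime
    where occurrence-based wPOO tracks pool proportions), 40 samples per
    species per stratum."""
    kw = dict(
        seed=seed,
        n_sites_allopatric_a=4, n_sites_allopatric_b=4,
        n_sites_allotopic_a=4, n_sites_allotopic_b=4, n_sites_syntopic=4,
        samples_per_site=10, sample_alpha=2.5,
        n_bins_total=160, pool_size=60, pool_overlap=0.5, syntopic_shift=0.5,
        availability_extra_bins=30,
    )
    kw.update(overrides)
    return GeneratorConfig(**kw).noiseless()


@pytest.fixture(scope="session")
def study():
    """One compact noisy study shared by read-only tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_study(small_config(seed=42))


@pytest.fixture(scope="session")
def noiseless_study():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_study(small_config(seed=7).noiseless())
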