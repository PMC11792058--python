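import dataclasses

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from chromdyn.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A quick, fully-featured study: every generator exercised at low n."""
    return SimConfig(
        seed=11, n_genes=60, n_naive=8, n_primed=8, n_lineage=8,
        n_loci_per_category={
            "permanently_open": 10, "accelerated_opening": 8,
            "decelerated_opening": 8, "accelerated_closing": 8,
            "decelerated_closing": 8, "kd_specific_open": 12,
            "kd_specific_closed": 8, "stable_other": 8,
        },
        n_interactors=6, n_shared_interactors=3, n_background=30,
        n_contaminants=3,
    )


@pytest.fixture(scope="session")
def small_data(small_cfg):
    return simulate_study(small_cfg, with_tracks=True)


@pytest.fixture(scope="session")
def default_data():
    """The study at its default (full) size, without coverage tracks."""
    return simulate_study(SimConfig(seed=1), with_tracks=False)


@pytest.fixture()
def noise_free_cfg(small_cfg) -> SimConfig:
    return dataclasses.replace(small_cfg, expr_noise_sd=0.0, peak_dropout=0.0)
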