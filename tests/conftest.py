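import numpy as np
import pytest

from radhyb import ancestry
from radhyb.synth import SimConfig, make_reference_panels


@pytest.fixture(scope="session")
def diag_config() -> SimConfig:
    """Six fully diagnostic loci, the study's marker-panel geometry."""
    return SimConfig(n_loci=6, n_diagnostic=6, n_panel=5, seed=11)


@pytest.fixture(scope="session")
def diag_panels(diag_config):
    return make_reference_panels(diag_config)


@pytest.fixture(scope="session")
def diag_ref(diag_panels):
    """Pseudocount-free panel: frequencies exactly 0/1 at every locus."""
    return ancestry.estimate_allele_freqs(
        diag_panels.panel_a, diag_panels.panel_b, pseudocount=0.0
    )


@pytest.fixture(scope="session")
def big_config() -> SimConfig:
    """300 fixed-difference loci, the locus-capped genomic analysis scale."""
    return SimConfig(n_loci=300, n_diagnostic=300, n_panel=5, seed=29)


@pytest.fixture(scope="session")
def big_panels(big_config):
    return make_reference_panels(big_config)


@pytest.fixture(scope="session")
def big_ref(big_panels):
    return ancestry.estimate_allele_freqs(big_panels.panel_a, big_panels.panel_b)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
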