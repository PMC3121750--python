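import numpy as np
import pytest

from archpipe.cohort import ArchitectureSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Polygenic cohort with signal: 150 cases / 450 controls, 400 SNPs."""
    spec = ArchitectureSpec(m=400, m_causal=60, h2_l=0.4, K=0.05, seed=424242)
    return simulate_cohort(spec, 150, 450)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with zero heritability: status independent of genotype."""
    spec = ArchitectureSpec(m=300, m_causal=0, h2_l=0.0, K=0.1, seed=51423)
    return simulate_cohort(spec, 200, 400)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
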