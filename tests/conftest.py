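import numpy as np
import pytest

from ampedit import ScenarioSpec, cut_site, make_amplicon, simulate_reads


@pytest.fixture(scope="session")
def amp_guide():
    """A 240-nt amplicon with one planted protospacer+NGG."""
    return make_amplicon(240, 0.5, seed=11)


@pytest.fixture(scope="session")
def clean_sample(amp_guide):
    """2,000 error-free reads edited at 40%."""
    amplicon, guide = amp_guide
    scenario = ScenarioSpec(edit_fraction=0.4, error_rate=0.0, n_reads=2000, seed=7)
    reads, truths = simulate_reads(amplicon, guide, scenario)
    return amplicon, guide, reads, truths


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
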