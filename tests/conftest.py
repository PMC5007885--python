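import numpy as np
import pytest

from agoblocks import io as agio
from agoblocks import simulate as sim


@pytest.fixture(scope="session")
def table_models():
    """The 50 packaged block models (match probability 0.9)."""
    return {m.block_id: m for m in agio.load_packaged_blocks()}


@pytest.fixture(scope="session")
def sharp_models():
    """Packaged models at the generator's default conservation (0.95)."""
    return sim.table_models()


@pytest.fixture(scope="session")
def small_family(sharp_models):
    """A reduced four-clade family (scale 0.15, ~28 proteins) with truth."""
    specs = sim.default_clade_specs(scale=0.15)
    proteins, truth = sim.generate_family(specs, sharp_models, seed=7)
    return specs, proteins, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
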