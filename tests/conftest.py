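import pytest

from netpharm import (Formulary, Ingredient, SynthesisConfig,
                      load_reference_formulary, write_bundle)
from netpharm.metrics import load_reference_centralities


@pytest.fixture(scope="session")
def reference_formulary():
    """The packaged three-herb ingredient table (41 records)."""
    return load_reference_formulary()


@pytest.fixture(scope="session")
def reference_centralities():
    """The packaged 26-row hub centrality table."""
    return load_reference_centralities()


@pytest.fixture
def tiny_formulary():
    herbs = ("HerbA", "HerbB")
    ings = (
        Ingredient("M1", "alpha", 55.0, 0.5, "HerbA"),
        Ingredient("M2", "beta", 20.0, 0.5, "HerbA"),   # fails OB
        Ingredient("M3", "gamma", 40.0, 0.05, "HerbB"),  # fails DL
        Ingredient("M1", "alpha", 55.0, 0.5, "HerbB"),   # shared molecule
    )
    return Formulary(herbs, ings)


@pytest.fixture(scope="session")
def synthetic_bundle(tmp_path_factory):
    """A default-scale synthetic input bundle with planted ground truth."""
    out = tmp_path_factory.mktemp("bundle")
    cfg = SynthesisConfig(seed=12345, planted_terms=((20, 40),))
    truth = write_bundle(cfg, out)
    return out, cfg, truth
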