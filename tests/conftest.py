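import warnings

import pytest

from dreamer import DiffusionConfig, GeneratorConfig, generate, run_dreamer


@pytest.fixture(scope="session")
def default_kg():
    """One synthetic KG at generator defaults, shared across the session."""
    kg, truth = generate(GeneratorConfig(rng_seed=1))
    return kg, truth


@pytest.fixture(scope="session")
def pipeline_result(default_kg):
    """Full pipeline run (K=200) on the default synthetic KG."""
    kg, _ = default_kg
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_dreamer(kg, DiffusionConfig(n_permutations=200, rng_seed=1))


@pytest.fixture()
def quiet():
    """Silence expected pipeline warnings (low-K, off-network seeds)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
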