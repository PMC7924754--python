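import numpy as np
import pytest

from rootcue import synth


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def small_params(seed=1, **overrides):
    """Generator settings for quick tests: a few hundred features."""
    defaults = dict(
        seed=seed,
        n_features=300,
        n_diff_features=10,
        n_interaction_features=0,
        n_genotype_features=0,
        n_samples_per_cell=6,
    )
    defaults.update(overrides)
    return synth.SynthParams(**defaults)


@pytest.fixture
def small_table():
    table, truth = synth.generate_feature_table(small_params())
    return table, truth
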