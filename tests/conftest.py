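import numpy as np
import pandas as pd
import pytest

from tmescore import CohortParams, generate_cohort


@pytest.fixture(scope="session")
def small_params():
    """A fast cohort: same structure as the default, scaled down."""
    return CohortParams(
        n_samples=60,
        n_genes=120,
        n_signatures=6,
        genes_per_signature=10,
        effect_size=3.0,
        noise_sd=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return generate_cohort(small_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_expr():
    """The 4-gene single-ladder matrix used by the worked running-sum example."""
    return pd.DataFrame(
        {"s1": [4.0, 3.0, 2.0, 1.0], "s2": [1.0, 2.0, 3.0, 4.0]},
        index=["g1", "g2", "g3", "g4"],
    )
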