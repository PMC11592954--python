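import numpy as np
import pytest

import evlm


@pytest.fixture(scope="session")
def citrus():
    return evlm.citrus()


@pytest.fixture(scope="session")
def citrus_design(citrus):
    return evlm.build_design(citrus, ["1", "tree", "pest", "tree:pest"])


@pytest.fixture(scope="session")
def citrus_interaction_cols(citrus_design):
    return tuple(c for c in citrus_design.column_names if ":" in c)


@pytest.fixture(scope="session")
def citrus_comparison(citrus, citrus_design, citrus_interaction_cols):
    return evlm.compare_nested_A(citrus, citrus_design, citrus_interaction_cols)


@pytest.fixture(scope="session")
def citrus_pair(citrus_design, citrus_interaction_cols):
    return evlm.ModelPair(citrus_design, citrus_interaction_cols)


def random_nested_instance(rng, n_max=40, r_max=8):
    """A random full-rank nested design with a gaussian response."""
    n = int(rng.integers(8, n_max + 1))
    r = int(rng.integers(2, min(r_max, n - 2) + 1))
    q = int(rng.integers(1, r))
    X = np.column_stack([np.ones(n), rng.standard_normal((n, r - 1))])
    y = rng.standard_normal(n) + X @ rng.standard_normal(r)
    return n, r, q, X, y
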