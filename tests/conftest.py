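import numpy as np
import pandas as pd
import pytest

from immunodecon.datatypes import ProportionEstimate, SignatureMatrix
from immunodecon.synthetic import GeneratorConfig, generate_cohort


def make_block_signature(n_genes, n_types, rng, uplift=50.0):
    """Small marker-block signature for oracle tests: each type gets a
    disjoint block of high-expression markers on a low log-normal baseline."""
    values = rng.lognormal(0.0, 0.25, size=(n_genes, n_types))
    per = n_genes // n_types
    for j in range(n_types):
        values[j * per:(j + 1) * per, j] = rng.lognormal(np.log(uplift), 0.25, per)
    df = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"ct{j}" for j in range(n_types)],
    )
    return SignatureMatrix(df)


@pytest.fixture(scope="session")
def small_signature():
    return make_block_signature(200, 5, np.random.default_rng(11))


@pytest.fixture(scope="session")
def default_cohort():
    """One noisy 4-archetype cohort shared by read-only tests."""
    return generate_cohort(GeneratorConfig(n_samples=300, seed=7))


@pytest.fixture(scope="session")
def noiseless_cohort():
    return generate_cohort(GeneratorConfig(n_samples=30, noise_sigma=0.0, seed=13))


@pytest.fixture()
def random_fractions():
    rng = np.random.default_rng(21)
    frac = rng.dirichlet(np.ones(22), size=40)
    from immunodecon.aggregation import LM22_CELL_TYPES

    return ProportionEstimate(
        fractions=pd.DataFrame(
            frac, index=[f"s{i}" for i in range(40)], columns=LM22_CELL_TYPES
        )
    )
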