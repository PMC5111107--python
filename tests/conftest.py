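import numpy as np
import pandas as pd
import pytest

from crcbench.expression import ExpressionMatrix
from crcbench.signatures import builtin_signatures
from crcbench.simulate import simulate_cohort


def make_matrix(values, genes=None, samples=None, dataset=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    ds = None
    if dataset is not None:
        ds = pd.Series(dataset, index=samples)
    return ExpressionMatrix(df, ds)


@pytest.fixture
def toy_matrix():
    return make_matrix([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
                       genes=["GA", "GB"], samples=["s1", "s2", "s3"])


@pytest.fixture(scope="session")
def builtin_sigs():
    return builtin_signatures()


@pytest.fixture(scope="session")
def planted_cohort():
    """A medium cohort with all built-in signatures planted at 3 log2 units
    and a 1:3 hazard contrast; shared across survival/pipeline tests."""
    sigs = list(builtin_signatures().values())
    matrix, clinical, truth = simulate_cohort(
        n=600, genes=800, subtype_props={"low": 0.5, "high": 0.5},
        signatures_to_plant=sigs, effect_size=3.0,
        hazard_map={"low": 1.0, "high": 3.0}, baseline_rate=0.02,
        censor_rate=0.2, seed=11)
    return matrix, clinical, truth
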