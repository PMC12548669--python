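import numpy as np
import pytest

from mbnet import SUVRDataset, WeightedNetwork, example_cohort_spec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Three balanced 60-subject groups, 30 VOIs — cheap, reused everywhere."""
    spec = example_cohort_spec({"CU": 60, "MCI": 60, "AD": 60}, d=30, seed=101)
    return generate_cohort(spec)


@pytest.fixture()
def tiny_dataset():
    rng = np.random.default_rng(3)
    values = 1.0 + 0.2 * rng.random((8, 4))
    return SUVRDataset(
        values=values,
        subject_ids=[f"s{i}" for i in range(8)],
        voi_names=["A", "B", "C", "D"],
        group="CU",
    )


def make_network(weights, voi_names=None, pvalues=None, **kw):
    """Helper: wrap a raw symmetric weight matrix as a WeightedNetwork."""
    weights = np.asarray(weights, dtype=float)
    d = weights.shape[0]
    if pvalues is None:
        pvalues = np.zeros((d, d))
        np.fill_diagonal(pvalues, 1.0)
    if voi_names is None:
        voi_names = [f"V{i}" for i in range(d)]
    return WeightedNetwork(weights=weights, pvalues=pvalues, voi_names=voi_names, **kw)


@pytest.fixture()
def toy_network():
    """Fixed 5-node weighted graph used against brute-force oracles."""
    w = np.array(
        [
            [0.0, 0.8, 0.0, 0.3, 0.0],
            [0.8, 0.0, -0.5, 0.0, 0.0],
            [0.0, -0.5, 0.0, 0.9, 0.2],
            [0.3, 0.0, 0.9, 0.0, 0.0],
            [0.0, 0.0, 0.2, 0.0, 0.0],
        ]
    )
    return make_network(w)
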