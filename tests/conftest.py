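import numpy as np
import pytest

import idpreweight as ir


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_dataset():
    """Tiny 5-frame, 2-observable dataset for solver unit tests."""
    preds = np.array(
        [
            [0.0, 1.0],
            [1.0, 0.5],
            [2.0, -0.5],
            [3.0, 0.0],
            [4.0, 2.0],
        ]
    )
    block = ir.ObservableBlock(
        data_type="toy",
        predictions=preds,
        exp_values=np.array([1.5, 0.8]),
        sigma_md=np.array([0.1, 0.1]),
        sigma_reg=0.3,
    )
    return ir.ExperimentalDataset([block])


def make_loo_dataset(seed=0, n=500, m=5):
    """Blocks: A informative+mismatched, B redundant copy of A, C independent.

    C's targets sit a known offset away from the prior averages so its
    normalizing prior RMSE is nonzero.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    w_true = ir.normalize_weights(np.exp(0.8 * z))
    prior = np.full(n, 1.0 / n)

    a_preds = np.column_stack([z * c + np.sin(c * z) for c in np.linspace(0.5, 2, m)])
    block_a = ir.ObservableBlock("A", a_preds, a_preds.T @ w_true)
    block_b = ir.ObservableBlock("B", a_preds.copy(), a_preds.T @ w_true)
    c_preds = rng.standard_normal((n, m))
    c_exp = c_preds.T @ prior + rng.normal(0.0, 0.5, size=m)
    block_c = ir.ObservableBlock("C", c_preds, c_exp)
    return ir.ExperimentalDataset([block_a, block_b, block_c]), prior


@pytest.fixture(scope="session")
def loo_results():
    dataset, prior = make_loo_dataset()
    return ir.loo_crossval(prior, dataset, kish_target=0.10)


@pytest.fixture(scope="session")
def default_protocol_run():
    """One full calibration on the default synthetic fixture, shared by tests.

    N=2000 frames, 3 blocks x 10 observables, biased prior vs tilted truth.
    """
    dataset, w_true = ir.default_fixture(seed=0)
    prior = np.full(dataset.n_frames, 1.0 / dataset.n_frames)
    result = ir.run_protocol(prior, dataset)
    return dataset, w_true, prior, result
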