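import numpy as np
import pytest

import clonalprof as cp


@pytest.fixture(scope="session")
def toy_cf():
    return cp.gen_toy_cf()


@pytest.fixture(scope="session")
def uniform_model():
    return cp.ContextModel.uniform()


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic dataset (exact input component, noisy Y)."""
    return cp.gen_dataset(cp.SynthConfig(n_cf=40, seqs_per_cf=30, seed=11))


@pytest.fixture(scope="session")
def exact_dataset():
    """Synthetic dataset with the noise-free true profiles as Y."""
    ds = cp.gen_dataset(cp.SynthConfig(n_cf=30, seqs_per_cf=5, seed=7))
    y = cp.ProfileTensor(ds.truth["true_profiles"].copy(),
                         ds.y.defined.copy(), ds.y.cf_ids)
    return cp.SynthDataset(ds.cfs, ds.x, y, ds.xstar, ds.truth)


def onehot_row(aa_index: int) -> np.ndarray:
    row = np.zeros(cp.N_AA)
    row[aa_index] = 1.0
    return row


@pytest.fixture
def make_pair():
    """Factory for matched (y, yhat) single-CF tensors from row dicts."""

    def build(rows_y, rows_yhat):
        freqs_y = np.zeros((1, cp.N_POSITIONS, cp.N_AA))
        freqs_h = np.zeros((1, cp.N_POSITIONS, cp.N_AA))
        defined = np.zeros((1, cp.N_POSITIONS), dtype=bool)
        for j, row in rows_y.items():
            freqs_y[0, j - 1] = row
            defined[0, j - 1] = True
        for j, row in rows_yhat.items():
            freqs_h[0, j - 1] = row
        y = cp.ProfileTensor(freqs_y, defined.copy(), ("cf",))
        yhat = cp.ProfileTensor(freqs_h, defined.copy(), ("cf",))
        return y, yhat

    return build
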