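import numpy as np
import pytest

from srscat.bank import ItemBank, ItemParameters
from srscat.simulate import SyntheticBankSpec, generate_bank, make_fixture


@pytest.fixture(scope="session")
def default_bank():
    bank, _ = generate_bank(seed=7)
    return bank


@pytest.fixture(scope="session")
def default_bank_truth():
    return generate_bank(seed=7)


@pytest.fixture(scope="session")
def high_disc_bank():
    spec = SyntheticBankSpec(discrimination_median=2.0, discrimination_sigma=0.1)
    bank, _ = generate_bank(spec, seed=5)
    return bank


@pytest.fixture(scope="session")
def toy_bank():
    """Three hand-written 4-category items, no masks."""
    return ItemBank(
        [
            ItemParameters(1, 1.4, (-0.8, 0.1, 0.9)),
            ItemParameters(2, 1.9, (-0.2, 0.6, 1.4)),
            ItemParameters(3, 1.1, (-1.2, -0.1, 1.1)),
        ]
    )


@pytest.fixture(scope="session")
def tiny_study():
    return make_fixture("tiny")


def grm_sample_matrix(bank, thetas, rng):
    """Independent keyed GRM sampler used by tests (inverse-CDF with its own
    logistic arithmetic, not the package's sampler)."""
    thetas = np.asarray(thetas, float)
    out = np.empty((thetas.size, bank.n_items), dtype=int)
    items = [bank.item(i) for i in bank.item_ids]
    for r, th in enumerate(thetas):
        u = rng.random(bank.n_items)
        for c, it in enumerate(items):
            star = 1.0 / (
                1.0 + np.exp(-it.discrimination * (th - np.asarray(it.thresholds)))
            )
            out[r, c] = int(np.sum(u[c] < star))
    return out
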