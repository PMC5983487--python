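import numpy as np
import pytest

from crfalign.factors import init_bank


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def zero_bank(order: int):
    """Bank whose every parameter is 0, so every score is exp(0) = 1."""
    bank = init_bank(order, seed=0)
    bank.unflatten(np.zeros(bank.n_params))
    return bank


@pytest.fixture(params=[1, 2], ids=["order1", "order2"])
def order(request):
    return request.param
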