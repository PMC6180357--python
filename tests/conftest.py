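import numpy as np
import pytest

from sfhlogit.datasets import draw_beta, gen_synthetic
from sfhlogit.encoding import ENCODING_PRESETS
from sfhlogit.fv import PARAM_PRESETS, keygen
from sfhlogit.sfh import Dataset


@pytest.fixture(scope="session")
def two_record_data() -> Dataset:
    """The worked example: records (1,1,+1) and (1,0,-1)."""
    return Dataset(np.array([[1.0, 1.0], [1.0, 0.0]]), np.array([1.0, -1.0]))


@pytest.fixture(scope="session")
def small_binary_data() -> Dataset:
    beta = draw_beta(5, np.random.default_rng(42))
    return gen_synthetic(30, 5, "binary", beta, seed=123)


@pytest.fixture(scope="session")
def mini_params():
    return PARAM_PRESETS["mini"]


@pytest.fixture(scope="session")
def mini_keys(mini_params):
    return keygen(mini_params, seed=1)


@pytest.fixture(scope="session")
def toy_params():
    return PARAM_PRESETS["toy"]


@pytest.fixture(scope="session")
def toy_cfg():
    return ENCODING_PRESETS["toy"]


@pytest.fixture(scope="session")
def toy_keys(toy_params):
    return keygen(toy_params, seed=7)


@pytest.fixture(scope="session")
def toy_encrypted_run(toy_params, toy_cfg, toy_keys):
    """One full encrypted training run on a tiny binary dataset, shared
    across the tests that inspect it from different angles."""
    from sfhlogit.encrypted import (
        decrypt_model,
        encrypt_dataset,
        encrypted_sfh_iteration,
    )

    beta = draw_beta(3, np.random.default_rng(5))
    data = gen_synthetic(10, 3, "binary", beta, seed=20)
    enc = encrypt_dataset(data, toy_cfg, toy_params, toy_keys.pk, seed=8)
    beta_enc, report = encrypted_sfh_iteration(
        enc, toy_cfg, toy_params, toy_keys.rlk, iters=1
    )
    model = decrypt_model(toy_keys.sk, beta_enc, toy_cfg, toy_params)
    return data, enc, beta_enc, report, model
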