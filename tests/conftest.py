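from __future__ import annotations

import numpy as np
import pytest

import audcea


@pytest.fixture(scope="session")
def default_params_config():
    return audcea.load_default_parameters()


@pytest.fixture()
def params(default_params_config):
    return default_params_config[0].copy()


@pytest.fixture()
def config(default_params_config):
    import dataclasses

    return dataclasses.replace(default_params_config[1])


@pytest.fixture()
def thresholds():
    return audcea.DrlThresholdTable.default()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
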