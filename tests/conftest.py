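from __future__ import annotations

import numpy as np
import pytest

from formayield.metnet import cbb_variant, rglyp_variant
from formayield.synth import CoreModelSpec, build_core_model


@pytest.fixture(scope="session")
def core_model():
    """The bundled reduced formatotrophic core network (default spec)."""
    return build_core_model(CoreModelSpec())


@pytest.fixture()
def rglyp_spec():
    return rglyp_variant()


@pytest.fixture()
def cbb_spec():
    return cbb_variant()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
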