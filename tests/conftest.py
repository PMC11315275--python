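import numpy as np
import pytest

from aupiometry import ProcedureConfig, Variant, default_table


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(params=[Variant.AUPIOMETER, Variant.ELIOS], ids=["aupiometer", "elios"])
def config(request):
    return ProcedureConfig(variant=request.param)
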