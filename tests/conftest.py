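import pytest

from melapharm import metrics
from melapharm import synthetic as syn


@pytest.fixture(scope="session")
def reference_table():
    """Packaged literature pharmacology table with censoring parsed."""
    return metrics.load_reference_table()


@pytest.fixture(scope="session")
def templates():
    """Annotated template library (known filter pass/fail)."""
    return syn.load_templates()


@pytest.fixture()
def noiseless_cfg():
    return syn.SimConfig(seed=11, noise_sd=0.0, replicates=1)
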