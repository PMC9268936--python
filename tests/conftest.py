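import numpy as np
import pytest

import wristbia as wb
from wristbia.synthetic import NO_NOISE, PhantomSpec


@pytest.fixture(scope="session")
def tables():
    return wb.default_tables()


@pytest.fixture(scope="session")
def spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def table4_experiment():
    """The ten-step Group-B withdrawal protocol (cumulative volumes)."""
    return wb.PumpExperiment(
        d0=3.98e-3, artery_length=0.175,
        steps=tuple(80.98e-9 * k for k in range(1, 11)),
    )


@pytest.fixture(scope="session")
def group_b_noise_free(spec):
    return wb.generate_group_experiment(spec, group="B", noise=NO_NOISE,
                                        mode="nyboer")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
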