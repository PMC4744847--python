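import numpy as np
import pytest

from anflif import PulseSpec, make_monophasic, table1

# analytic 0.5-probability level of a 40 us cathodic pulse for the reference
# fiber: mu / (1 - exp(-40/tau))
THRESHOLD_40US = 104.5 / (1.0 - np.exp(-40.0 / 248.4))


@pytest.fixture(scope="session")
def params():
    return table1()


@pytest.fixture()
def threshold_pulse():
    """40 us monophasic pulse at the reference fiber's threshold level."""
    return make_monophasic(THRESHOLD_40US, 40.0)


@pytest.fixture()
def biphasic_spec():
    """Symmetric 40 us/phase, zero-IPG cathodic-anodic pulse template."""
    return PulseSpec(pulse_class="biphasic", cathodic_amplitude=1.0, cathodic_duration=40.0)
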