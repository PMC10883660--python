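import numpy as np
import pytest

from olivemap.protocol import generate_protocol
from olivemap.synthetic import PopulationSpec, generate_population

DIRS8 = np.arange(0.0, 360.0, 45.0)


@pytest.fixture(scope="session")
def binocular_protocol():
    return generate_protocol(seed=0)


@pytest.fixture(scope="session")
def monocular_protocol():
    return generate_protocol(monocular_blocks=True, include_conv_div=True,
                             seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact tuned population on the binocular protocol."""
    spec = PopulationSpec(seed=42)
    for name, n in (("forward", 12), ("backward", 8), ("cw_rotation", 4),
                    ("ccw_rotation", 4), ("nonselective", 6)):
        spec.classes[name].n = n
    return generate_population(spec)


@pytest.fixture(scope="session")
def monocular_dataset():
    """A small population recorded under the three-block protocol."""
    spec = PopulationSpec(seed=7)
    for name, n in (("forward", 8), ("backward", 6), ("cw_rotation", 4),
                    ("ccw_rotation", 4), ("nonselective", 4)):
        spec.classes[name].n = n
    protocol = generate_protocol(monocular_blocks=True, include_conv_div=True,
                                 seed=7)
    return generate_population(spec, protocol=protocol)
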