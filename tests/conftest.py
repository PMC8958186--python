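import pytest

import prismaflow as pf

#: The four arm layouts (full / no previous / no other / main only) with the
#: node and edge counts implied by the fixed 22-node inventory.
ARM_CASES = [
    (pf.ArmConfig(True, True), 22, 15),
    (pf.ArmConfig(False, True), 19, 13),
    (pf.ArmConfig(True, False), 16, 10),
    (pf.ArmConfig(False, False), 13, 8),
]

ALL_CONFIGS = [
    pf.ArmConfig(prev, other, interactive)
    for prev in (True, False)
    for other in (True, False)
    for interactive in (True, False)
]


@pytest.fixture(scope="session")
def blank_fd() -> pf.FlowData:
    return pf.blank_template()


@pytest.fixture(scope="session")
def example_fd() -> pf.FlowData:
    return pf.generate_example_data(1)


@pytest.fixture
def full_config() -> pf.ArmConfig:
    return pf.ArmConfig()
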