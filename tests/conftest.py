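import hypothesis
import pytest

from refluxdx.association import AssociationConfig
from refluxdx.gerd import GerdConfig
from refluxdx.hrm import Cc30Config

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=100, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def cc30_cfg() -> Cc30Config:
    return Cc30Config()


@pytest.fixture(scope="session")
def gerd_cfg() -> GerdConfig:
    return GerdConfig()


@pytest.fixture(scope="session")
def assoc_cfg() -> AssociationConfig:
    return AssociationConfig()
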