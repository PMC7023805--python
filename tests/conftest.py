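import pytest
from hypothesis import HealthCheck, settings

from domevol import PhyloTree

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def balanced_nested(labels):
    if len(labels) == 1:
        return labels[0]
    mid = len(labels) // 2
    return (balanced_nested(labels[:mid]), balanced_nested(labels[mid:]))


@pytest.fixture
def quartet_tree():
    return PhyloTree.from_nested((("L1", "L2"), ("L3", "L4")))


@pytest.fixture(scope="session")
def study_tree():
    """The validation topology: a 20-leaf ingroup with a 2-leaf outgroup."""
    ingroup = [f"s{i:02d}" for i in range(20)]
    return PhyloTree.from_nested(
        (("og1", "og2"), balanced_nested(ingroup)), outgroup=["og1", "og2"]
    )
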