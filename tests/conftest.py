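import pytest

from numtopo import timeline


@pytest.fixture(scope="session")
def haptic_run():
    return timeline.build_haptic_run(1.5)


@pytest.fixture(scope="session")
def visual_run():
    return timeline.build_visual_run(1.95)
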