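import pytest

from pitosim.pk_core import CycleParams, MaternalProfile


@pytest.fixture
def worked_profile() -> MaternalProfile:
    """The reference worked example: 160-lb woman, 3-min half-life, 4.7 L blood."""
    return MaternalProfile.from_weight(
        weight_lb=160, half_life_min=3, rounded_volume=True
    )


@pytest.fixture
def light_profile() -> MaternalProfile:
    """128-lb woman (3.8 L blood volume in rounded mode)."""
    return MaternalProfile.from_weight(
        weight_lb=128, half_life_min=3, rounded_volume=True
    )


@pytest.fixture
def one_minute_cycle() -> CycleParams:
    return CycleParams(1.0)
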