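import numpy as np
import pytest

from twomass import FoldState, ForcePair, ModelParams


@pytest.fixture
def params() -> ModelParams:
    """Standard model constants (Q = 3)."""
    return ModelParams()


@pytest.fixture
def undamped() -> ModelParams:
    return ModelParams(zeta1=0.0, zeta2=0.0)


@pytest.fixture
def rest_state() -> FoldState:
    return FoldState()


@pytest.fixture
def zero_forces():
    """External-force callback returning zero (free vibration)."""
    return lambda state: ForcePair()


def open_state(dy: float = 0.5e-3) -> FoldState:
    """Both masses displaced laterally by ``dy`` — an open glottis."""
    return FoldState(r1=(0.0, dy), r2=(0.0, dy))
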