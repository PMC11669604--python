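import numpy as np
import pytest

from gliosim.fields import Grid3D, TissueState, ball_indicator, extract_boundary


@pytest.fixture
def grid16():
    return Grid3D((16, 16, 16))


@pytest.fixture
def ball_domain(grid16):
    ind = ball_indicator(grid16, (8, 8, 8), 5.5)
    return extract_boundary(ind, grid16)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_state(grid16, ball_domain):
    st = TissueState.zeros(grid16)
    st.c = np.where(ball_domain.indicator, 0.3, 0.0)
    st.l = np.full(grid16.shape, 0.2)
    st.F = np.full(grid16.shape, 0.2)
    return st
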