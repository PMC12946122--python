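import numpy as np
import pytest

from chronodyn.pomdp import Belief, DiscretePOMDP


@pytest.fixture
def two_state_model() -> DiscretePOMDP:
    """Small hand-checkable model: 2 states, 1 action, 2 observation symbols."""
    return DiscretePOMDP(
        trans=np.array([[[0.9, 0.1]], [[0.2, 0.8]]]),
        obs_lik=np.array([[0.7, 0.3], [0.3, 0.7]]),
        cost=np.array([[1.0], [3.0]]),
        gamma=0.9,
    )


@pytest.fixture
def uniform2() -> Belief:
    return Belief(np.array([0.5, 0.5]))
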