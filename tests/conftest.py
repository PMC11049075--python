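import numpy as np
import pytest

from protentia.categorical import Categorical, FiniteSet, StochasticMap
from protentia.engine import GenerativeModel
from protentia.fixtures import make_tmaze, random_model


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def two_state_model():
    """Tiny 2-state/2-obs/2-action model with a noisy likelihood."""
    S = FiniteSet(["s1", "s2"])
    O = FiniteSet(["o1", "o2"])
    U = FiniteSet(["u1", "u2"])
    A = StochasticMap(S, O, [[0.9, 0.2], [0.1, 0.8]])
    B = {"u1": StochasticMap.identity(S),
         "u2": StochasticMap(S, S, [[0.0, 1.0], [1.0, 0.0]])}
    return GenerativeModel(states=S, observations=O, actions=U, A=A, B=B,
                           C=Categorical(O, [0.7, 0.3]),
                           D=Categorical.uniform(S),
                           E=Categorical.uniform(U), gamma=1.0)


@pytest.fixture
def identity_model():
    """Noiseless likelihood, identity transitions."""
    S = FiniteSet(["s1", "s2"])
    O = FiniteSet(["o1", "o2"])
    U = FiniteSet(["u1"])
    return GenerativeModel(states=S, observations=O, actions=U,
                           A=StochasticMap(S, O, [[1, 0], [0, 1]]),
                           B={"u1": StochasticMap.identity(S)},
                           C=Categorical.uniform(O),
                           D=Categorical.uniform(S),
                           E=Categorical.uniform(U), gamma=1.0)


@pytest.fixture(scope="session")
def tmaze():
    return make_tmaze()


@pytest.fixture
def small_random_model():
    return random_model(3, 3, 2, seed=11)
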