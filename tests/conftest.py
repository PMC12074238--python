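import numpy as np
import pytest

from pamsim import (
    AugmentedVariant,
    Condition,
    GameConfig,
    preset_profiles,
)


@pytest.fixture
def ideal_agent():
    return preset_profiles()["ideal"]


@pytest.fixture
def presets():
    return preset_profiles()


def make_config(condition=Condition.REFERENCE, help_rate=None, **kwargs):
    """GameConfig with the studied design rates (70% success, 30% help)."""
    if help_rate is None:
        help_rate = 0.0 if condition is Condition.REFERENCE else 0.30
    return GameConfig(condition=condition, help_rate=help_rate, **kwargs)


@pytest.fixture
def mf_config():
    return make_config(Condition.MITIGATED_FAILURE, seed=1)


@pytest.fixture
def io_config():
    return make_config(Condition.INPUT_OVERRIDE, seed=1)


@pytest.fixture
def as_redesigned_config():
    return make_config(
        Condition.AUGMENTED_SUCCESS,
        augmented_variant=AugmentedVariant.REDESIGNED,
        seed=1,
    )


@pytest.fixture
def reference_config():
    return make_config(Condition.REFERENCE, seed=1)


def random_valid_config(rng: np.random.Generator) -> GameConfig:
    """A random configuration satisfying every config invariant."""
    condition = rng.choice(list(Condition))
    variant = rng.choice(list(AugmentedVariant))
    n_trials = int(rng.integers(2, 41))
    # keep at least one scheduled failure after rounding
    while True:
        success_rate = float(rng.uniform(0.05, 0.95))
        n_succ = int(np.floor(success_rate * n_trials + 0.5))
        if 1 <= n_succ <= n_trials - 1:
            break
    cap = success_rate if condition is Condition.AUGMENTED_SUCCESS else 1.0 - success_rate
    if condition is Condition.REFERENCE:
        help_rate = 0.0
    else:
        # cap so rounding cannot exceed the trigger-side trial count
        n_side = n_succ if condition is Condition.AUGMENTED_SUCCESS else n_trials - n_succ
        help_rate = min(float(rng.uniform(0.0, cap)), max(n_side - 0.5, 0.0) / n_trials)
    n_lanes = int(rng.integers(2, 6))
    return GameConfig(
        condition=condition,
        augmented_variant=variant,
        n_trials=n_trials,
        success_rate=success_rate,
        help_rate=help_rate,
        n_lanes=n_lanes,
        escape_threshold=int(rng.integers(1, 5)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
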