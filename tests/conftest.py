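import numpy as np
import pytest

import healthlong as hl


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic survey-like cohort, ages 50-90."""
    return hl.generate_synthetic()


@pytest.fixture(scope="session")
def two_class_chain():
    """Bounded 2-class age chain: p = [0.5, 0], single death state."""
    schedule = hl.MortalitySchedule((0, 1), [0.5, 0.0])
    return hl.chain_from_schedule(schedule)


def random_bounded_chain(rng, max_omega=3, max_alpha=2):
    """A random bounded (no open-ended class) age chain for oracle checks."""
    omega = int(rng.integers(1, max_omega + 1))
    alpha = int(rng.integers(1, max_alpha + 1))
    p = rng.uniform(0.05, 0.95, size=omega)
    p[-1] = 0.0  # bounded: the last class is certainly fatal
    schedule = hl.MortalitySchedule(tuple(range(omega)), p)
    if alpha == 1:
        split = None
    else:
        f = rng.uniform(0.05, 0.95, size=(alpha, omega))
        split = f / f.sum(axis=0, keepdims=True)
    P = hl.chain_from_schedule(schedule, cause_split=split)
    return schedule, P
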