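import numpy as np
import pytest

from regulonscan.pwm import PWM


def make_sharp_pwm(width: int = 12, seed: int = 0,
                   dominant_count: float = 97.0) -> PWM:
    """A high-information PWM with one dominant base per column."""
    rng = np.random.default_rng(seed)
    counts = np.full((width, 4), 1.0)
    for j, d in enumerate(rng.integers(0, 4, width)):
        counts[j, d] = dominant_count
    return PWM(f"sharp_w{width}_s{seed}", counts)


def random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def sharp_pwm() -> PWM:
    return make_sharp_pwm()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
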