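import numpy as np
import pytest

from corrlink import examples
from corrlink.estimators import JointCountTable


@pytest.fixture
def chr1_table() -> JointCountTable:
    """Rice chromosome-1 marker pair (near-Mendelian segregation)."""
    return examples.rice_pair_chr1()


@pytest.fixture
def chr4_table() -> JointCountTable:
    """Rice chromosome-4 marker pair (strong segregation distortion)."""
    return examples.rice_pair_chr4()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def random_f2_table(rng: np.random.Generator, n: int = 200) -> JointCountTable:
    """A random F2 joint count table at a random interior theta."""
    theta = rng.uniform(0.02, 0.48)
    p = np.array(
        [
            [0.25 * (1 - theta) ** 2, 0.5 * theta * (1 - theta), 0.25 * theta**2],
            [0.5 * theta * (1 - theta), 0.5 * (theta**2 + (1 - theta) ** 2),
             0.5 * theta * (1 - theta)],
            [0.25 * theta**2, 0.5 * theta * (1 - theta), 0.25 * (1 - theta) ** 2],
        ]
    )
    return JointCountTable(rng.multinomial(n, p.ravel()).reshape(3, 3))
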