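import numpy as np
import pandas as pd
import pytest

from var2func.motif import PWM


@pytest.fixture
def gata_pwm() -> PWM:
    """Strong 6-bp GATA-family-style motif (WGATAA core)."""
    counts = np.array([
        [60, 10, 10, 20],
        [2, 2, 94, 2],
        [94, 2, 2, 2],
        [2, 2, 2, 94],
        [94, 2, 2, 2],
        [70, 10, 10, 10],
    ])
    return PWM.from_counts("GATA_like", counts)


@pytest.fixture
def toy_pwm() -> PWM:
    """Small asymmetric 4-bp motif for brute-force comparisons."""
    probs = np.array([
        [0.7, 0.1, 0.1, 0.1],
        [0.1, 0.6, 0.2, 0.1],
        [0.05, 0.05, 0.8, 0.1],
        [0.25, 0.25, 0.25, 0.25],
    ])
    return PWM("toy", probs)


@pytest.fixture
def small_lipid_matrix():
    """4+4 samples x 6 lipids with a planted two-fold depletion in class B."""
    rng = np.random.default_rng(7)
    lipids = ["A_0", "A_1", "A_2", "B_0", "B_1", "B_2"]
    base = np.array([5.0, 8.0, 2.0, 10.0, 4.0, 6.0])
    vals = rng.lognormal(np.log(base), 0.05, size=(8, 6))
    vals[4:, 3:] /= 2.0
    matrix = pd.DataFrame(vals, index=[f"s{i}" for i in range(8)], columns=lipids)
    groups = pd.Series(["control"] * 4 + ["treated"] * 4, index=matrix.index)
    class_map = pd.Series([l.split("_")[0] for l in lipids], index=lipids)
    return matrix, groups, class_map
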