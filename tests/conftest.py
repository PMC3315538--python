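import numpy as np
import pytest

from icscore import VariableSpec, encode_dataset
from icscore.synthetic import default_staircase_spec, generate
from icscore.variables import ThresholdGrid, build_threshold_grid

STAIRCASE_SPECS = [
    VariableSpec("stair_a", "continuous"),
    VariableSpec("stair_b", "continuous"),
    VariableSpec("flag", "binary"),
    VariableSpec("noise_u", "continuous"),
    VariableSpec("noise_n", "continuous"),
    VariableSpec("noise_b", "binary"),
]


def encode_staircase(n, seed, max_cuts=20):
    """Draw a staircase cohort and encode it with quantile grids."""
    spec = default_staircase_spec()
    records, outcomes, risks = generate(spec, n, seed=seed)
    grids = {
        s.name: build_threshold_grid(
            [r[s.name] for r in records], variable=s.name, max_cuts=max_cuts
        )
        for s in STAIRCASE_SPECS
        if s.kind == "continuous"
    }
    Xm = encode_dataset(records, STAIRCASE_SPECS, grids, outcomes)
    return Xm, records, outcomes, risks, grids


@pytest.fixture(scope="session")
def staircase_small():
    """n=400 staircase cohort (seed 7) for optimizer-level tests."""
    return encode_staircase(400, seed=7)


@pytest.fixture(scope="session")
def simple_1d():
    """1-D separable-by-threshold data: y = sign(x), cut grid includes 0."""
    rng = np.random.default_rng(0)
    x = rng.uniform(-1, 1, 80)
    x = x[np.abs(x) > 0.05]
    y = np.where(x < 0, -1, 1)
    grid = ThresholdGrid("x", (-0.5, 0.0, 0.5))
    Xm = encode_dataset(
        [{"x": v} for v in x], [VariableSpec("x", "continuous")], [grid], y
    )
    return Xm
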