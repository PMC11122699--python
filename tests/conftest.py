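import numpy as np
import pandas as pd
import pytest

from flankerssp.model import SSPParameters
from flankerssp.simulate import SimulationSettings, simulate_trials


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_trials(params: SSPParameters, n_per_condition: int, seed: int) -> pd.DataFrame:
    """Screened trial table simulated from known parameters."""
    rng = np.random.default_rng(seed)
    frames = []
    for condition in ("congruent", "incongruent"):
        rt, acc, trunc = simulate_trials(
            params, condition, n_per_condition, SimulationSettings(), rng=rng
        )
        frames.append(
            pd.DataFrame({"condition": condition, "rt": rt, "accuracy": acc.astype(int)})
        )
    df = pd.concat(frames, ignore_index=True)
    return df[(df["rt"] >= 150) & (df["rt"] <= 2000)].reset_index(drop=True)


@pytest.fixture(scope="session")
def reference_params() -> SSPParameters:
    """Mid-range generating parameters used across simulation tests."""
    return SSPParameters(a=0.08, ter=0.31, p=0.48, sd_a=1.5, rd=1.5 / 43.6)


@pytest.fixture(scope="session")
def reference_trials(reference_params) -> pd.DataFrame:
    return make_trials(reference_params, 192, seed=90210)
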