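import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def make_spot_table(intensities, fov=0, round_=0, channel=0, cls=""):
    """Minimal schema-complete SpotTable for gating tests."""
    n = len(intensities)
    return pd.DataFrame(
        {
            "spot_id": np.arange(n),
            "fov": fov,
            "round": round_,
            "channel": channel,
            "gene": "",
            "z": 0.0,
            "y": 0.0,
            "x": 0.0,
            "intensity": np.asarray(intensities, dtype=float),
            "class": cls,
            "cell_id": 0,
        }
    )


@pytest.fixture
def tiny_sim_config():
    """Small noiseless section: fast to render, exact by construction."""
    from scmst.synth import noiseless_config

    return noiseless_config(seed=11)


@pytest.fixture
def tiny_counts():
    from scmst.synth import counts_config, simulate_counts

    cm, subpop, cents = simulate_counts(counts_config(seed=5, n_cells=300))
    return cm, subpop
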