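import numpy as np
import pandas as pd
import pytest

from methstrat.synthetic_data import SimConfig, generate_cohort

# small probe space keeps the suite fast; the cluster structure is the
# same as the full-size default
SMALL = dict(n_probes=3000, n_signature_probes=300)


@pytest.fixture(scope="session")
def discovery_cohort():
    return generate_cohort(SimConfig(seed=11, **SMALL))


@pytest.fixture(scope="session")
def validation_cohort():
    return generate_cohort(
        SimConfig(
            seed=12,
            cluster_sizes=(12, 11, 17),
            event_rates=(1 / 12, 4 / 11, 13 / 17),
            control_n=0,
            cohort_name="validation",
            sample_prefix="V",
            **SMALL,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_beta():
    """4 probes x 4 samples with easily hand-checked values."""
    return pd.DataFrame(
        {
            "s1": [0.1, 0.5, 0.9, 0.5],
            "s2": [0.2, 0.5, 0.8, 0.5],
            "s3": [0.8, 0.5, 0.2, 0.5],
            "s4": [0.9, 0.5, 0.1, 0.5],
        },
        index=["p1", "p2", "p3", "p4"],
    )
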