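import numpy as np
import pandas as pd
import pytest

from mprameta import synthetic
from mprameta.featurize import PWM


@pytest.fixture(scope="session")
def sharp_pwm():
    """An 8-bp near-consensus PWM (0.97 on one base per position)."""
    rng = np.random.default_rng(7)
    mat = np.full((8, 4), 0.01)
    for i, c in enumerate(rng.integers(0, 4, 8)):
        mat[i, c] = 0.97
    return PWM("sharp", mat / mat.sum(axis=1, keepdims=True))


@pytest.fixture(scope="session")
def small_counts():
    """500 regions x 30 barcodes with ground truth, fixed seed."""
    cfg = synthetic.SimConfig(n_regions=500, n_controls=100, seed=11)
    return synthetic.simulate_counts(cfg)


@pytest.fixture(scope="session")
def paired_data():
    """Paired datasets with shared + specific structure, n = 2000."""
    cfg = synthetic.PairedSimConfig(
        base=synthetic.SimConfig(n_regions=2000, seed=5),
        shared_effect_sd=1.0,
        specific_effect_sd=1.0,
        noise_sd=0.5,
    )
    return synthetic.simulate_paired_datasets(cfg)
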