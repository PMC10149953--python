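import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_table(x, y, frame=None, photons=None, sigma=None, channel="paGFP"):
    """Build a minimal localization table from coordinate arrays."""
    x = np.asarray(x, dtype=float)
    n = x.size
    return pd.DataFrame(
        {
            "x_nm": x,
            "y_nm": np.asarray(y, dtype=float),
            "frame": np.asarray(frame if frame is not None else np.zeros(n), dtype=np.int64),
            "photons": np.asarray(
                photons if photons is not None else np.full(n, 1000.0), dtype=float
            ),
            "sigma_nm": np.asarray(sigma if sigma is not None else np.full(n, 10.0), dtype=float),
            "channel": channel,
        }
    )


@pytest.fixture
def small_table():
    return make_table(
        x=[100.0, 250.5, 900.25],
        y=[50.0, 300.0, 777.5],
        frame=[0, 5, 9],
        photons=[800.0, 1200.0, 950.0],
        sigma=[8.0, 12.5, 20.0],
    )
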