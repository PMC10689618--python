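import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_plate(greens, reds=None, plate_id="P001", role="data"):
    """Minimal single-plate well table from intensity lists."""
    n = len(greens)
    reds = reds if reds is not None else [100.0] * n
    rows = "ABCDEFGHIJKLMNOP"
    return pd.DataFrame(
        {
            "plate_id": plate_id,
            "well_row": [rows[i % 16] for i in range(n)],
            "well_col": [1 + i // 16 for i in range(n)],
            "role": role,
            "compound_id": [f"C{i:04d}" for i in range(n)],
            "concentration_um": 10.0,
            "red_intensity": np.asarray(reds, dtype=float),
            "green_intensity": np.asarray(greens, dtype=float),
        }
    )


@pytest.fixture
def tiny_screen_sim():
    """A small noiseless screen with planted classes, shared across tests."""
    from phagoscreen.synthetic_data import ScreenSimConfig, gen_screen

    cfg = ScreenSimConfig(
        n_compounds=200,
        frac_increase=0.1,
        frac_decrease=0.1,
        frac_toxic=0.05,
        cv_noise=0.0,
        seed=42,
    )
    return gen_screen(cfg)
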