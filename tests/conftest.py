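import numpy as np
import pandas as pd
import pytest

from proximif import SimConfig, generate_tissue


@pytest.fixture(scope="session")
def small_tissue() -> pd.DataFrame:
    """A modest mixed tissue reused by read-only tests."""
    cfg = SimConfig(window_um=(500.0, 500.0), lambda_stroma=4e-4,
                    nest_parent_intensity=3e-5, nest_mean_cells=60,
                    nest_sigma_um=30, lambda_cd8=4e-4, seed=7)
    return generate_tissue(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
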