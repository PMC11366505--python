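import numpy as np
import pandas as pd
import pytest

from pigpex.excretion_models import load_published_models
from pigpex.projection import default_schedule
from pigpex.synthetic_data import default_generator_config, generate


@pytest.fixture(scope="session")
def published():
    return load_published_models()


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def clean_dataset():
    """Default synthetic balance data, no injected outliers, seed 0."""
    return generate(default_generator_config(seed=0, outlier_rate=0.0))


def iid_covariate_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Generic covariate draw spanning the grower-finisher range."""
    return pd.DataFrame(
        {
            "bw_kg": rng.uniform(10, 100, n),
            "fi_kg_d": rng.uniform(0.5, 3.0, n),
            "diet_p_pct": rng.uniform(0.3, 0.7, n),
        }
    )
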