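import numpy as np
import pandas as pd
import pytest

from gicafc.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default two-group cohort (k=6, 10+10 subjects, SNR ~ 2)."""
    return generate_cohort(CohortConfig(seed=3))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Noiseless, undegraded cohort: runs equal mixing @ maps exactly."""
    cfg = CohortConfig(seed=1, noise_sd=0.0,
                       intra_fc_scale={"control": 1.0, "patient": 1.0})
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def covariates_39(rng):
    """Covariate table shaped like the study: 20 controls, 19 patients."""
    n = 39
    return pd.DataFrame({
        "group": ["control"] * 20 + ["patient"] * 19,
        "age": rng.normal(53, 7, n),
        "gender": rng.choice(["M", "F"], n),
        "education": rng.normal(11, 2.5, n),
    })
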