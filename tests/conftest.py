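import numpy as np
import pandas as pd
import pytest

from dmardseq import SimConfig, generate_registry
from dmardseq.grids import build_state_grids, carry_forward_covariates


def make_visits(rows):
    """Visits table from (patient_id, month, tcz, tnfi, other, csdmard) tuples."""
    df = pd.DataFrame(rows, columns=["patient_id", "months_since_enrollment", "tcz", "tnfi", "other_bdmard_or_jak", "csdmard"])
    df["glucocorticoid"] = 0
    df["cdai"] = np.nan
    df["haq"] = np.nan
    return df


@pytest.fixture(scope="session")
def small_registry():
    """Shared synthetic cohort (n=400) for unit tests; default conditions."""
    cfg = SimConfig(n_patients=400, seed=20210114)
    patients, visits, latent = generate_registry(cfg, return_latent=True)
    return cfg, patients, visits, latent


@pytest.fixture(scope="session")
def small_grids(small_registry):
    _, _, visits, _ = small_registry
    return build_state_grids(carry_forward_covariates(visits))
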