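import numpy as np
import pytest

from sarcimmune.survival import SurvivalRecord
from sarcimmune.synthetic import CohortConfig, generate_cohort

ZERO_MUTATIONS = {s: {"snv": (0, 0), "indel": (0, 0), "fusion": (0, 0)}
                  for s in ["SS", "LMS", "DDLPS", "UPS", "ES", "OS", "CS"]}
NULL_HAZARD = {"t_cell_fraction": 0.0, "neoantigen_quality": 0.0, "interaction": 0.0}


@pytest.fixture(scope="session")
def default_cohort():
    """One default 31-patient cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def records_from_clinical(clinical):
    return [SurvivalRecord(r.patient_id, float(r.pfs_days), int(r.event))
            for _, r in clinical.iterrows()]


def random_survival_records(rng, n, censor_frac=0.3, prefix="s"):
    times = rng.exponential(scale=100.0, size=n)
    events = (rng.random(n) > censor_frac).astype(int)
    return [SurvivalRecord(f"{prefix}{i}", float(max(t, 1e-6)), int(e))
            for i, (t, e) in enumerate(zip(times, events))]
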