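from datetime import date, timedelta

import numpy as np
import pytest

from irskit.io import default_model_spec
from irskit.lines import MedicationRecord
from irskit.simulate import SimConfig, gen_biomarkers, gen_outcomes


@pytest.fixture(scope="session")
def spec():
    return default_model_spec()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def day(n: int) -> date:
    """Calendar date n days after an arbitrary origin."""
    return date(2020, 1, 1) + timedelta(days=n)


def dose(days, agent="pembrolizumab", cls="PD-1", pid="p1"):
    """Single-day medication records at the given day offsets."""
    return [MedicationRecord(pid, agent, cls, day(d), day(d)) for d in days]


@pytest.fixture(scope="session")
def default_cohort(spec):
    """One moderately sized biomarker + outcome draw shared across tests."""
    cfg = SimConfig(n_patients=2000, seed=11)
    rng = np.random.default_rng(cfg.seed)
    bio = gen_biomarkers(cfg, rng)
    out = gen_outcomes(bio, cfg, rng, spec)
    return cfg, bio, out
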