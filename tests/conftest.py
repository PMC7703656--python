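import numpy as np
import pytest

from catvk.dilution import dilution_series
from catvk.kinetics import GROUP_2VOFS
from catvk.synthcats import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def pla_cohort():
    """One noisy single-fluid cohort at the study design (shared, read-only)."""
    cfg = GeneratorConfig(fluids=("PLA",), true_params={"PLA": GROUP_2VOFS},
                          seed=23)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def pla_subjects(pla_cohort):
    records, _ = pla_cohort
    return [(dilution_series(r), r.schedule, r.covariates()) for r in records]


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Degenerate generator: no IIV, no measurement noise, no analyte scatter."""
    cfg = GeneratorConfig(fluids=("PLA",), true_params={"PLA": GROUP_2VOFS},
                          seed=3, cv_hb=0.0, cv_rbc=0.0, iiv_cv={},
                          hb_per_rbc_cv=0.0, urine_cv=0.0)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
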