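import numpy as np
import pytest

from nigm.synthetic import SimulationConfig, SubjectParams, simulate_cohort


@pytest.fixture(scope="session")
def tiny_bundle():
    """Two fully rendered subjects: enough for preprocessing/QC tests."""
    cfg = SimulationConfig(n_subjects=2, rng_seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def subject_params():
    """One deterministic set of subject parameters for generator-level tests."""
    return SubjectParams(
        subject_id="T01", age=60.0, sex=1, bmi=28.0, hba1c_mmol_mol=55.0,
        phototype=3, sc_thickness_um=160.0, baseline_glucose_mmol=7.0,
        tau_min=10.0, baseline_factor=1.0,
        confounder_amps=np.array([30.0, 20.0, 40.0, 28.0, 25.0, 35.0, 50.0, 25.0]),
        device_id="D00",
    )
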