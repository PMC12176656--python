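import numpy as np
import pytest

from admarkers import SimConfig, add_derived_columns, calibrate_baseline_hazard, generate_cohort


@pytest.fixture(scope="session")
def calibrated_config() -> SimConfig:
    """Default simulation config with the baseline hazard calibrated once."""
    cfg = SimConfig()
    calibrate_baseline_hazard(cfg)
    return cfg


@pytest.fixture(scope="session")
def cohort(calibrated_config):
    """A study-sized synthetic cohort (n=2,148, fixed seed)."""
    return generate_cohort(calibrated_config, n=2148, seed=1)


@pytest.fixture(scope="session")
def analysis_frame(cohort):
    """Preprocessed analytical sample: derived columns, dropouts excluded."""
    frame = add_derived_columns(cohort)
    frame = frame[frame["dropout"] == 0].copy()
    frame["incident_dementia"] = (
        frame["event"].isin(["ad_dementia", "other_dementia"]).astype(int)
    )
    return frame


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
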