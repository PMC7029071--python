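import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from echodens.io import DetectorProfile, SpeciesProfile
from echodens.simulate import simulate_rn, simulate_survey


@pytest.fixture(scope="session")
def pip_profile() -> SpeciesProfile:
    """A common-pipistrelle-like acoustic profile."""
    return SpeciesProfile(
        name="P. pipistrellus", main_frequency=44.0, spl_min=90.0, spl_max=120.0,
        signal_angles=(25.0, 42.0, 70.0), flight_speed_v=5.4, home_range_area=1.7,
    )


@pytest.fixture(scope="session")
def detector() -> DetectorProfile:
    return DetectorProfile()


@pytest.fixture(scope="session")
def rn_truth():
    """Intercept-only RN dataset with known lambda=2, r=0.3."""
    return simulate_rn(
        200, 15, {"(Intercept)": float(np.log(2.0))},
        {"intercept": float(logit(0.3))}, seed=11,
    )


@pytest.fixture(scope="session")
def survey(pip_profile):
    """Small synthetic survey: 3 sites x 2 nights, one species at known density."""
    scenario = {
        "species": {
            pip_profile.name: {
                "profile": pip_profile, "true_density": 20.0,
                "r": 30.0, "alpha_deg": 42.0,
            }
        },
        "n_sites": 3,
        "nights": ["2016-06-20", "2016-06-21"],
        "theta_deg": 200.0,
    }
    return simulate_survey(scenario, seed=5)


@pytest.fixture(scope="session")
def survey_config(pip_profile):
    from echodens.io import Config

    return Config(
        species={pip_profile.name: pip_profile},
        detector=DetectorProfile(),
        periods=[{"id": "P1", "start": "2016-06-01", "end": "2016-06-30"}],
        settings={"spl_step_db": 10.0, "n_boot": 100,
                  "detection_candidates": "minimal", "rn_top_k": 0},
        literature_densities={pip_profile.name: 15.4},
    )
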