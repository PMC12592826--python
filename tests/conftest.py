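import warnings

import numpy as np
import pytest

import naaglm as na

RECOVERY_STAGE_RATES = {
    na.StageCode.WAKE: 4.0,
    na.StageCode.LIGHT: 10.0,
    na.StageCode.DEEP: 5.0,
    na.StageCode.REM: 8.0,
}


@pytest.fixture(scope="session")
def sim_config() -> na.SimConfig:
    return na.SimConfig()


@pytest.fixture(scope="session")
def recovery_model() -> na.TrueModel:
    """Ground truth used throughout: SDB x2, arousal x1.5, bump 2.0 @ 15 s."""
    return na.TrueModel.from_rates_per_hour(
        RECOVERY_STAGE_RATES,
        beta_sdb=np.log(2.0),
        beta_ar=np.log(1.5),
        history_curve=na.gaussian_bump(peak=2.0, peak_lag_s=15.0, width_s=5.0),
    )


@pytest.fixture(scope="session")
def night(sim_config, recovery_model):
    """One fully simulated 8-h night, shared across read-only tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return na.simulate_night(sim_config, recovery_model, seed=1)


@pytest.fixture(scope="session")
def fitted_night(night):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = na.PointProcessGLM().fit_night(
            night.train, night.hypnogram, night.events
        )
    return night, model


def all_light_hypnogram(hours: float = 2.0) -> na.Hypnogram:
    n = int(hours * 3600 / 30)
    return na.Hypnogram((na.StageCode.LIGHT,) * n, 30.0, 0.0)
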