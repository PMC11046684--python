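import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from stereoshape.geometry import ViewingGeometry
from stereoshape.observers import CohortConfig, ObserverParams
from stereoshape.predictors import ObjectSpec

ZERO_SDS = {
    "gain_h": 0.0, "gain_v": 0.0, "gain_u": 0.0, "sat_deg": 0.0,
    "coupling": 0.0, "slant_noise_sd": 0.0, "ratio_noise_sd": 0.0,
    "report_threshold": 0.0, "lapse": 0.0, "direction_reliability": 0.0,
}


@pytest.fixture
def geom():
    """Screen-experiment geometry: 29.3 cm distance, 6.2 cm IPD."""
    return ViewingGeometry(ipd_cm=6.2, distance_cm=29.3)


@pytest.fixture
def real_obj():
    """The printed 7.5-cm square held at a 35 cm viewing distance."""
    return ObjectSpec(half_width=3.75, viewing_distance=35.0)


@pytest.fixture
def screen_obj(geom):
    """The 16-degree on-screen square expressed in cm."""
    return ObjectSpec(
        half_width=geom.distance_cm * np.tan(np.radians(8.0)),
        viewing_distance=geom.distance_cm,
    )


def make_cohort(n=4, reps=1, seed=0, sds=None, **param_overrides):
    """Small deterministic cohort for unit tests."""
    means = ObserverParams(**param_overrides)
    return CohortConfig(
        n_participants=n, repetitions=reps, seed=seed, means=means,
        param_sds=dict(ZERO_SDS if sds is None else sds),
    )


def noiseless_cohort(n=2, reps=1, seed=0, **param_overrides):
    """All population SDs and trial noise zero: pure generative model."""
    overrides = {"slant_noise_sd": 0.0, "ratio_noise_sd": 0.0, "lapse": 0.0}
    overrides.update(param_overrides)
    return make_cohort(n=n, reps=reps, seed=seed, **overrides)
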