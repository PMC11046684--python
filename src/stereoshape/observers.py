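"""Synthetic observer cohorts for the slant, shape, and real-object tasks.

The generative observer turns the geometric predictions into simulated
adjustment settings.  Perceived slant is a per-axis gain on the
closed-form disparity slant: unit gain for horizontal magnification, a
smaller gain plus a tanh saturation for vertical (empirically the
induced effect plateaus at higher magnifications), and a small residual
gain for uniform magnification (pure geometry predicts a null there, but
observers still show a systematic drift in the horizontal-magnification
direction).  Perceived slant couples into the shape percept through a
coupling factor in (0, 1]: shape distortion is typically weaker than the
full slant geometry demands.  Adjustment noise is Gaussian on slant
(degrees) and log-normal on shape ratios.

Each participant owns an independent random stream spawned from the
cohort seed, so enlarging a cohort never perturbs existing participants,
and the slant task, shape task and real-object session of one
participant use separate child streams of that participant's stream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    AXES,
    HORIZONTAL,
    LEFT,
    RIGHT,
    UNIFORM,
    VERTICAL,
    MagnificationSpec,
    ViewingGeometry,
)
from .predictors import (
    ObjectSpec,
    nulling_shape_ratio,
    perspective_shape_ratio,
    predicted_slant_closed_form,
)

SLANT_TASK_MAGS = (0.0, 3.0, 6.0, 9.0, 12.0)
SHAPE_TASK_MAGS = (0.0, 1.0, 2.0, 3.0, 4.0)
SPECTACLE_MAG_PCT = 3.8  # horizontal magnifier over the right eye
REAL_OBJECTS = ("phone", "square")
# Drawn object sizes: the printed square is 7.5 cm; a typical phone is
# taken as 7 cm wide and 14 cm tall.
OBJECT_LEFT_SIDE_CM = {"phone": 14.0, "square": 7.5}
OBJECT_HALF_WIDTH_CM = {"phone": 3.5, "square": 3.75}


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of one synthetic observer.

    gain_h / gain_v / gain_u
        Slant gain per magnification axis (dimensionless, >= 0).
    sat_deg
        Saturation scale (degrees) for the vertical-axis (induced)
        slant; the response magnitude follows sat*tanh(|slant|/sat).
    coupling
        Slant-to-shape coupling in (0, 1]; 1 means the shape percept
        fully reflects the perceived slant.
    slant_noise_sd
        Adjustment noise SD on slant settings, degrees.
    ratio_noise_sd
        Adjustment noise SD on log shape ratios.
    report_threshold
        Perceived slant magnitude (degrees) above which a real object is
        reported as slanted.
    lapse
        Probability of an attention lapse on a binary report (the answer
        is then a coin flip).
    direction_reliability
        Probability that a reported slant direction matches the sign of
        the perceived slant (0.5 = random).
    """

    gain_h: float = 1.0
    gain_v: float = 0.85
    gain_u: float = 0.35
    sat_deg: float = 15.0
    coupling: float = 0.8
    slant_noise_sd: float = 2.0
    ratio_noise_sd: float = 0.01
    report_threshold: float = 4.0
    lapse: float = 0.05
    direction_reliability: float = 0.55

    def __post_init__(self) -> None:
        for name in ("gain_h", "gain_v", "gain_u"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.coupling <= 1:
            raise ValueError(f"coupling must be in (0, 1], got {self.coupling}")
        if self.sat_deg <= 0:
            raise ValueError("sat_deg must be > 0")
        if self.slant_noise_sd < 0 or self.ratio_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        for name in ("lapse", "direction_reliability"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


# Bounds used when drawing individual parameters from truncated normals.
_PARAM_BOUNDS: Dict[str, Tuple[float, float]] = {
    "gain_h": (0.0, np.inf),
    "gain_v": (0.0, np.inf),
    "gain_u": (0.0, np.inf),
    "sat_deg": (1.0, np.inf),
    "coupling": (0.05, 1.0),
    "slant_noise_sd": (0.0, np.inf),
    "ratio_noise_sd": (0.0, np.inf),
    "report_threshold": (0.0, np.inf),
    "lapse": (0.0, 1.0),
    "direction_reliability": (0.5, 1.0),
}

# Default between-participant SDs: modest individual differences in
# gains and coupling, none in the report parameters by default.
DEFAULT_PARAM_SDS: Dict[str, float] = {
    "gain_h": 0.05,
    "gain_v": 0.08,
    "gain_u": 0.08,
    "sat_deg": 1.0,
    "coupling": 0.05,
    "slant_noise_sd": 0.3,
    "ratio_noise_sd": 0.002,
    "report_threshold": 0.5,
    "lapse": 0.0,
    "direction_reliability": 0.0,
}


@dataclass(frozen=True)
class CohortConfig:
    """A simulated experiment: who, how often, and under what conditions."""

    n_participants: int = 20
    repetitions: int = 4
    slant_mags: Sequence[float] = SLANT_TASK_MAGS
    shape_mags: Sequence[float] = SHAPE_TASK_MAGS
    seed: int = 0
    means: ObserverParams = field(default_factory=ObserverParams)
    param_sds: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PARAM_SDS))

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def realize_cohort(config: CohortConfig) -> List[ObserverParams]:
    """Draw each participant's parameters from the population.

    Deterministic in the cohort seed; participant i's draw does not
    depend on the presence of participants j > i.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    participants = []
    for ss in streams:
        rng = np.random.default_rng(ss.spawn(4)[0])
        fields = {}
        for f in dataclasses.fields(ObserverParams):
            lo, hi = _PARAM_BOUNDS[f.name]
            fields[f.name] = _truncated_normal(
                rng, getattr(config.means, f.name),
                config.param_sds.get(f.name, 0.0), lo, hi,
            )
        participants.append(ObserverParams(**fields))
    return participants


def _task_rng(config: CohortConfig, participant: int, task_index: int) -> np.random.Generator:
    """Child stream `task_index` of one participant (0 = parameter draw)."""
    ss = np.random.SeedSequence(config.seed).spawn(config.n_participants)[participant]
    return np.random.default_rng(ss.spawn(4)[task_index])


def perceived_slant(
    obs: ObserverParams,
    mag: MagnificationSpec,
    geom: ViewingGeometry,
    rng: np.random.Generator,
) -> float:
    """One noisy perceived-slant draw (degrees) for a magnification."""
    if mag.axis == HORIZONTAL:
        base = obs.gain_h * predicted_slant_closed_form(mag, geom)
    elif mag.axis == VERTICAL:
        cf = predicted_slant_closed_form(mag, geom)
        saturated = obs.sat_deg * np.tanh(abs(cf) / obs.sat_deg)
        base = obs.gain_v * np.sign(cf) * saturated
    else:  # uniform: geometry predicts zero; residual follows the
        # horizontal-equivalent direction with a small gain
        equivalent = MagnificationSpec(
            eye=mag.eye, axis=HORIZONTAL, percent=mag.percent
        )
        base = obs.gain_u * predicted_slant_closed_form(equivalent, geom)
    return float(base + rng.normal(0.0, obs.slant_noise_sd))


def signed_magnification(eye: str, percent: float) -> float:
    """Signed condition axis: left-eye magnification negative, right positive."""
    return -percent if eye == LEFT else percent


def simulate_slant_adjustment(
    config: CohortConfig, geom: ViewingGeometry
) -> pd.DataFrame:
    """Simulate the slant-nulling task for a whole cohort.

    The recorded response is the *physical* slant that made the cloud
    look frontoparallel, i.e. minus the perceived slant: the surface is
    set to face away from the magnified eye.
    """
    participants = realize_cohort(config)
    rows = []
    for i, obs in enumerate(participants):
        rng = _task_rng(config, i, 1)
        for axis in AXES:
            for eye in (LEFT, RIGHT):
                for pct in config.slant_mags:
                    mag = MagnificationSpec(eye=eye, axis=axis, percent=pct)
                    for rep in range(config.repetitions):
                        sp = perceived_slant(obs, mag, geom, rng)
                        rows.append(
                            (f"P{i:02d}", "slant", axis, eye,
                             signed_magnification(eye, pct), rep, -sp)
                        )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "task", "axis", "eye",
                 "magnification_pct", "repetition", "response"],
    )


def simulate_shape_adjustment(
    config: CohortConfig, geom: ViewingGeometry, obj: ObjectSpec
) -> pd.DataFrame:
    """Simulate the shape-nulling task (adjust a quad until it looks square).

    The recorded response is the on-screen right/left height ratio that
    cancelled the percept: the nulling ratio of the coupled perceived
    slant, with multiplicative log-normal setting noise.
    """
    participants = realize_cohort(config)
    rows = []
    for i, obs in enumerate(participants):
        rng = _task_rng(config, i, 2)
        for axis in AXES:
            for eye in (LEFT, RIGHT):
                for pct in config.shape_mags:
                    mag = MagnificationSpec(eye=eye, axis=axis, percent=pct)
                    for rep in range(config.repetitions):
                        sp = perceived_slant(obs, mag, geom, rng)
                        ratio = nulling_shape_ratio(obs.coupling * sp, obj)
                        ratio *= float(np.exp(rng.normal(0.0, obs.ratio_noise_sd)))
                        rows.append(
                            (f"P{i:02d}", "shape", axis, eye,
                             signed_magnification(eye, pct), rep, ratio)
                        )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "task", "axis", "eye",
                 "magnification_pct", "repetition", "response"],
    )


def simulate_real_object_session(
    config: CohortConfig,
    obj: ObjectSpec = ObjectSpec(),
    spectacle_percent: float = SPECTACLE_MAG_PCT,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate drawings and binary slant reports with and without spectacles.

    Control spectacles are plano (no magnification); experimental
    spectacles put a horizontal magnifier over the right eye.  Each
    participant draws each object once per spectacle condition; the
    drawn right/left ratio is the perspective shape ratio of the coupled
    perceived slant, with log-normal drawing noise.  The binary slant
    report fires when the perceived slant magnitude exceeds the
    observer's threshold (with lapses), and the reported direction
    matches the true sign only with the observer's direction
    reliability.
    """
    participants = realize_cohort(config)
    geom_obj = ViewingGeometry(ipd_cm=ViewingGeometry().ipd_cm,
                               distance_cm=obj.viewing_distance)
    drawing_rows = []
    report_rows = []
    for i, obs in enumerate(participants):
        rng = _task_rng(config, i, 3)
        for spectacles in ("control", "experimental"):
            pct = spectacle_percent if spectacles == "experimental" else 0.0
            mag = MagnificationSpec(eye=RIGHT, axis=HORIZONTAL, percent=pct)
            for obj_name in REAL_OBJECTS:
                obj_spec = ObjectSpec(
                    half_width=OBJECT_HALF_WIDTH_CM[obj_name],
                    viewing_distance=obj.viewing_distance,
                )
                sp = perceived_slant(obs, mag, geom_obj, rng)
                ratio = perspective_shape_ratio(obs.coupling * sp, obj_spec)
                ratio *= float(np.exp(rng.normal(0.0, obs.ratio_noise_sd)))
                left = OBJECT_LEFT_SIDE_CM[obj_name]
                drawing_rows.append(
                    (f"P{i:02d}", spectacles, obj_name, left, ratio * left)
                )

                sp_report = perceived_slant(obs, mag, geom_obj, rng)
                p_slanted = (1 - obs.lapse) * float(
                    abs(sp_report) > obs.report_threshold
                ) + obs.lapse * 0.5
                slanted = int(rng.random() < p_slanted)
                if slanted:
                    # positive perceived slant = right side farther = left closer
                    true_dir = "left_closer" if sp_report > 0 else "right_closer"
                    if rng.random() < obs.direction_reliability:
                        direction = true_dir
                    else:
                        direction = (
                            "right_closer" if true_dir == "left_closer"
                            else "left_closer"
                        )
                else:
                    direction = "none"
                report_rows.append(
                    (f"P{i:02d}", spectacles, obj_name, slanted, direction)
                )
    drawings = pd.DataFrame(
        drawing_rows,
        columns=["participant_id", "spectacles", "object", "left_cm", "right_cm"],
    )
    reports = pd.DataFrame(
        report_rows,
        columns=["participant_id", "spectacles", "object", "slanted", "direction"],
    )
    return drawings, reports
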