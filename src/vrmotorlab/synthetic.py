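"""Synthetic learners, trajectories and cohorts.

Three generators feed the pipeline:

* **Learner agents** hit targets with a logistic probability of the gap
  between their current skill and the block's total difficulty index; skill
  approaches an asymptote exponentially with practice.  They drive the
  closed-loop regulator simulations.
* **Analytic trajectories** traverse an ideal line or circle with a
  minimum-jerk speed profile split into overlapping submovement bursts,
  plus controllable orthogonal sinusoidal deviation and white positional
  noise -- enough structure to exercise SAT and SPARC with known answers.
* **Cohorts** are participants x {T0, T1, T2} outcome tables with
  configurable standardised effects, between-participant spread,
  measurement noise and missingness, used to validate the statistics stage
  (parameter recovery, type-I error, power).

Everything is reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io_session import OUTCOME_COLUMNS, Trajectory
from .kinematics import CircleShape, IdealShape, LineShape
from .regulator import (
    BlockLog,
    DifficultyState,
    TrialEvent,
    trials_for_block,
)


# --- learner agents --------------------------------------------------------

@dataclass(frozen=True)
class LearnerProfile:
    """Synthetic participant for closed-loop simulation.

    Skill after ``b`` blocks of practice is
    ``asymptote - (asymptote - baseline) * (1 - learning_rate)**b`` (units of
    the difficulty index); the probability of hitting a target is
    ``logistic((skill - difficulty_index) / slope)``.  ``fp_propensity``
    scales the chance of striking a distractor; ``periphery_penalty`` is a
    logit handicap applied to peripheral spawns.
    """

    baseline_skill: float
    asymptote_skill: float
    learning_rate: float
    slope: float = 2.5
    fp_propensity: float = 0.08
    periphery_penalty: float = 0.6

    def __post_init__(self) -> None:
        if self.asymptote_skill < self.baseline_skill:
            raise ParameterError("asymptote_skill must be >= baseline_skill")
        if not (0.0 <= self.learning_rate <= 1.0):
            raise ParameterError("learning_rate must lie in [0, 1]")
        if self.slope <= 0:
            raise ParameterError("slope must be positive")
        if self.fp_propensity < 0 or self.periphery_penalty < 0:
            raise ParameterError("propensities must be non-negative")

    def skill(self, block_index: int) -> float:
        gap = self.asymptote_skill - self.baseline_skill
        return self.asymptote_skill - gap * (1.0 - self.learning_rate) ** block_index


def _logistic(x: float) -> float:
    # clip keeps the probability strictly inside (0, 1)
    return 1.0 / (1.0 + math.exp(-float(np.clip(x, -35.0, 35.0))))


def success_probability(
    learner: LearnerProfile, state: DifficultyState, block_index: int
) -> float:
    """Hit probability: logistic in (skill - difficulty index) / slope."""
    gap = learner.skill(block_index) - state.total_difficulty_index()
    return _logistic(gap / learner.slope)


@dataclass(frozen=True)
class PopulationSpec:
    """Calibration constants for the default synthetic learner population.

    Chosen so a simulated cohort follows the feasibility course of a real
    7-day deployment: a brief too-easy phase after starting at the easiest
    level, entry of the cohort-median success rate into the 60-80 % band
    within roughly a dozen blocks, and sustained occupancy near the
    regulator's 75 % goal thereafter.  Learning continues (slowly) across
    the whole session, which is what holds the operating point near the
    upper band edge rather than the band midpoint.
    """

    baseline_mean: float = 5.0
    baseline_sd: float = 1.2
    asymptote_gain_mean: float = 110.0
    asymptote_gain_sd: float = 15.0
    learning_rate_mean: float = 0.005
    learning_rate_sd: float = 0.0012
    learning_rate_bounds: tuple = (0.002, 0.012)
    slope: float = 2.5
    fp_propensity_range: tuple = (0.03, 0.12)
    periphery_penalty_range: tuple = (0.4, 1.0)


def sample_population(
    n: int, rng: np.random.Generator, spec: PopulationSpec = PopulationSpec()
) -> List[LearnerProfile]:
    """Draw ``n`` learner profiles from the population distribution."""
    if n < 1:
        raise ParameterError("need at least one learner")
    learners = []
    for _ in range(n):
        baseline = max(0.0, rng.normal(spec.baseline_mean, spec.baseline_sd))
        gain = max(5.0, rng.normal(spec.asymptote_gain_mean, spec.asymptote_gain_sd))
        lr = float(
            np.clip(
                rng.normal(spec.learning_rate_mean, spec.learning_rate_sd),
                *spec.learning_rate_bounds,
            )
        )
        learners.append(
            LearnerProfile(
                baseline_skill=baseline,
                asymptote_skill=baseline + gain,
                learning_rate=lr,
                slope=spec.slope,
                fp_propensity=float(rng.uniform(*spec.fp_propensity_range)),
                periphery_penalty=float(rng.uniform(*spec.periphery_penalty_range)),
            )
        )
    return learners


def _spawn_location(rng: np.random.Generator, spawn_bias: Optional[str]) -> tuple:
    if spawn_bias == "central":
        scale = 0.7
    elif spawn_bias == "peripheral":
        scale = 1.0  # peripheral bias resamples below
    else:
        scale = 1.0
    loc = rng.uniform(-scale, scale, size=2)
    if spawn_bias == "peripheral" and max(abs(loc[0]), abs(loc[1])) <= 0.6:
        loc = np.sign(loc) * (0.6 + 0.4 * np.abs(loc))
    return (float(loc[0]), float(loc[1]))


def simulate_block(
    learner: LearnerProfile,
    state: DifficultyState,
    block_index: int,
    rng: np.random.Generator,
) -> BlockLog:
    """Simulate one block of play for a learner under a difficulty state.

    Targets spawn uniformly over the normalised working area (optionally
    biased centrally); each is hit with the learner's success probability,
    handicapped at peripheral spawns.  False positives occur per trial with
    a rate scaled by distractor count and the salience mix; low-salience
    (target-like) distractors are over-represented among them.
    """
    n_trials = trials_for_block(state)
    base_logit = (
        learner.skill(block_index) - state.total_difficulty_index()
    ) / learner.slope
    fp_rate = min(
        0.9,
        learner.fp_propensity
        * (state.n_distractors / 23.0)
        * (0.3 + 0.7 * state.salience_mix),
    )
    exposure = state.exposure_time_s()
    events: List[TrialEvent] = []
    for _ in range(n_trials):
        loc = _spawn_location(rng, state.spawn_bias)
        peripheral = max(abs(loc[0]), abs(loc[1])) > 0.6
        logit = base_logit - (learner.periphery_penalty if peripheral else 0.0)
        if rng.random() < _logistic(logit):
            latency = 0.2 + float(rng.beta(2.0, 3.0)) * max(exposure - 0.2, 0.05)
            events.append(TrialEvent(kind="hit", location=loc, latency=latency))
        else:
            events.append(TrialEvent(kind="omission", location=loc))
        if state.n_distractors > 0 and rng.random() < fp_rate:
            # target-like distractors are twice as likely to draw the strike
            m = state.salience_mix
            p_low = 2.0 * m / (1.0 + m) if m > 0 else 0.0
            sal = "low" if rng.random() < p_low else "high"
            events.append(
                TrialEvent(
                    kind="false_positive",
                    location=_spawn_location(rng, state.spawn_bias),
                    distractor_salience=sal,
                )
            )
    return BlockLog(block_index=block_index, trials=tuple(events), state_used=state)


# --- minimum-jerk trajectories ---------------------------------------------

def min_jerk_position(tau: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk displacement: 0 -> 1 over tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def min_jerk_speed(tau: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk speed; peak value 1.875 at tau = 0.5."""
    tau = np.asarray(tau, float)
    out = 30 * tau**2 * (1 - tau) ** 2
    out[(tau < 0) | (tau > 1)] = 0.0
    return out


#: Fraction of a burst's duration shared with its successor.
SUBMOVEMENT_OVERLAP = 0.25

#: Full sinusoidal deviation cycles per task (integer => exact RMS a/sqrt(2)).
DEVIATION_CYCLES = 4


@dataclass(frozen=True)
class TrajectoryGenSpec:
    """Recipe for a synthetic drawing-task trajectory.

    The base path traverses ``shape`` with a minimum-jerk speed profile
    split into ``n_submovements`` overlapping bursts; ``deviation_amp_cm``
    adds an orthogonal sinusoid and ``noise_sd_cm`` white positional noise.
    ``duration_s`` is authoritative; if ``mean_speed`` (m/s) is given the
    duration is derived from the shape's path length instead.
    """

    shape: IdealShape
    duration_s: float = 2.0
    mean_speed: Optional[float] = None
    n_submovements: int = 1
    deviation_amp_cm: float = 0.0
    noise_sd_cm: float = 0.0
    seed: Optional[int] = None
    rate_hz: float = 60.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError("duration must be positive")
        if self.mean_speed is not None and self.mean_speed <= 0:
            raise ParameterError("mean_speed must be positive")
        if self.n_submovements < 1:
            raise ParameterError("need at least one submovement")
        if self.deviation_amp_cm < 0 or self.noise_sd_cm < 0:
            raise ParameterError("amplitudes must be non-negative")

    def effective_duration(self) -> float:
        if self.mean_speed is not None:
            return self.shape.length / self.mean_speed
        return self.duration_s


def _submovement_arc(t: np.ndarray, duration: float, n_sub: int) -> np.ndarray:
    """Normalised arc-length coordinate 0 -> 1 from overlapping bursts."""
    if n_sub == 1:
        return min_jerk_position(t / duration)
    burst = duration / (1.0 + (1.0 - SUBMOVEMENT_OVERLAP) * (n_sub - 1))
    step = (1.0 - SUBMOVEMENT_OVERLAP) * burst
    s = np.zeros_like(t)
    for k in range(n_sub):
        s += min_jerk_position((t - k * step) / burst) / n_sub
    return s


def _orthogonal_direction(shape: IdealShape) -> np.ndarray:
    if isinstance(shape, LineShape):
        u = shape.direction
        helper = np.array([0.0, 0.0, 1.0])
        if abs(u @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        w = np.cross(u, helper)
        return w / np.linalg.norm(w)
    return np.asarray(shape.n, float)  # circle: deviate out of plane


def generate_trajectory(spec: TrajectoryGenSpec) -> Trajectory:
    """Render a synthetic 60 Hz controller trajectory from a recipe."""
    duration = spec.effective_duration()
    n = int(round(duration * spec.rate_hz))
    if n + 1 < 8:
        raise ParameterError("duration too short: need at least 8 samples")
    t = np.arange(n + 1) / spec.rate_hz
    s = _submovement_arc(t, duration, spec.n_submovements)
    shape = spec.shape
    if isinstance(shape, LineShape):
        p0 = np.asarray(shape.p0, float)
        xyz = p0[None, :] + np.outer(s * shape.length, shape.direction)
    elif isinstance(shape, CircleShape):
        e1, e2 = shape.plane_basis()
        theta = 2.0 * math.pi * s
        xyz = (
            np.asarray(shape.c, float)[None, :]
            + shape.r * np.outer(np.cos(theta), e1)
            + shape.r * np.outer(np.sin(theta), e2)
        )
    else:  # pragma: no cover - typing guard
        raise ParameterError(f"unknown shape {type(shape).__name__}")
    if spec.deviation_amp_cm > 0:
        w = _orthogonal_direction(shape)
        dev = (spec.deviation_amp_cm / 100.0) * np.sin(
            2.0 * math.pi * DEVIATION_CYCLES * t / duration
        )
        xyz = xyz + np.outer(dev, w)
    if spec.noise_sd_cm > 0:
        rng = np.random.default_rng(spec.seed)
        xyz = xyz + rng.normal(0.0, spec.noise_sd_cm / 100.0, size=xyz.shape)
    return Trajectory(
        t=t, xyz=xyz, nominal_rate=spec.rate_hz, task=shape.kind, hand="dominant"
    )


# --- synthetic cohorts -----------------------------------------------------

@dataclass(frozen=True)
class OutcomeSpec:
    """One outcome's T0 distribution and standardised T1/T2 shifts.

    ``d_t1``/``d_t2`` are paired standardised effects: the mean change from
    T0 in units of the within-participant change SD (sqrt(2) * noise SD).
    """

    mean: float
    sd: float
    d_t1: float = 0.0
    d_t2: float = 0.0
    noise_frac: float = 0.5  # measurement noise SD as a fraction of sd
    integer: bool = False
    floor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ParameterError("outcome SD must be positive")
        if not (0.0 <= self.noise_frac < 1.0):
            raise ParameterError("noise_frac must lie in [0, 1)")


def default_outcomes(
    effects: Optional[Dict[str, Sequence[float]]] = None
) -> Dict[str, OutcomeSpec]:
    """Outcome set mirroring a pre/post/follow-up VR assessment battery.

    Baselines follow typical values for older adults on these instruments;
    all true effects default to zero (a null battery) unless ``effects``
    maps outcome names to (d_t1, d_t2) pairs.  The reaction-time outcome is
    the designated negative control (mean 398 ms, SD 117 ms, no effect).
    """
    effects = effects or {}
    base = {
        "sat_line": OutcomeSpec(mean=3.7, sd=1.4),
        "sat_circle": OutcomeSpec(mean=3.9, sd=1.6),
        "sparc_line": OutcomeSpec(mean=-1.97, sd=0.15),
        "sparc_circle": OutcomeSpec(mean=-3.77, sd=2.2),
        "bbt_vr": OutcomeSpec(mean=29.0, sd=13.0, integer=True, floor=0.0),
        "reaction_time_ms": OutcomeSpec(mean=398.0, sd=117.0, floor=0.0),
    }
    out = {}
    for name, spec in base.items():
        if name in effects:
            d1, d2 = effects[name]
            spec = replace(spec, d_t1=float(d1), d_t2=float(d2))
        out[name] = spec
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic participants x time-points outcome table."""

    n_participants: int = 20
    outcomes: Dict[str, OutcomeSpec] = field(default_factory=default_outcomes)
    missing_rate: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ParameterError("need at least 2 participants")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ParameterError("missing_rate must lie in [0, 1)")
        if not self.outcomes:
            raise ParameterError("cohort needs at least one outcome")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a long-format outcome table from a cohort recipe.

    Model per outcome: a participant random intercept with SD
    ``sqrt(sd^2 - noise^2)``, plus the configured standardised shift at
    T1/T2 (in units of the change SD ``sqrt(2) * noise``), plus iid
    measurement noise.  With zero noise the intercepts carry the full SD
    and repeated measurements are identical, so zero-effect specs yield
    T0 = T1 = T2 exactly.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    time_points = ("T0", "T1", "T2")
    for name, ospec in spec.outcomes.items():
        noise_sd = ospec.noise_frac * ospec.sd
        between_sd = math.sqrt(max(ospec.sd**2 - noise_sd**2, 0.0))
        change_sd = math.sqrt(2.0) * noise_sd
        shifts = {
            "T0": 0.0,
            "T1": ospec.d_t1 * change_sd,
            "T2": ospec.d_t2 * change_sd,
        }
        intercepts = rng.normal(ospec.mean, between_sd, size=spec.n_participants)
        for i in range(spec.n_participants):
            pid = f"P{i + 1:02d}"
            for tp in time_points:
                value = intercepts[i] + shifts[tp] + rng.normal(0.0, noise_sd)
                if ospec.floor is not None:
                    value = max(value, ospec.floor)
                if ospec.integer:
                    value = float(int(round(value)))
                if spec.missing_rate > 0 and rng.random() < spec.missing_rate:
                    value = np.nan
                rows.append((pid, tp, name, value))
    return pd.DataFrame(rows, columns=OUTCOME_COLUMNS)
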