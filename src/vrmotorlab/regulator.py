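"""Self-adaptive difficulty regulation for a whack-a-mole style VR game.

The game presents blocks of 1-24 target trials.  After each block the
regulator computes the block's success rate (hits / target trials),
classifies it into one of three bands --

* ``> 75 %``  the block was *too easy*,
* ``50-75 %`` the block was *difficult* (the desired operating band),
* ``< 50 %``  the block was *too difficult*

-- and adjusts the game parameters for the next block.  Adjustment is a
deterministic decision table: increases in difficulty walk a fixed priority
ladder (withdraw cues first, then shorten target exposure, enlarge the
working area, add distractors, and finally make distractors more
target-like); decreases relax the dimension that block diagnostics implicate
(peripheral omissions -> shrink the area and restore a cue; false positives
on target-like distractors -> lower the salience mix; otherwise lengthen the
exposure).  The controller aims to hold players at roughly 75 % success.

Difficulty is summarised by a scalar *total difficulty index*: the sum of
all dimension levels.  Synthetic learners (see :mod:`vrmotorlab.synthetic`)
respond to difficulty only through this index, which is what makes the
closed loop analysable.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import IntegrityError, ParameterError

logger = logging.getLogger(__name__)

# --- difficulty space ------------------------------------------------------

#: Cue modes ordered from easiest (most help) to hardest (no help).
CUE_ORDER: Tuple[str, ...] = ("visual_and_auditory", "auditory_spatial", "none")

MAX_EXPOSURE_LEVEL = 10
MAX_AREA_LEVEL = 10
MAX_DISTRACTORS = 23
SALIENCE_STEPS = 4  # salience_mix moves in steps of 1/SALIENCE_STEPS

#: Success-rate band edges: [0, LOWER) too difficult, [LOWER, UPPER] difficult,
#: (UPPER, 1] too easy.  Both boundaries belong to the middle band.
LOWER_BAND = 0.50
UPPER_BAND = 0.75

#: Normalised coordinate beyond which a spawn counts as peripheral.
PERIPHERY_FRAC = 0.6

#: Block size mapping: 4 + 2 * index, clamped to the game's 1-24 trial range.
TRIALS_BASE = 4
TRIALS_STEP = 2
TRIALS_MIN, TRIALS_MAX = 1, 24


class Verdict(enum.Enum):
    TOO_EASY = "too_easy"
    DIFFICULT = "difficult"
    TOO_DIFFICULT = "too_difficult"


@dataclass(frozen=True)
class DifficultyState:
    """Adjustable game parameters for one block.

    Every level is oriented so that *higher means harder*: ``exposure_level``
    shortens the target's on-screen time, ``area_level`` widens the working
    area, ``n_distractors`` adds competing moles, ``salience_mix`` is the
    fraction of low-salience-contrast (target-like) distractors, and
    ``cue_mode`` withdraws help as it moves along :data:`CUE_ORDER`.
    ``spawn_bias`` is a fine-tuning knob that does not enter the difficulty
    index.
    """

    exposure_level: int = 0
    area_level: int = 0
    n_distractors: int = 0
    salience_mix: float = 0.0
    cue_mode: str = CUE_ORDER[0]
    spawn_bias: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.exposure_level <= MAX_EXPOSURE_LEVEL):
            raise ParameterError(f"exposure_level out of bounds: {self.exposure_level}")
        if not (0 <= self.area_level <= MAX_AREA_LEVEL):
            raise ParameterError(f"area_level out of bounds: {self.area_level}")
        if not (0 <= self.n_distractors <= MAX_DISTRACTORS):
            raise ParameterError(f"n_distractors out of bounds: {self.n_distractors}")
        if not (0.0 <= self.salience_mix <= 1.0):
            raise ParameterError(f"salience_mix out of bounds: {self.salience_mix}")
        if self.cue_mode not in CUE_ORDER:
            raise ParameterError(f"unknown cue_mode: {self.cue_mode!r}")
        if self.spawn_bias not in (None, "central", "peripheral"):
            raise ParameterError(f"unknown spawn_bias: {self.spawn_bias!r}")

    @property
    def cue_rank(self) -> int:
        return CUE_ORDER.index(self.cue_mode)

    @property
    def salience_level(self) -> int:
        return int(round(self.salience_mix * SALIENCE_STEPS))

    def total_difficulty_index(self) -> int:
        """Scalar difficulty: the sum of all dimension levels (0..49)."""
        return (
            self.exposure_level
            + self.area_level
            + self.n_distractors
            + self.salience_level
            + self.cue_rank
        )

    def exposure_time_s(self) -> float:
        """Target on-screen time implied by ``exposure_level`` (2.0 -> 0.5 s)."""
        return 2.0 - 0.15 * self.exposure_level


def easiest_state() -> DifficultyState:
    return DifficultyState()


def hardest_state() -> DifficultyState:
    return DifficultyState(
        exposure_level=MAX_EXPOSURE_LEVEL,
        area_level=MAX_AREA_LEVEL,
        n_distractors=MAX_DISTRACTORS,
        salience_mix=1.0,
        cue_mode=CUE_ORDER[-1],
    )


MAX_DIFFICULTY_INDEX = hardest_state().total_difficulty_index()


# --- block events ----------------------------------------------------------

@dataclass(frozen=True)
class TrialEvent:
    """One trial outcome: a target hit/omission or a struck distractor.

    ``location`` is the spawn coordinate (azimuth, elevation) normalised to
    the current working area, each in [-1, 1].  ``latency`` is present only
    for hits; ``distractor_salience`` ("high"/"low") only for false positives.
    """

    kind: str  # hit | omission | false_positive
    location: Tuple[float, float]
    latency: Optional[float] = None
    distractor_salience: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in ("hit", "omission", "false_positive"):
            raise ParameterError(f"unknown trial event kind: {self.kind!r}")
        if (self.latency is not None) != (self.kind == "hit"):
            raise IntegrityError("latency must be present iff kind == 'hit'")
        if (self.distractor_salience != "none") != (self.kind == "false_positive"):
            raise IntegrityError(
                "distractor_salience must be set iff kind == 'false_positive'"
            )
        if self.kind == "false_positive" and self.distractor_salience not in ("high", "low"):
            raise ParameterError(
                f"false_positive salience must be high/low, got {self.distractor_salience!r}"
            )

    @property
    def is_target(self) -> bool:
        return self.kind in ("hit", "omission")

    @property
    def is_peripheral(self) -> bool:
        return max(abs(self.location[0]), abs(self.location[1])) > PERIPHERY_FRAC


@dataclass(frozen=True)
class BlockLog:
    """All trial events of one block plus the difficulty state used."""

    block_index: int
    trials: Tuple[TrialEvent, ...]
    state_used: DifficultyState

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        n_targets = sum(1 for ev in self.trials if ev.is_target)
        if not (1 <= n_targets <= TRIALS_MAX):
            raise IntegrityError(
                f"block {self.block_index}: {n_targets} target trials outside 1..{TRIALS_MAX}"
            )

    @property
    def n_targets(self) -> int:
        return sum(1 for ev in self.trials if ev.is_target)

    @property
    def n_hits(self) -> int:
        return sum(1 for ev in self.trials if ev.kind == "hit")


@dataclass
class SessionLog:
    """Sequence of regulated blocks for one player."""

    blocks: List[BlockLog]
    learner_id: str = "anonymous"
    seed: Optional[int] = None

    def success_rates(self) -> np.ndarray:
        return np.array([success_rate(b) for b in self.blocks], dtype=float)

    def difficulty_indices(self) -> np.ndarray:
        return np.array(
            [b.state_used.total_difficulty_index() for b in self.blocks], dtype=int
        )


@dataclass(frozen=True)
class BlockDiagnostics:
    """Per-block performance indicators driving the decision table."""

    success_rate: float
    omission_fraction: float
    false_positive_count: int
    omission_periphery_share: float
    fp_low_salience_share: float


# --- block evaluation ------------------------------------------------------

def success_rate(block: BlockLog) -> float:
    """Hits divided by target trials; false positives are not trials."""
    n_targets = block.n_targets
    if n_targets == 0:
        raise IntegrityError("block has no target trials")
    return block.n_hits / n_targets


def classify_block(rate: float) -> Verdict:
    """Map a success rate to a verdict; both band edges are 'difficult'."""
    if not (0.0 <= rate <= 1.0):
        raise ParameterError(f"success rate outside [0, 1]: {rate}")
    if rate > UPPER_BAND:
        return Verdict.TOO_EASY
    if rate >= LOWER_BAND:
        return Verdict.DIFFICULT
    return Verdict.TOO_DIFFICULT


def diagnose(block: BlockLog) -> BlockDiagnostics:
    """Compute the indicators the regulator uses to pick what to adjust."""
    targets = [ev for ev in block.trials if ev.is_target]
    omissions = [ev for ev in targets if ev.kind == "omission"]
    fps = [ev for ev in block.trials if ev.kind == "false_positive"]
    rate = success_rate(block)
    omission_fraction = len(omissions) / len(targets)
    periphery_share = (
        sum(1 for ev in omissions if ev.is_peripheral) / len(omissions)
        if omissions
        else 0.0
    )
    low_share = (
        sum(1 for ev in fps if ev.distractor_salience == "low") / len(fps)
        if fps
        else 0.0
    )
    return BlockDiagnostics(
        success_rate=rate,
        omission_fraction=omission_fraction,
        false_positive_count=len(fps),
        omission_periphery_share=periphery_share,
        fp_low_salience_share=low_share,
    )


# --- decision table --------------------------------------------------------

def _raise_one(state: DifficultyState) -> DifficultyState:
    """One difficulty increase along the fixed priority ladder.

    Cues are help, so they are the first help withdrawn; target-like
    distractors are the subtlest manipulation, so they come last.  Returns
    the state unchanged when every dimension is already at its ceiling.
    """
    if state.cue_rank < len(CUE_ORDER) - 1:
        return replace(state, cue_mode=CUE_ORDER[state.cue_rank + 1])
    if state.exposure_level < MAX_EXPOSURE_LEVEL:
        return replace(state, exposure_level=state.exposure_level + 1)
    if state.area_level < MAX_AREA_LEVEL:
        return replace(state, area_level=state.area_level + 1)
    if state.n_distractors < MAX_DISTRACTORS:
        return replace(state, n_distractors=state.n_distractors + 1)
    if state.salience_level < SALIENCE_STEPS:
        return replace(state, salience_mix=(state.salience_level + 1) / SALIENCE_STEPS)
    logger.debug("raise requested at max difficulty; clamped")
    return state


def _lower_one(state: DifficultyState) -> DifficultyState:
    """One difficulty decrease, undoing the ladder in reverse order."""
    if state.salience_level > 0:
        return replace(state, salience_mix=(state.salience_level - 1) / SALIENCE_STEPS)
    if state.n_distractors > 0:
        return replace(state, n_distractors=state.n_distractors - 1)
    if state.area_level > 0:
        return replace(state, area_level=state.area_level - 1)
    if state.exposure_level > 0:
        return replace(state, exposure_level=state.exposure_level - 1)
    if state.cue_rank > 0:
        return replace(state, cue_mode=CUE_ORDER[state.cue_rank - 1])
    logger.debug("lower requested at min difficulty; clamped")
    return state


def adjust(
    state: DifficultyState, verdict: Verdict, diagnostics: BlockDiagnostics
) -> DifficultyState:
    """Decision-table update producing the next block's difficulty state.

    * ``TOO_EASY``: raise one step along the priority ladder (two steps when
      the success rate was at or above 90 %, to shorten the too-easy phase).
    * ``TOO_DIFFICULT``: relax the implicated dimension -- peripheral
      omissions shrink the area and restore one cue; false positives on
      target-like distractors lower the salience mix; otherwise the exposure
      is lengthened (with a generic step-down fallback at the floor).
    * ``DIFFICULT``: no net level change; spawn bias is fine-tuned toward
      the centre when peripheral omissions dominate.
    """
    if verdict is Verdict.TOO_EASY:
        new = _raise_one(state)
        if diagnostics.success_rate >= 0.9:
            new = _raise_one(new)
        return replace(new, spawn_bias=None)

    if verdict is Verdict.TOO_DIFFICULT:
        new = state
        if diagnostics.omission_periphery_share > 0.5:
            if new.area_level > 0:
                new = replace(new, area_level=new.area_level - 1)
            if new.cue_rank > 0:
                new = replace(new, cue_mode=CUE_ORDER[new.cue_rank - 1])
        elif (
            diagnostics.fp_low_salience_share > 0.5
            and diagnostics.false_positive_count > 0
            and new.salience_level > 0
        ):
            new = replace(
                new, salience_mix=(new.salience_level - 1) / SALIENCE_STEPS
            )
        elif new.exposure_level > 0:
            new = replace(new, exposure_level=new.exposure_level - 1)
        if new.total_difficulty_index() == state.total_difficulty_index():
            # implicated dimensions were already at their floor
            new = _lower_one(new)
        return replace(new, spawn_bias=None)

    # DIFFICULT: in-band, hold the level, only fine-tune spawn placement.
    bias = "central" if diagnostics.omission_periphery_share > PERIPHERY_FRAC else None
    return replace(state, spawn_bias=bias)


def trials_for_block(state: DifficultyState) -> int:
    """Number of target trials for a block: grows with difficulty, 1..24."""
    n = TRIALS_BASE + TRIALS_STEP * state.total_difficulty_index()
    return int(np.clip(n, TRIALS_MIN, TRIALS_MAX))


# --- closed loop -----------------------------------------------------------

def run_regulated_session(
    learner,
    n_blocks: int,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    initial_state: Optional[DifficultyState] = None,
    learner_id: str = "anonymous",
) -> SessionLog:
    """Simulate ``n_blocks`` of closed-loop play for one synthetic learner.

    Each iteration simulates a block under the current difficulty state,
    diagnoses it, classifies the success rate and applies the decision table
    to produce the next state.  Fully reproducible given ``seed``/``rng``.
    """
    from .synthetic import simulate_block  # local import: avoids module cycle

    if n_blocks < 1:
        raise ParameterError("n_blocks must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    state = initial_state if initial_state is not None else easiest_state()
    blocks: List[BlockLog] = []
    for b in range(n_blocks):
        block = simulate_block(learner, state, b, rng)
        blocks.append(block)
        diag = diagnose(block)
        verdict = classify_block(diag.success_rate)
        state = adjust(state, verdict, diag)
    stored_seed = seed if isinstance(seed, (int, np.integer)) else None
    return SessionLog(blocks=blocks, learner_id=learner_id, seed=stored_seed)


# --- cohort feasibility analytics ------------------------------------------

def cohort_success_matrix(sessions: Sequence[SessionLog]) -> np.ndarray:
    """(n_learners, n_blocks) success-rate matrix; sessions must align."""
    if not sessions:
        raise ParameterError("no sessions given")
    lengths = {len(s.blocks) for s in sessions}
    if len(lengths) != 1:
        raise ParameterError("sessions have unequal block counts")
    return np.vstack([s.success_rates() for s in sessions])


def time_to_band(
    sessions: Sequence[SessionLog], band: Tuple[float, float] = (0.60, 0.80)
) -> Optional[int]:
    """First (1-based) block whose cohort-median success rate is in ``band``."""
    med = np.median(cohort_success_matrix(sessions), axis=0)
    inside = (med >= band[0]) & (med <= band[1])
    hits = np.nonzero(inside)[0]
    return int(hits[0]) + 1 if hits.size else None


def band_occupancy(
    sessions: Sequence[SessionLog],
    band: Tuple[float, float] = (0.60, 0.80),
    first_block: int = 12,
    last_block: int = 55,
) -> float:
    """Share of blocks ``first_block..last_block`` (1-based, inclusive) whose
    cohort-median success rate lies inside ``band``."""
    med = np.median(cohort_success_matrix(sessions), axis=0)
    if last_block > med.size:
        raise ParameterError(
            f"sessions have {med.size} blocks, need at least {last_block}"
        )
    window = med[first_block - 1 : last_block]
    inside = (window >= band[0]) & (window <= band[1])
    return float(inside.mean())


def block_success_table(sessions: Sequence[SessionLog]):
    """Per-block median and quartiles of the cohort success rate."""
    import pandas as pd

    mat = cohort_success_matrix(sessions)
    q1, med, q3 = np.percentile(mat, [25, 50, 75], axis=0)
    return pd.DataFrame(
        {
            "block": np.arange(1, mat.shape[1] + 1),
            "q1": q1,
            "median": med,
            "q3": q3,
        }
    )
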