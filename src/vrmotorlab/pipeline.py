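"""End-to-end experiment orchestration.

``run_full_experiment`` composes the whole artefact: a cohort of synthetic
learners plays regulated sessions (a 7-day block budget), their accumulated
practice improves the generation parameters of T0/T1/T2 assessment
trajectories, the kinematics engine scores those into an outcome table, and
the statistics stage produces the final report.  Every file the run writes
names the configuration hash and master seed, and a manifest makes the run
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from . import __version__
from .errors import ParameterError
from .io_session import write_outcome_table, write_session_log
from .kinematics import CircleShape, LineShape, analyze_task
from .regulator import (
    band_occupancy,
    block_success_table,
    run_regulated_session,
    time_to_band,
)
from .stats import run_study_analysis
from .synthetic import (
    PopulationSpec,
    TrajectoryGenSpec,
    generate_trajectory,
    sample_population,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunables of a full simulated study, with study-default values.

    Band bounds (0.50, 0.75), the 10 Hz/4th-order filter, the 0.1 cm SAT
    error floor, the SPARC parameters and alpha = .05 are the assessment
    constants; the rest parameterise the synthetic world.
    """

    seed: int = 0
    n_participants: int = 20
    n_days: int = 7
    blocks_per_day: int = 10
    band_lower: float = 0.50
    band_upper: float = 0.75
    cutoff_hz: float = 10.0
    filter_order: int = 4
    error_floor_cm: float = 0.1
    sparc_amp_threshold: float = 0.05
    sparc_max_cutoff_hz: float = 20.0
    alpha: float = 0.05
    #: Fractional shrink of deviation/submovement/duration parameters per
    #: unit of relative skill gain; 0 disables any practice effect.
    practice_gain: float = 0.6
    #: Share of the T1 improvement retained at the 1-week follow-up.
    retention: float = 0.9
    population: PopulationSpec = field(default_factory=PopulationSpec)

    def __post_init__(self) -> None:
        if not (0.0 < self.band_lower < self.band_upper < 1.0):
            raise ParameterError("band bounds must satisfy 0 < lower < upper < 1")
        if self.practice_gain < 0 or not (0.0 <= self.retention <= 1.0):
            raise ParameterError("practice_gain >= 0 and retention in [0, 1] required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        pop = d.pop("population", None)
        cfg = cls(**d) if pop is None else cls(population=PopulationSpec(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in pop.items()
        }), **d)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha1(payload.encode()).hexdigest()[:10]


# Baseline (T0) assessment-trajectory parameters for each drawing task.
_T0_TASK_PARAMS = {
    "line": dict(duration_s=1.6, n_submovements=3, deviation_amp_cm=1.6, noise_sd_cm=0.12),
    "circle": dict(duration_s=3.2, n_submovements=5, deviation_amp_cm=1.8, noise_sd_cm=0.12),
}

_LINE = LineShape(p0=(0.0, 1.2, 0.4), p1=(0.35, 1.45, 0.55))
_CIRCLE = CircleShape(c=(0.1, 1.3, 0.5), r=0.12, n=(0.0, 0.0, 1.0))


def _assessment_spec(task: str, improvement: float, seed: int) -> TrajectoryGenSpec:
    """Trajectory recipe after a given fractional improvement in [0, 1)."""
    p = _T0_TASK_PARAMS[task]
    shape = _LINE if task == "line" else _CIRCLE
    shrink = max(0.0, 1.0 - improvement)
    return TrajectoryGenSpec(
        shape=shape,
        duration_s=p["duration_s"] * max(shrink, 0.3),
        n_submovements=max(1, int(round(p["n_submovements"] * shrink))),
        deviation_amp_cm=p["deviation_amp_cm"] * shrink,
        noise_sd_cm=p["noise_sd_cm"],
        seed=seed,
    )


def run_full_experiment(config: RunConfig, out_dir) -> dict:
    """Simulate, assess, score and analyse a full cohort; write all artefacts.

    Returns the summary report (also written to ``report.json``), which
    includes the feasibility analytics ``time_to_band`` and
    ``band_occupancy`` alongside the per-outcome statistics.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"{config.config_hash()}_s{config.seed}"
    master = np.random.SeedSequence(config.seed)
    pop_rng = np.random.default_rng(master.spawn(1)[0])
    learners = sample_population(config.n_participants, pop_rng, config.population)

    n_blocks = config.n_days * config.blocks_per_day
    sessions = []
    session_dir = out / f"sessions_{tag}"
    session_dir.mkdir(exist_ok=True)
    improvements: List[float] = []
    for i, learner in enumerate(learners):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1000 + i]))
        session = run_regulated_session(
            learner, n_blocks, rng=rng, learner_id=f"P{i + 1:02d}"
        )
        sessions.append(session)
        write_session_log(session, session_dir / f"{session.learner_id}.jsonl")
        start, end = learner.skill(0), learner.skill(n_blocks)
        denom = learner.asymptote_skill - start
        improvements.append((end - start) / denom if denom > 0 else 0.0)
        logger.info("participant %d: %d blocks simulated", i + 1, n_blocks)

    # T0/T1/T2 assessment trajectories scored by the kinematics engine
    rows = []
    rt_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    for i, session in enumerate(sessions):
        pid = session.learner_id
        rel_gain = improvements[i]
        for tp_idx, (tp, factor) in enumerate(
            (("T0", 0.0), ("T1", 1.0), ("T2", config.retention))
        ):
            improvement = config.practice_gain * rel_gain * factor
            for task_idx, task in enumerate(("line", "circle")):
                spec = _assessment_spec(
                    task,
                    improvement,
                    seed=int(
                        np.random.SeedSequence(
                            [config.seed, 10 + i, tp_idx, task_idx]
                        ).generate_state(1)[0]
                        % (2**31)
                    ),
                )
                traj = generate_trajectory(spec)
                ideal = _LINE if task == "line" else _CIRCLE
                res = analyze_task(
                    traj,
                    ideal,
                    cutoff_hz=config.cutoff_hz,
                    order=config.filter_order,
                    error_floor_cm=config.error_floor_cm,
                    amp_threshold=config.sparc_amp_threshold,
                    max_cutoff_hz=config.sparc_max_cutoff_hz,
                )
                rows.append((pid, tp, f"sat_{task}", res.sat))
                rows.append((pid, tp, f"sparc_{task}", res.sparc))
            # transfer outcome: digital-cube count grows with practice
            bbt = 29.0 + 10.0 * improvement + rt_rng.normal(0.0, 3.0)
            rows.append((pid, tp, "bbt_vr", float(max(0, int(round(bbt))))))
            # negative control: simple reaction time carries no true effect
            rt = max(120.0, rt_rng.normal(398.0, 117.0))
            rows.append((pid, tp, "reaction_time_ms", rt))

    table = pd.DataFrame(
        rows, columns=["participant_id", "time_point", "outcome_name", "value"]
    )
    outcome_path = out / f"outcomes_{tag}.csv"
    write_outcome_table(table, outcome_path)

    stats_report = run_study_analysis(table, alpha=config.alpha)
    feasibility = {
        "time_to_band": time_to_band(sessions),
        "band_occupancy": band_occupancy(
            sessions,
            first_block=12,
            last_block=min(55, n_blocks),
        )
        if n_blocks >= 12
        else None,
        "mean_success_rate": float(
            np.mean([s.success_rates().mean() for s in sessions])
        ),
    }
    block_success_table(sessions).to_csv(out / f"block_success_{tag}.csv", index=False)

    report = {"feasibility": feasibility, "statistics": stats_report}
    (out / f"report_{tag}.json").write_text(json.dumps(report, indent=2, default=float))

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "outputs": {
            "outcomes": outcome_path.name,
            "report": f"report_{tag}.json",
            "sessions": session_dir.name,
            "block_success": f"block_success_{tag}.csv",
        },
    }
    (out / f"manifest_{tag}.json").write_text(json.dumps(manifest, indent=2, default=list))
    return report
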