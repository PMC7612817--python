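"""Synthetic behavioral sessions with the study's structure.

Sessions have a fixed platform angle (the platform is rotated only between
sessions), speakers on a twelve-slot ring, ~10% probe trials that never
occur within the first ten trials of a session, correction trials after
errors on test trials, and single-trial choices drawn from a generative
:class:`~frameloc.models.ModelSpec` agent.

Reaction times are drawn from a log-normal by default; the study reports
reaction times but does not model their generation, so this exists only to
give the reaction-time analysis realistic positive input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import models
from .geometry import (
    ALL_SLOTS,
    TaskCondition,
    TaskVariant,
    correct_response,
    head_from_world,
    load_task_variant,
    world_from_head,
)
from .models import ModelSpec, primary_probability, spec_from_dict, spec_to_dict

__all__ = [
    "TRIAL_COLUMNS",
    "SessionConfig",
    "simulate_session",
    "simulate_experiment",
    "balanced_trials_from_model",
    "draw_simulation_summary",
    "write_trials",
    "read_trials",
    "exclude_for_analysis",
]

TRIAL_COLUMNS = [
    "subject_id", "session_id", "trial_index", "platform_angle",
    "speaker_world", "speaker_head", "trial_type", "response",
    "is_correct", "reaction_time_s",
]

MAX_PROBE_RATE = 0.10
PROBE_FREE_TRIALS = 10  # probes never occur among the first ten trials


@dataclass
class SessionConfig:
    """Configuration of one simulated session (fixed platform angle)."""

    task_variant: str | TaskVariant
    platform_angle: float
    n_trials: int = 100
    probe_rate: float = 0.10
    agent: ModelSpec = field(default_factory=lambda: models.get_preset("world_sim"))
    seed: int | np.random.SeedSequence | None = None
    subject_id: str = "sim"
    session_id: str = "S00"
    max_corrections: int = 5
    omission_rate: float = 0.0
    reaction_time_model: tuple[str, float, float] = ("lognormal", 0.0, 0.4)

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")
        if not (0.0 <= self.probe_rate <= MAX_PROBE_RATE):
            raise ValueError(
                f"probe_rate must lie in [0, {MAX_PROBE_RATE}]; probes were "
                "capped at 10% of trials in any session")
        self.variant = load_task_variant(self.task_variant)


def _draw_reaction_time(rng: np.random.Generator, model: tuple[str, float, float]) -> float:
    kind, a, b = model
    if kind == "lognormal":
        return float(rng.lognormal(mean=a, sigma=b))
    if kind == "constant":
        return float(a)
    raise ValueError(f"unknown reaction time model {kind!r}")


def _condition_for_speaker(variant: TaskVariant, platform: float, trained_angle: float) -> TaskCondition:
    """Task conditions list trained angles in the task's own frame."""
    if variant.frame == "world":
        return TaskCondition(platform_angle=platform, speaker_world=trained_angle)
    world = world_from_head(trained_angle, platform)
    return TaskCondition(platform_angle=platform, speaker_world=world)


def _agent_probability_table(agent: ModelSpec, variant: TaskVariant) -> dict[tuple[float, float], float]:
    """Primary-response probability for every grid condition (cached per session)."""
    heads = np.repeat(ALL_SLOTS, len(ALL_SLOTS))
    worlds = np.tile(ALL_SLOTS, len(ALL_SLOTS))
    p = primary_probability(agent, heads, worlds, variant.layout)
    p = np.atleast_1d(p)
    return {(float(h), float(w)): float(pi) for h, w, pi in zip(heads, worlds, p)}


def simulate_session(config: SessionConfig) -> pd.DataFrame:
    """Simulate one session; returns a tidy trial table.

    ``n_trials`` counts scheduled (non-correction) trials; correction trials
    are appended after errors on test trials, repeating the same condition
    until the agent answers correctly or ``max_corrections`` is reached.
    Probe trials are always rewarded and never followed by corrections.
    """
    rng = np.random.default_rng(config.seed)
    variant = config.variant
    platform = float(np.round(config.platform_angle, 6))
    prob = _agent_probability_table(config.agent, variant)

    rows: list[dict] = []
    n_probes = 0
    position = 0  # 1-based index of the next emitted trial

    def emit(condition: TaskCondition, trial_type: str) -> dict:
        nonlocal position
        position += 1
        p_primary = prob[(condition.speaker_head, condition.speaker_world)]
        if config.omission_rate > 0 and rng.random() < config.omission_rate:
            response = "none"
            correct = False
        else:
            response = (variant.primary_response if rng.random() < p_primary
                        else variant.secondary_response)
            rewarded = correct_response(condition, variant)
            correct = (rewarded == "probe") or (response == rewarded)
        row = {
            "subject_id": config.subject_id,
            "session_id": config.session_id,
            "trial_index": position,
            "platform_angle": condition.platform_angle,
            "speaker_world": condition.speaker_world,
            "speaker_head": condition.speaker_head,
            "trial_type": trial_type,
            "response": response,
            "is_correct": bool(correct),
            "reaction_time_s": _draw_reaction_time(rng, config.reaction_time_model),
        }
        rows.append(row)
        return row

    # probe speakers are the untrained angles in the task-relevant frame
    probe_pool = variant.probe_angles

    for _ in range(config.n_trials):
        upcoming = position + 1
        allow_probe = (upcoming > PROBE_FREE_TRIALS
                       and (n_probes + 1) <= int(config.probe_rate * upcoming))
        if allow_probe and rng.random() < config.probe_rate:
            n_probes += 1
            angle = float(rng.choice(probe_pool))
            if variant.frame == "world":
                condition = TaskCondition(platform_angle=platform, speaker_world=angle)
            else:
                condition = TaskCondition(platform_angle=platform,
                                          speaker_world=world_from_head(angle, platform))
            emit(condition, "probe")
            continue
        trained_angle = float(rng.choice(variant.trained_angles))
        condition = _condition_for_speaker(variant, platform, trained_angle)
        row = emit(condition, "test")
        n_corr = 0
        while (not row["is_correct"] and row["response"] != "none"
               and n_corr < config.max_corrections):
            row = emit(condition, "correction")
            n_corr += 1

    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def simulate_experiment(plan: dict[float, int] | None, agent: ModelSpec,
                        seed: int | np.random.SeedSequence,
                        task_variant: str | TaskVariant = "world_NS",
                        subject_id: str = "sim",
                        sessions_per_angle: int = 1, **session_kwargs) -> pd.DataFrame:
    """Concatenate sessions across platform angles.

    ``plan`` maps platform angle to the number of scheduled trials at that
    angle (default: 100 trials at each of the twelve angles), split over
    ``sessions_per_angle`` sessions (the platform is rotated only between
    sessions, so testing an angle repeatedly means separate sessions).
    Per-session seeds are spawned deterministically from the master seed,
    so individual sessions are independently reproducible.
    """
    if plan is None:
        plan = {angle: 100 for angle in ALL_SLOTS}
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = master.spawn(len(plan) * sessions_per_angle)
    tables = []
    i = 0
    for angle, n_trials in sorted(plan.items()):
        per_session = _split_evenly(n_trials, sessions_per_angle)
        for n_sess in per_session:
            config = SessionConfig(
                task_variant=task_variant,
                platform_angle=angle,
                n_trials=n_sess,
                agent=agent,
                seed=children[i],
                subject_id=subject_id,
                session_id=f"S{i:02d}",
                **session_kwargs,
            )
            tables.append(simulate_session(config))
            i += 1
    return pd.concat(tables, ignore_index=True)


def _split_evenly(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if j < extra else 0) for j in range(parts)]


def balanced_trials_from_model(spec: ModelSpec, variant: str | TaskVariant,
                               n_per_cell: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw ``n_per_cell`` single-trial responses for every grid condition.

    A condition-balanced table without session structure, useful for
    statistics whose input is a trial table but whose behavior under a known
    generating model is the question (e.g. permutation-test calibration).
    """
    variant = load_task_variant(variant)
    n_cells = len(ALL_SLOTS) ** 2
    heads = np.repeat(np.repeat(ALL_SLOTS, len(ALL_SLOTS)), n_per_cell)
    worlds = np.repeat(np.tile(ALL_SLOTS, len(ALL_SLOTS)), n_per_cell)
    p = np.repeat(np.atleast_1d(
        primary_probability(spec, heads[::n_per_cell], worlds[::n_per_cell], variant.layout)),
        n_per_cell)
    primary = rng.random(n_cells * n_per_cell) < p
    response = np.where(primary, variant.primary_response, variant.secondary_response)
    trained = set(variant.trained)
    frame_angle = worlds if variant.frame == "world" else heads
    is_test = np.isin(frame_angle, list(trained))
    df = pd.DataFrame({
        "subject_id": "sim",
        "session_id": "balanced",
        "trial_index": np.arange(1, n_cells * n_per_cell + 1) + PROBE_FREE_TRIALS,
        "platform_angle": [float(a) for a in map(_wrap_round, worlds - heads)],
        "speaker_world": worlds,
        "speaker_head": heads,
        "trial_type": np.where(is_test, "test", "probe"),
        "response": response,
        "is_correct": True,  # not meaningful for balanced draws
        "reaction_time_s": 1.0,
    })
    return df[TRIAL_COLUMNS]


def _wrap_round(a: float) -> float:
    from .geometry import wrap_angle
    return float(wrap_angle(a))


def draw_simulation_summary(spec: ModelSpec, n_draws: int = 1000,
                            task_variant: str | TaskVariant = "world_NS",
                            seed: int | np.random.SeedSequence | None = None,
                            conditions: list[TaskCondition] | None = None) -> pd.DataFrame:
    """Multinomial response counts per condition and implied percent correct.

    For each condition, ``n_draws`` single-trial responses are drawn from the
    model's choice distribution; correctness follows the task's reward rules
    (probe conditions have no defined correct response and get NaN).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    variant = load_task_variant(task_variant)
    rng = np.random.default_rng(seed)
    if conditions is None:
        from .geometry import condition_grid
        conditions = condition_grid()
    records = []
    for cond in conditions:
        p = primary_probability(spec, cond.speaker_head, cond.speaker_world, variant.layout)
        n_primary = int(rng.binomial(n_draws, float(p)))
        rewarded = correct_response(cond, variant)
        if rewarded == "probe":
            pct = np.nan
        else:
            n_correct = n_primary if rewarded == variant.primary_response else n_draws - n_primary
            pct = 100.0 * n_correct / n_draws
        records.append({
            "platform_angle": cond.platform_angle,
            "speaker_world": cond.speaker_world,
            "speaker_head": cond.speaker_head,
            "rewarded_response": rewarded,
            "n_draws": n_draws,
            "n_primary": n_primary,
            "n_secondary": n_draws - n_primary,
            "p_primary_model": float(p),
            "percent_correct": pct,
        })
    return pd.DataFrame.from_records(records)


# --- Trial table I/O ----------------------------------------------------

def write_trials(trials: pd.DataFrame, path: str | Path,
                 generating_spec: ModelSpec | None = None) -> None:
    """Write a trial table as CSV; optionally write a JSON sidecar with the
    generating model parameters (ground truth for recovery tests)."""
    path = Path(path)
    trials.to_csv(path, index=False)
    if generating_spec is not None:
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(spec_to_dict(generating_spec), indent=2))


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`."""
    df = pd.read_csv(Path(path))
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    df["is_correct"] = df["is_correct"].astype(bool)
    return df[TRIAL_COLUMNS]


def read_generating_spec(path: str | Path) -> ModelSpec:
    """Read the JSON sidecar written next to a trial table."""
    return spec_from_dict(json.loads(Path(path).read_text()))


def exclude_for_analysis(trials: pd.DataFrame, *, keep_probes: bool = True) -> pd.DataFrame:
    """Drop correction trials and no-response trials (and optionally probes)."""
    keep = (trials["trial_type"] != "correction") & (trials["response"] != "none")
    if not keep_probes:
        keep &= trials["trial_type"] != "probe"
    return trials.loc[keep].reset_index(drop=True)
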