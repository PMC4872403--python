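"""The 25-module training registry, trial generation and session scheduling.

The program comprises 25 exercises: eight attended-signal, eight
explicit-distractor and eight implicit-distractor modules (four visual and
four auditory each, climbing a four-tier stimulus-complexity ladder), plus a
single visual go/no-go response-inhibition exercise.  Sessions present up to
seven exercises of 3-5 minutes within a 30-minute slot, and complex-stimulus
exercises are unveiled only after the simpler exercise in the same
(category, modality) chain has been completed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from .staircase import CATEGORIES, ChallengeMapping, StaircaseState, challenge_to_stimulus

logger = logging.getLogger(__name__)

__all__ = [
    "VISUAL_LADDER",
    "AUDITORY_LADDER",
    "SESSION_MINUTES",
    "MAX_EXERCISES_PER_SESSION",
    "TRIALS_PER_BLOCK",
    "EXERCISE_COMPLETE_MINUTES",
    "FULL_DOSE_HOURS",
    "FULL_DOSE_SESSIONS",
    "ExerciseSpec",
    "TrainingTrial",
    "build_registry",
    "registry_to_json",
    "generate_trial",
    "generate_block",
    "schedule_session",
    "SessionRecord",
    "CurriculumSummary",
    "accumulate_curriculum",
    "engagement_rank",
]

VISUAL_LADDER = ("gabor", "shapes_textures", "motion", "scenes")
AUDITORY_LADDER = ("tones", "sweeps", "phonemes", "words")

SESSION_MINUTES = 30
MAX_EXERCISES_PER_SESSION = 7
#: Per-exercise block durations are drawn from {3, 4, 5} minutes.
BLOCK_MINUTES_CHOICES = (3, 4, 5)
#: Trials presented per 3-5 min exercise block.
TRIALS_PER_BLOCK = 40
#: Minutes of training after which an exercise counts as completed and
#: unlocks the next tier in its chain.
EXERCISE_COMPLETE_MINUTES = 60
FULL_DOSE_HOURS = 30.0
FULL_DOSE_SESSIONS = 60

#: Engagement ranks of the meta-game wrapper, indexed by sessions completed.
RANKS = ("cadet", "ensign", "lieutenant", "commander")


@dataclass(frozen=True)
class ExerciseSpec:
    """One of the 25 training modules."""

    id: str
    category: str
    modality: str
    tier: int
    ladder_label: str
    duration_minutes: float = 4.0
    response_format: str = "two_afc_yes_no"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.modality not in ("visual", "auditory"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if not 1 <= self.tier <= 4:
            raise ValueError("tier must be in 1..4")
        if not 3.0 <= self.duration_minutes <= 5.0:
            raise ValueError("duration_minutes must be in [3, 5]")
        if self.response_format not in ("two_afc_yes_no", "go_no_go"):
            raise ValueError(f"unknown response_format {self.response_format!r}")

    @property
    def distractor_kind(self) -> str:
        return {
            "attended_signal": "none",
            "explicit_distractor": "explicit",
            "implicit_distractor": "implicit",
            "response_inhibition": "none",
        }[self.category]


@dataclass(frozen=True)
class TrainingTrial:
    """One presented trial of one exercise.

    ``response``/``correct`` are filled in once an observer answers.
    A false positive is an affirmative response on a trial without a target,
    i.e. a distractor-related error.
    """

    exercise_id: str
    challenge: float
    target_present: bool
    distractor_kind: str
    stimulus_params: Mapping[str, float]
    response: str | None = None
    correct: bool | None = None
    is_false_positive: bool = False

    def __post_init__(self) -> None:
        if self.is_false_positive and (
            self.target_present or self.response not in ("yes", "go")
        ):
            raise ValueError(
                "is_false_positive requires target absent and an affirmative response"
            )


_CAT_ABBREV = {
    "attended_signal": "as",
    "explicit_distractor": "ed",
    "implicit_distractor": "id",
    "response_inhibition": "ri",
}


def build_registry(config: Mapping | None = None) -> list[ExerciseSpec]:
    """Build the canonical 25-exercise registry.

    Deterministic and idempotent.  The 24 two-alternative forced-choice
    exercises are 3 categories x 2 modalities x 4 complexity tiers; the 25th
    is the single visual go/no-go response-inhibition exercise (complex-scene
    content; tier 1 because it heads its own single-exercise chain and is
    available from the first session).  Any config attempting to override the
    counts is rejected.
    """
    if config:
        forbidden = {"n_modules", "per_category", "per_modality"} & set(config)
        if forbidden:
            raise ValueError(
                f"registry counts are fixed by design; cannot override {sorted(forbidden)}"
            )
    specs: list[ExerciseSpec] = []
    for category in ("attended_signal", "explicit_distractor", "implicit_distractor"):
        for modality, ladder in (("visual", VISUAL_LADDER), ("auditory", AUDITORY_LADDER)):
            for tier, label in enumerate(ladder, start=1):
                specs.append(
                    ExerciseSpec(
                        id=f"{_CAT_ABBREV[category]}_{modality[:3]}_t{tier}_{label}",
                        category=category,
                        modality=modality,
                        tier=tier,
                        ladder_label=label,
                    )
                )
    specs.append(
        ExerciseSpec(
            id="ri_vis_t1_scenes_gonogo",
            category="response_inhibition",
            modality="visual",
            tier=1,
            ladder_label="scenes",
            response_format="go_no_go",
        )
    )
    assert len(specs) == 25
    return specs


def registry_to_json(registry: Sequence[ExerciseSpec]) -> str:
    return json.dumps([asdict(s) for s in registry], indent=2)


def generate_trial(
    spec: ExerciseSpec,
    state: StaircaseState,
    rng: np.random.Generator,
    *,
    target_present: bool | None = None,
    target_prevalence: float = 0.5,
) -> TrainingTrial:
    """Emit one trial at the staircase's current challenge.

    Stimulus parameters come from the exercise category's challenge mapping.
    For 2AFC exercises target presence defaults to a fair Bernoulli draw
    (use :func:`generate_block` for exactly balanced blocks); the go/no-go
    exercise emits withhold-targets vs go-distractors at the same prevalence.
    """
    if target_present is None:
        target_present = bool(rng.random() < target_prevalence)
    mapping = ChallengeMapping(category=spec.category)
    params = {mapping.stimulus_axis: challenge_to_stimulus(mapping, state.challenge)}
    return TrainingTrial(
        exercise_id=spec.id,
        challenge=state.challenge,
        target_present=target_present,
        distractor_kind=spec.distractor_kind,
        stimulus_params=params,
    )


def generate_block(
    spec: ExerciseSpec,
    state: StaircaseState,
    rng: np.random.Generator,
    n_trials: int = TRIALS_PER_BLOCK,
    *,
    target_prevalence: float = 0.5,
) -> list[TrainingTrial]:
    """Generate a stratified block: target counts exactly match prevalence.

    ``round(n_trials * target_prevalence)`` trials carry a target; order is
    shuffled.  At the default 50 % prevalence an even-length block is exactly
    balanced.
    """
    n_targets = int(round(n_trials * target_prevalence))
    flags = np.zeros(n_trials, dtype=bool)
    flags[:n_targets] = True
    rng.shuffle(flags)
    return [
        generate_trial(spec, state, rng, target_present=bool(f)) for f in flags
    ]


def is_unveiled(
    spec: ExerciseSpec,
    registry: Sequence[ExerciseSpec],
    minutes_trained: Mapping[str, float],
    *,
    complete_minutes: float = EXERCISE_COMPLETE_MINUTES,
) -> bool:
    """Unveiling predicate: tier k needs the same-chain tier k-1 completed."""
    if spec.tier == 1:
        return True
    prev = [
        s
        for s in registry
        if s.category == spec.category
        and s.modality == spec.modality
        and s.tier == spec.tier - 1
    ]
    return all(minutes_trained.get(p.id, 0.0) >= complete_minutes for p in prev)


def schedule_session(
    progress: Mapping[str, float],
    registry: Sequence[ExerciseSpec] | None = None,
    rng: np.random.Generator | None = None,
    *,
    session_minutes: float = SESSION_MINUTES,
    max_exercises: int = MAX_EXERCISES_PER_SESSION,
    complete_minutes: float = EXERCISE_COMPLETE_MINUTES,
) -> list[tuple[ExerciseSpec, int]]:
    """Pick the exercises (with block durations) for one 30-minute session.

    ``progress`` maps exercise id to minutes trained so far and must cover
    the registry.  Only unveiled exercises are schedulable; the least-trained
    ones go first (ties broken by exercise id); block durations are drawn
    from {3, 4, 5} minutes subject to the session cap.  Returns a list of
    ``(spec, minutes)`` pairs, empty (with a diagnostic) if nothing is
    available.
    """
    if registry is None:
        registry = build_registry()
    missing = {s.id for s in registry} - set(progress)
    if missing:
        raise ValueError(f"progress map missing exercises: {sorted(missing)[:3]}...")
    if rng is None:
        rng = np.random.default_rng()

    available = [
        s
        for s in registry
        if is_unveiled(s, registry, progress, complete_minutes=complete_minutes)
    ]
    if not available:
        logger.warning("no exercises available to schedule; empty session")
        return []
    available.sort(key=lambda s: (progress[s.id], s.id))

    session: list[tuple[ExerciseSpec, int]] = []
    total = 0.0
    for spec in available:
        if len(session) >= max_exercises:
            break
        minutes = int(rng.choice(BLOCK_MINUTES_CHOICES))
        if total + minutes > session_minutes:
            minutes_fit = int(session_minutes - total)
            if minutes_fit < min(BLOCK_MINUTES_CHOICES):
                break
            minutes = minutes_fit
        session.append((spec, minutes))
        total += minutes
    return session


@dataclass(frozen=True)
class SessionRecord:
    """Bookkeeping for one completed 30-minute session."""

    subject_id: str
    session_index: int
    start_hours: float  # hours since intervention start on the study calendar
    minutes: float = float(SESSION_MINUTES)

    @property
    def end_hours(self) -> float:
        return self.start_hours + self.minutes / 60.0


@dataclass(frozen=True)
class CurriculumSummary:
    total_hours: float
    n_sessions: int
    weeks_spanned: float
    completed: bool


def accumulate_curriculum(
    sessions: Iterable[SessionRecord],
    *,
    full_dose_hours: float = FULL_DOSE_HOURS,
) -> CurriculumSummary:
    """Summarize a subject's session stream into compliance bookkeeping.

    Raises on overlapping session intervals.  ``completed`` flags the full
    30-hour dose.
    """
    records = sorted(sessions, key=lambda s: s.start_hours)
    for a, b in zip(records, records[1:]):
        if b.start_hours < a.end_hours - 1e-9:
            raise ValueError(
                f"overlapping sessions for {a.subject_id}: "
                f"session {a.session_index} ends at {a.end_hours:.2f} h but "
                f"session {b.session_index} starts at {b.start_hours:.2f} h"
            )
    total_hours = sum(s.minutes for s in records) / 60.0
    weeks = (
        (records[-1].end_hours - records[0].start_hours) / (24.0 * 7.0)
        if records
        else 0.0
    )
    return CurriculumSummary(
        total_hours=total_hours,
        n_sessions=len(records),
        weeks_spanned=weeks,
        completed=total_hours >= full_dose_hours,
    )


def engagement_rank(n_sessions: int) -> str:
    """Meta-game rank from sessions completed (cosmetic engagement counter)."""
    idx = min(len(RANKS) - 1, n_sessions * len(RANKS) // FULL_DOSE_SESSIONS)
    return RANKS[idx]
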