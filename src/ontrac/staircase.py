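"""Performance-adaptive staircase control of exercise difficulty.

Each training exercise adjusts its challenge level with a 3-down-1-up
transformed up-down staircase: three consecutive correct responses raise the
challenge by one step, any error lowers it immediately, and every reversal of
direction halves the step size down to a floor.  This rule converges on the
stimulus level at which the probability of a correct response is
``0.5 ** (1/3) ~= 0.794``, holding moment-to-moment performance inside the
75-85 % band that keeps an exercise challenging but not frustrating.

Challenge is represented on a normalized [0, 1] axis (0 = easiest,
1 = hardest) and mapped onto the physical stimulus axis of each exercise
category by :func:`challenge_to_stimulus`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_TARGET_BAND",
    "DEFAULT_INITIAL_CHALLENGE",
    "DEFAULT_INITIAL_STEP",
    "DEFAULT_STEP_FLOOR",
    "THREE_DOWN_ONE_UP_P",
    "StaircaseState",
    "ChallengeMapping",
    "LogisticObserver",
    "update_core",
    "update_staircase",
    "simulate_staircase",
    "StaircaseRun",
    "challenge_to_stimulus",
    "reversals_from_history",
    "trajectory_frame",
]

#: Performance band the adaptive controller is designed to hold.
DEFAULT_TARGET_BAND: tuple[float, float] = (0.75, 0.85)
#: Easy starting point so difficulty builds up progressively.
DEFAULT_INITIAL_CHALLENGE: float = 0.1
#: Initial step on the unit challenge axis; halved at each reversal.
DEFAULT_INITIAL_STEP: float = 0.08
#: Smallest allowed step size.
DEFAULT_STEP_FLOOR: float = 0.01
#: Theoretical convergence point of the 3-down-1-up rule: P(3 correct) = 0.5.
THREE_DOWN_ONE_UP_P: float = 0.5 ** (1.0 / 3.0)  # ~0.7937

Direction = Literal["up", "down", "none"]

CATEGORIES = (
    "attended_signal",
    "explicit_distractor",
    "implicit_distractor",
    "response_inhibition",
)


@dataclass(frozen=True)
class StaircaseState:
    """Full state of one 3-down-1-up staircase.

    ``history`` records ``(challenge_at_presentation, correct)`` for every
    trial, so reversal counts are recoverable by replay
    (:func:`reversals_from_history`).
    """

    challenge: float = DEFAULT_INITIAL_CHALLENGE
    step: float = DEFAULT_INITIAL_STEP
    n_consecutive_correct: int = 0
    n_reversals: int = 0
    last_direction: Direction = "none"
    history: tuple[tuple[float, bool], ...] = field(default_factory=tuple)
    target_band: tuple[float, float] = DEFAULT_TARGET_BAND
    step_floor: float = DEFAULT_STEP_FLOOR

    def __post_init__(self) -> None:
        if not (0.0 <= self.challenge <= 1.0):
            raise ValueError(f"challenge {self.challenge!r} outside [0, 1]")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.step_floor <= 0:
            raise ValueError("step floor must be positive")
        if self.n_consecutive_correct < 0 or self.n_reversals < 0:
            raise ValueError("counters must be non-negative")


@dataclass(frozen=True)
class ChallengeMapping:
    """Sign convention linking the unit challenge axis to a stimulus axis.

    * attended_signal: harder means a *less* salient target.
    * explicit/implicit_distractor: harder means distractors *more* similar
      to the target.
    * response_inhibition: harder means *faster* interstimulus times.
    """

    category: str
    isi_range_s: tuple[float, float] = (0.5, 3.0)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        lo, hi = self.isi_range_s
        if not (0 < lo < hi):
            raise ValueError("isi_range_s must satisfy 0 < min < max")

    @property
    def stimulus_axis(self) -> str:
        return {
            "attended_signal": "target_salience",
            "explicit_distractor": "distractor_similarity",
            "implicit_distractor": "distractor_similarity",
            "response_inhibition": "interstimulus_time",
        }[self.category]

    @property
    def direction(self) -> int:
        """+1 if the stimulus parameter increases with challenge, else -1."""
        return 1 if self.stimulus_axis == "distractor_similarity" else -1


def challenge_to_stimulus(mapping: ChallengeMapping, challenge: float) -> float:
    """Map a unit-axis challenge onto the exercise's stimulus parameter.

    Salience and similarity come back in [0, 1]; interstimulus time in the
    mapping's configured seconds range, decreasing as challenge rises.
    """
    if not (0.0 <= challenge <= 1.0):
        raise ValueError(f"challenge {challenge!r} outside [0, 1]")
    axis = mapping.stimulus_axis
    if axis == "target_salience":
        return 1.0 - challenge
    if axis == "distractor_similarity":
        return challenge
    lo, hi = mapping.isi_range_s
    return hi - challenge * (hi - lo)


def update_core(
    challenge: float,
    step: float,
    n_consecutive_correct: int,
    n_reversals: int,
    last_direction: Direction,
    correct: bool,
    step_floor: float = DEFAULT_STEP_FLOOR,
) -> tuple[float, float, int, int, Direction]:
    """Pure 3-down-1-up update on plain scalars (the engine's inner loop).

    Returns ``(challenge, step, n_consecutive_correct, n_reversals,
    last_direction)``.  :func:`update_staircase` is the dataclass wrapper.
    """
    if correct:
        n_consecutive_correct += 1
        if n_consecutive_correct < 3:
            return challenge, step, n_consecutive_correct, n_reversals, last_direction
        move: Direction = "up"
        n_consecutive_correct = 0
    else:
        move = "down"
        n_consecutive_correct = 0

    if last_direction != "none" and move != last_direction:
        n_reversals += 1
        step = max(step / 2.0, step_floor)

    challenge += step if move == "up" else -step
    challenge = min(1.0, max(0.0, challenge))
    return challenge, step, n_consecutive_correct, n_reversals, move


def update_staircase(state: StaircaseState, correct: bool) -> StaircaseState:
    """Apply one trial outcome under the 3-down-1-up rule.

    Any error steps the challenge down immediately; the third consecutive
    correct response steps it up and resets the counter.  A change of stepping
    direction counts as a reversal and halves the step (not below the floor).
    The updated challenge is silently clamped to [0, 1].
    """
    history = state.history + ((state.challenge, bool(correct)),)
    challenge, step, n_correct, n_reversals, direction = update_core(
        state.challenge,
        state.step,
        state.n_consecutive_correct,
        state.n_reversals,
        state.last_direction,
        bool(correct),
        state.step_floor,
    )
    if challenge in (0.0, 1.0) and challenge != state.challenge:
        logger.debug("challenge clamped/at boundary (%.3f)", challenge)
    return replace(
        state,
        challenge=challenge,
        step=step,
        n_consecutive_correct=n_correct,
        n_reversals=n_reversals,
        last_direction=direction,
        history=history,
    )


def reversals_from_history(
    history: Sequence[tuple[float, bool]],
    *,
    initial: StaircaseState | None = None,
) -> int:
    """Recover the reversal count by replaying the update rule over history."""
    if initial is None:
        initial = StaircaseState()
    state = replace(initial, history=())
    for _, correct in history:
        state = update_staircase(state, correct)
    return state.n_reversals


@dataclass(frozen=True)
class LogisticObserver:
    """Psychophysical observer: P(correct | challenge) on the unit axis.

    ``P = guess + (1 - guess - lapse) * sigmoid(slope * (threshold - c))`` —
    a logistic psychometric function, decreasing in challenge, with a 2AFC
    guess floor and a lapse-limited ceiling.
    """

    threshold: float = 0.5
    slope: float = 8.0
    lapse: float = 0.02
    guess: float = 0.5

    def __call__(self, challenge: float) -> float:
        core = 1.0 / (1.0 + math.exp(-self.slope * (self.threshold - challenge)))
        return self.guess + (1.0 - self.guess - self.lapse) * core

    def quantile(self, p: float) -> float:
        """Challenge at which P(correct) equals ``p`` (inverse function)."""
        core = (p - self.guess) / (1.0 - self.guess - self.lapse)
        if not (0.0 < core < 1.0):
            raise ValueError(f"p={p} not attainable by this observer")
        return self.threshold - math.log(core / (1.0 - core)) / self.slope


@dataclass(frozen=True)
class StaircaseRun:
    """Trajectory and steady-state summary of a simulated staircase."""

    states: tuple[StaircaseState, ...]
    correct: np.ndarray
    challenges: np.ndarray
    burn_in: int
    steady_state_accuracy: float
    mean_converged_challenge: float


def _check_monotone(observer: Callable[[float], float]) -> None:
    grid = np.linspace(0.0, 1.0, 21)
    probs = np.array([observer(c) for c in grid])
    increases = np.diff(probs)
    if np.any(increases > 1e-9) and probs[-1] > probs[0]:
        raise ValueError(
            "observer has P(correct) increasing in challenge; the staircase "
            "assumes a non-increasing psychometric function "
            f"(P(0)={probs[0]:.3f}, P(1)={probs[-1]:.3f})"
        )


def simulate_staircase(
    observer: Callable[[float], float],
    n_trials: int,
    seed: int | np.random.Generator,
    *,
    initial: StaircaseState | None = None,
    burn_in_trials: int = 200,
    burn_in_reversals: int = 6,
) -> StaircaseRun:
    """Run a staircase against a stochastic observer and summarize it.

    The steady-state window starts after ``burn_in_trials`` trials or after
    the trial of the ``burn_in_reversals``-th reversal, whichever is later.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    _check_monotone(observer)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    state = initial if initial is not None else StaircaseState()
    uniforms = rng.random(n_trials)
    states: list[StaircaseState] = []
    correct = np.empty(n_trials, dtype=bool)
    challenges = np.empty(n_trials, dtype=float)
    reversal_trial: dict[int, int] = {}
    for t in range(n_trials):
        challenges[t] = state.challenge
        correct[t] = uniforms[t] < observer(state.challenge)
        new_state = update_staircase(state, bool(correct[t]))
        if new_state.n_reversals > state.n_reversals:
            reversal_trial.setdefault(new_state.n_reversals, t)
        state = new_state
        states.append(state)

    burn_in = min(burn_in_trials, n_trials)
    if burn_in_reversals in reversal_trial:
        burn_in = max(burn_in, min(reversal_trial[burn_in_reversals] + 1, n_trials))
    elif state.n_reversals < burn_in_reversals:
        logger.warning(
            "only %d reversals in %d trials; burn-in fixed at %d trials",
            state.n_reversals,
            n_trials,
            burn_in,
        )
    if burn_in >= n_trials:
        burn_in = max(0, n_trials - 1)

    steady_acc = float(np.mean(correct[burn_in:]))
    mean_challenge = float(np.mean(challenges[burn_in:]))
    return StaircaseRun(
        states=tuple(states),
        correct=correct,
        challenges=challenges,
        burn_in=burn_in,
        steady_state_accuracy=steady_acc,
        mean_converged_challenge=mean_challenge,
    )


def trajectory_frame(run: StaircaseRun):
    """Staircase trajectory as a DataFrame (CSV-serializable)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "trial_index": np.arange(len(run.correct)),
            "challenge": run.challenges,
            "correct": run.correct.astype(int),
            "step": [s.step for s in run.states],
            "reversals": [s.n_reversals for s in run.states],
        }
    )
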