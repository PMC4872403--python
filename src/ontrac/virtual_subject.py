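"""Virtual ADHD subjects: psychometric observers, learning, symptom model.

Each simulated child carries three latent abilities on the unit challenge
axis — ``signal_sensitivity`` (attended-signal detection),
``distractor_suppression`` (resistance to target-like distractors) and
``inhibition`` (withholding prepotent responses).  Responses to training
trials follow a logistic psychometric function of (trait - challenge);
training increases the exercised trait with saturating returns; and the
parent-rated symptom total is generated as a noisy, monotone-decreasing
function of the distractor-suppression trait.  That last choice encodes the
program's mechanistic hypothesis — improved suppression of distraction
drives improvement in ADHD symptoms — as an explicit generative assumption,
so the downstream analysis pipeline can be validated against a cohort whose
ground truth is known.

Defaults describe the emulated study population: n = 31 children aged
12 +/- 1.9 years, ~48 % on stimulant medication, a 2:1 allocation ratio, and
roughly half of the trained arm complying only partially (1-13 hours).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .battery import TrainingTrial

logger = logging.getLogger(__name__)

__all__ = [
    "TRAIT_NAMES",
    "CATEGORY_TRAIT",
    "ADHD_RS_MAX",
    "VirtualSubject",
    "CohortConfig",
    "p_correct",
    "respond",
    "apply_learning",
    "emit_symptom_rating",
    "generate_cohort",
    "cohort_frame",
]

TRAIT_NAMES = ("signal_sensitivity", "distractor_suppression", "inhibition")

#: Which latent trait each exercise category exercises.
CATEGORY_TRAIT: Mapping[str, str] = {
    "attended_signal": "signal_sensitivity",
    "explicit_distractor": "distractor_suppression",
    "implicit_distractor": "distractor_suppression",
    "response_inhibition": "inhibition",
}

#: ADHD rating scale total: 18 items scored 0-3.
ADHD_RS_MAX = 54

#: Logistic psychometric scale on the unit challenge axis (slope 8, i.e.
#: sigma = 0.125), matching the default simulated observer.
PSYCHOMETRIC_SLOPE = 8.0
GUESS_FLOOR_2AFC = 0.5


@dataclass(frozen=True)
class VirtualSubject:
    """Latent parameters of one simulated child."""

    subject_id: str
    age_years: float
    medication: bool
    traits: Mapping[str, float]
    lapse_rate: float = 0.02
    learning_rates: Mapping[str, float] = field(
        default_factory=lambda: {t: 6e-4 for t in TRAIT_NAMES}
    )
    symptom_intercept: float = 38.0
    symptom_noise_sd: float = 2.5
    coupling_strength: float = 30.0
    compliance_propensity: float = 0.5

    def __post_init__(self) -> None:
        missing = set(TRAIT_NAMES) - set(self.traits)
        if missing:
            raise ValueError(f"missing traits: {sorted(missing)}")
        for name, v in self.traits.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"trait {name}={v} outside [0, 1]")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must be in [0, 0.1]")
        if any(r < 0 for r in self.learning_rates.values()):
            raise ValueError("learning rates must be >= 0")
        if self.symptom_noise_sd < 0:
            raise ValueError("symptom_noise_sd must be >= 0")
        if not 0.0 <= self.compliance_propensity <= 1.0:
            raise ValueError("compliance_propensity must be in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for a simulated cohort (defaults = study design)."""

    n_subjects: int = 31
    arm_ratio: tuple[int, int] = (2, 1)
    fraction_medicated: float = 15 / 31
    seed: int = 0
    coupling_strength: float = 30.0
    dropout_probability: float = 0.1
    partial_compliance_fraction: float = 10 / 21
    age_mean: float = 12.0
    age_sd: float = 1.9
    age_range: tuple[float, float] = (8.0, 16.0)
    trait_beta: tuple[float, float] = (2.0, 3.0)
    lapse_max: float = 0.05
    learning_rate_median: float = 6e-4
    learning_rate_log_sd: float = 0.9
    control_learning_rate: float = 0.0
    symptom_intercept_mean: float = 38.0
    symptom_intercept_sd: float = 5.0
    symptom_noise_sd: float = 2.5
    partial_hours_range: tuple[float, float] = (1.0, 13.0)

    def validate(self) -> None:
        errors = []
        if self.n_subjects < 2:
            errors.append("n_subjects must be >= 2")
        if min(self.arm_ratio) <= 0:
            errors.append("arm_ratio components must be positive")
        for name in (
            "fraction_medicated",
            "dropout_probability",
            "partial_compliance_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name}={v} outside [0, 1]")
        if self.age_sd <= 0:
            errors.append("age_sd must be positive")
        if not 0 <= self.lapse_max <= 0.1:
            errors.append("lapse_max must be in [0, 0.1]")
        if self.learning_rate_median < 0 or self.control_learning_rate < 0:
            errors.append("learning rates must be >= 0")
        if self.coupling_strength < 0:
            errors.append("coupling_strength must be >= 0")
        lo, hi = self.partial_hours_range
        if not 0 < lo <= hi:
            errors.append("partial_hours_range must satisfy 0 < lo <= hi")
        if errors:
            raise ValueError("invalid cohort config: " + "; ".join(errors))


def p_correct(
    subject: VirtualSubject,
    category: str,
    challenge: float,
    *,
    guess: float = GUESS_FLOOR_2AFC,
    slope: float = PSYCHOMETRIC_SLOPE,
) -> float:
    """Closed-form P(correct) for this subject on a trial of a category.

    ``gamma + (1 - gamma - lambda) * logistic(slope * (trait - challenge))``
    with guess floor gamma and lapse rate lambda; bounded in
    [gamma*(...), 1 - lambda-ish] and strictly decreasing in challenge.
    """
    trait_name = CATEGORY_TRAIT.get(category)
    if trait_name is None:
        raise ValueError(f"no trait mapped for category {category!r}")
    trait = subject.traits[trait_name]
    core = 1.0 / (1.0 + math.exp(-slope * (trait - challenge)))
    return guess + (1.0 - guess - subject.lapse_rate) * core


def respond(
    subject: VirtualSubject,
    trial: TrainingTrial,
    rng: np.random.Generator,
    *,
    category: str | None = None,
) -> TrainingTrial:
    """Answer one training trial; returns the trial with the outcome filled in.

    The response string is derived from correctness and the trial's target
    status: a wrong answer on a no-target trial is an affirmative response to
    a distractor, i.e. a false positive.
    """
    if category is None:
        category = _category_from_id(trial.exercise_id)
    correct = bool(rng.random() < p_correct(subject, category, trial.challenge))
    go_no_go = category == "response_inhibition"
    if trial.target_present:
        # target: "yes" (2AFC) / withhold (go/no-go)
        response = ("withhold" if correct else "go") if go_no_go else (
            "yes" if correct else "no"
        )
        fp = False
    else:
        response = ("go" if correct else "withhold") if go_no_go else (
            "no" if correct else "yes"
        )
        fp = (not correct) and not go_no_go
    return replace(trial, response=response, correct=correct, is_false_positive=fp)


def _category_from_id(exercise_id: str) -> str:
    prefix = exercise_id.split("_", 1)[0]
    table = {
        "as": "attended_signal",
        "ed": "explicit_distractor",
        "id": "implicit_distractor",
        "ri": "response_inhibition",
    }
    if prefix not in table:
        raise ValueError(f"cannot infer category from exercise id {exercise_id!r}")
    return table[prefix]


def apply_learning(
    subject: VirtualSubject,
    trained_minutes: Mapping[str, float] | Iterable[tuple[str, float]],
) -> VirtualSubject:
    """Update traits after training: saturating, minute-driven plasticity.

    ``trained_minutes`` maps exercise category to minutes trained.  Each
    exercised trait moves by ``rate * minutes * (1 - trait)``; a trait at the
    1.0 ceiling no longer changes, and traits stay inside [0, 1] for any
    number of updates.
    """
    if not isinstance(trained_minutes, Mapping):
        acc: dict[str, float] = {}
        for cat, mins in trained_minutes:
            acc[cat] = acc.get(cat, 0.0) + mins
        trained_minutes = acc
    traits = dict(subject.traits)
    for category, minutes in trained_minutes.items():
        trait_name = CATEGORY_TRAIT[category]
        rate = subject.learning_rates.get(trait_name, 0.0)
        t = traits[trait_name]
        traits[trait_name] = min(1.0, max(0.0, t + rate * minutes * (1.0 - t)))
    return replace(subject, traits=traits)


def emit_symptom_rating(
    subject: VirtualSubject,
    timepoint: str,
    rng: np.random.Generator,
) -> int:
    """Parent-rated ADHD symptom total (0-54 scale, higher = more severe).

    ``clamp(intercept - coupling * distractor_suppression + noise, 0, 54)``
    rounded to an integer.  With zero coupling the ratings are independent of
    training (the null-generator mode used for type-I-error validation).
    """
    del timepoint  # ratings depend on current traits, not on calendar time
    raw = (
        subject.symptom_intercept
        - subject.coupling_strength * subject.traits["distractor_suppression"]
        + (rng.normal(0.0, subject.symptom_noise_sd) if subject.symptom_noise_sd else 0.0)
    )
    return int(round(min(float(ADHD_RS_MAX), max(0.0, raw))))


def generate_cohort(config: CohortConfig) -> list[VirtualSubject]:
    """Seeded, reproducible cohort draw.

    Ages are Normal(12, 1.9) truncated to [8, 16] by resampling; the
    medicated count is exactly ``round(fraction * n)``, assigned at random;
    traits are i.i.d. Beta draws; per-trait learning rates are log-normal
    around the configured median, independent across traits so that gains in
    one ability are not mechanically yoked to gains in another.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    lo, hi = config.age_range
    ages = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(config.age_mean, config.age_sd, size=2 * n)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        ages[filled : filled + take] = ok[:take]
        filled += take

    n_med = int(round(config.fraction_medicated * n))
    med = np.zeros(n, dtype=bool)
    med[rng.choice(n, size=n_med, replace=False)] = True

    a, b = config.trait_beta
    subjects = []
    for i in range(n):
        traits = {t: float(rng.beta(a, b)) for t in TRAIT_NAMES}
        rates = {
            t: float(
                config.learning_rate_median
                * math.exp(rng.normal(0.0, config.learning_rate_log_sd))
            )
            for t in TRAIT_NAMES
        }
        subjects.append(
            VirtualSubject(
                subject_id=f"S{i + 1:03d}",
                age_years=float(ages[i]),
                medication=bool(med[i]),
                traits=traits,
                lapse_rate=float(rng.uniform(0.0, config.lapse_max)),
                learning_rates=rates,
                symptom_intercept=float(
                    rng.normal(config.symptom_intercept_mean, config.symptom_intercept_sd)
                ),
                symptom_noise_sd=config.symptom_noise_sd,
                coupling_strength=config.coupling_strength,
                compliance_propensity=float(rng.uniform(0.0, 1.0)),
            )
        )
    return subjects


def cohort_frame(subjects: Sequence[VirtualSubject]) -> pd.DataFrame:
    """Cohort table (one row per subject) for CSV export."""
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "age_years": s.age_years,
            "medication": int(s.medication),
            "lapse_rate": s.lapse_rate,
            "symptom_intercept": s.symptom_intercept,
            "symptom_noise_sd": s.symptom_noise_sd,
            "coupling_strength": s.coupling_strength,
            "compliance_propensity": s.compliance_propensity,
        }
        for t in TRAIT_NAMES:
            row[f"trait_{t}"] = s.traits[t]
            row[f"learning_rate_{t}"] = s.learning_rates[t]
        rows.append(row)
    return pd.DataFrame(rows)
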