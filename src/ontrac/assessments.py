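"""The assessment battery: CPT halves with d', span speed, Stroop, SWAN, CGI.

The cognitive battery mirrors a standard clinic protocol:

* a continuous performance test (CPT) in two 10-minute halves — a
  sustained-attention half with rare targets (22.5 % of trials) and a
  response-inhibition half with frequent targets (77.5 %), both scored with
  the signal-detection sensitivity index d';
* spatial and verbal span tasks (loads {1,3,5,7} and {3,5,7,9}, probes
  matching on exactly 50 % of trials) scored as mean response speed on the
  two highest loads, accuracy being stable across timepoints by design;
* the paper-and-pencil Stroop test (three 100-stimulus sheets, 45 s each)
  scored as correct color-word items minus correct color items, a typically
  negative interference score;
* the SWAN screening cutoffs and the clinician-rated CGI severity scale;
* a fixed-challenge distractor probe embedded in the training program whose
  false-positive count, measured at training start and end, is the
  distractor-suppression outcome correlated with symptom change.

The simulated CPT/probe observers use a saturating (clipped-linear) link in
the latent traits rather than the logistic used during training, so that a
perfect observer genuinely reaches ceiling (all hits, zero false alarms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .virtual_subject import VirtualSubject

logger = logging.getLogger(__name__)

__all__ = [
    "TIMEPOINTS",
    "INSTRUMENTS",
    "INSTRUMENT_TIMEPOINTS",
    "SWAN_CUTOFFS",
    "STROOP_SHEET_SIZE",
    "CPTConfig",
    "CPTResult",
    "SpanConfig",
    "SpanResult",
    "StroopResult",
    "ProbeConfig",
    "ProbeResult",
    "AssessmentRecord",
    "compute_dprime",
    "run_cpt",
    "run_span",
    "score_stroop",
    "simulate_stroop",
    "swan_screen",
    "emit_cgi",
    "embedded_distractor_probe",
    "validate_schedule",
    "records_frame",
]

TIMEPOINTS = ("baseline", "mid", "post", "followup")

INSTRUMENTS = (
    "adhd_rs",
    "cgi",
    "cpt_sustained",
    "cpt_inhibition",
    "span_spatial",
    "span_verbal",
    "stroop",
    "embedded_distractor",
)

#: Clinical scales are measured at all four visits; cognitive tests only at
#: baseline and post; the embedded probe at training start/end (coded as the
#: baseline/post visits of the trained arm).
INSTRUMENT_TIMEPOINTS: Mapping[str, tuple[str, ...]] = {
    "adhd_rs": TIMEPOINTS,
    "cgi": TIMEPOINTS,
    "cpt_sustained": ("baseline", "post"),
    "cpt_inhibition": ("baseline", "post"),
    "span_spatial": ("baseline", "post"),
    "span_verbal": ("baseline", "post"),
    "stroop": ("baseline", "post"),
    "embedded_distractor": ("baseline", "post"),
}

#: Screening cutoffs on mean per-item scores; eligibility is a strict ">".
SWAN_CUTOFFS: Mapping[str, float] = {
    "combined": 2.11,
    "inattentive": 2.48,
    "hyperactive": 2.00,
}

STROOP_SHEET_SIZE = 100

SPAN_LOADS = {"spatial": (1, 3, 5, 7), "verbal": (3, 5, 7, 9)}


@dataclass(frozen=True)
class AssessmentRecord:
    """One subject x timepoint x instrument measurement."""

    subject_id: str
    timepoint: str
    instrument: str
    value: float

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.instrument not in INSTRUMENTS:
            raise ValueError(f"unknown instrument {self.instrument!r}")
        if self.timepoint not in INSTRUMENT_TIMEPOINTS[self.instrument]:
            raise ValueError(
                f"{self.instrument} is not scheduled at {self.timepoint}"
            )
        if self.instrument == "cgi" and not (1 <= self.value <= 7):
            raise ValueError("cgi must be in 1..7")
        if self.instrument == "adhd_rs" and not (0 <= self.value <= 54):
            raise ValueError("adhd_rs must be in [0, 54]")


# --------------------------------------------------------------------------
# d-prime


def compute_dprime(
    hits: int,
    false_alarms: int,
    n_targets: int,
    n_nontargets: int,
    *,
    correction: str = "loglinear",
) -> float:
    """Signal-detection sensitivity d' = z(hit rate) - z(false-alarm rate).

    The log-linear correction (add 0.5 to each cell, 1 to each denominator)
    keeps extreme rates of 0 or 1 finite; ``correction=None`` uses raw rates.
    """
    for name, v in (
        ("hits", hits),
        ("false_alarms", false_alarms),
        ("n_targets", n_targets),
        ("n_nontargets", n_nontargets),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if hits > n_targets or false_alarms > n_nontargets:
        raise ValueError("counts exceed their totals")
    if correction == "loglinear":
        hr = (hits + 0.5) / (n_targets + 1)
        far = (false_alarms + 0.5) / (n_nontargets + 1)
    elif correction in (None, "none"):
        hr = hits / n_targets
        far = false_alarms / n_nontargets
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return float(norm.ppf(hr) - norm.ppf(far))


# --------------------------------------------------------------------------
# CPT

#: Target prevalence by CPT phase.
CPT_TARGET_FRACTION = {"sustained_attention": 0.225, "response_inhibition": 0.775}


@dataclass(frozen=True)
class CPTConfig:
    """One 10-minute CPT half: 200 trials at 3 s each by default, so that
    the 22.5 % / 77.5 % prevalences give exact integer target counts."""

    n_trials: int = 200
    trial_seconds: float = 3.0
    #: baseline hit probability at trait 0 (saturating-link intercept)
    hit_floor: float = 0.5
    #: maximum false-alarm probability at trait 0
    fa_ceiling: float = 0.5


@dataclass(frozen=True)
class CPTResult:
    phase: str
    n_targets: int
    n_nontargets: int
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    d_prime: float


def _integral_target_count(n_trials: int, fraction: float) -> tuple[int, int]:
    n_targets = fraction * n_trials
    if abs(n_targets - round(n_targets)) > 1e-9:
        adjusted = int(round(n_targets))
        logger.warning(
            "%d trials x %.3f prevalence is not integral; using %d targets",
            n_trials,
            fraction,
            adjusted,
        )
        return adjusted, n_trials - adjusted
    return int(round(n_targets)), n_trials - int(round(n_targets))


def run_cpt(
    subject: VirtualSubject,
    phase: str,
    config: CPTConfig | None = None,
    rng: np.random.Generator | None = None,
) -> CPTResult:
    """Simulate one CPT half for a subject and score it with d'.

    The trial sequence is stratified: exactly ``fraction * n_trials`` targets.
    Hits are driven by the signal-sensitivity trait in both halves; false
    alarms by signal sensitivity in the sustained half (vigilance failures)
    and by the inhibition trait in the inhibition half (failures to withhold).
    A lapse-free subject with traits at 1.0 hits every target and never false
    alarms, so its d' is the corrected-rate ceiling for the trial counts.
    """
    if phase not in CPT_TARGET_FRACTION:
        raise ValueError(f"unknown CPT phase {phase!r}")
    config = config or CPTConfig()
    rng = rng if rng is not None else np.random.default_rng()
    n_targets, n_nontargets = _integral_target_count(
        config.n_trials, CPT_TARGET_FRACTION[phase]
    )

    lam = subject.lapse_rate
    t_hit = subject.traits["signal_sensitivity"]
    t_fa = subject.traits[
        "signal_sensitivity" if phase == "sustained_attention" else "inhibition"
    ]
    p_hit = lam / 2 + (1 - lam) * (config.hit_floor + (1 - config.hit_floor) * t_hit)
    p_fa = lam / 2 + (1 - lam) * config.fa_ceiling * (1 - t_fa)

    hits = int(rng.binomial(n_targets, p_hit))
    fas = int(rng.binomial(n_nontargets, p_fa))
    return CPTResult(
        phase=phase,
        n_targets=n_targets,
        n_nontargets=n_nontargets,
        hits=hits,
        misses=n_targets - hits,
        false_alarms=fas,
        correct_rejections=n_nontargets - fas,
        d_prime=compute_dprime(hits, fas, n_targets, n_nontargets),
    )


# --------------------------------------------------------------------------
# Span tasks


@dataclass(frozen=True)
class SpanConfig:
    """48 trials: 12 per load, 6 match / 6 non-match, so match prevalence is
    exactly 50 %.  Response time is base + slope * load / trait + noise."""

    trials_per_load: int = 12
    rt_base_s: float = 0.4
    rt_load_slope_s: float = 0.05
    rt_noise_sd_s: float = 0.15
    trait_floor: float = 0.05
    stable_accuracy: float = 0.9


@dataclass(frozen=True)
class SpanResult:
    domain: str
    loads: tuple[int, ...]
    n_trials: int
    n_match: int
    high_load_mean_speed_s: float
    accuracy: float

    @property
    def match_fraction(self) -> float:
        return self.n_match / self.n_trials


def expected_high_load_speed(
    subject: VirtualSubject, domain: str, config: SpanConfig | None = None
) -> float:
    """Closed-form mean of the high-load response speed (no noise)."""
    config = config or SpanConfig()
    loads = SPAN_LOADS[domain]
    high = loads[-2:]
    trait = max(subject.traits["signal_sensitivity"], config.trait_floor)
    return config.rt_base_s + config.rt_load_slope_s * float(np.mean(high)) / trait


def run_span(
    subject: VirtualSubject,
    domain: str,
    config: SpanConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SpanResult:
    """Simulate one span session; the metric is mean speed at the two
    highest loads (5/7 circles spatially, 7/9 letters verbally)."""
    if domain not in SPAN_LOADS:
        raise ValueError(f"unknown span domain {domain!r}")
    config = config or SpanConfig()
    rng = rng if rng is not None else np.random.default_rng()
    loads = SPAN_LOADS[domain]
    trait = max(subject.traits["signal_sensitivity"], config.trait_floor)

    per_load = config.trials_per_load
    n_trials = per_load * len(loads)
    n_match = n_trials // 2  # 6 of 12 per load are match probes
    high = loads[-2:]
    rts = []
    for load in high:
        mean_rt = config.rt_base_s + config.rt_load_slope_s * load / trait
        rts.append(mean_rt + rng.normal(0.0, config.rt_noise_sd_s, size=per_load))
    return SpanResult(
        domain=domain,
        loads=loads,
        n_trials=n_trials,
        n_match=n_match,
        high_load_mean_speed_s=float(np.mean(np.concatenate(rts))),
        accuracy=config.stable_accuracy,
    )


# --------------------------------------------------------------------------
# Stroop


@dataclass(frozen=True)
class StroopResult:
    word_correct: int
    color_correct: int
    colorword_correct: int
    interference: int


def score_stroop(
    word_correct: int, color_correct: int, colorword_correct: int
) -> int:
    """Interference = color-word correct minus color correct (<= 0 typically);
    each sheet holds 100 stimuli, so counts above 100 are rejected."""
    for name, v in (
        ("word_correct", word_correct),
        ("color_correct", color_correct),
        ("colorword_correct", colorword_correct),
    ):
        if not 0 <= v <= STROOP_SHEET_SIZE:
            raise ValueError(f"{name}={v} outside [0, {STROOP_SHEET_SIZE}]")
    return colorword_correct - color_correct


def simulate_stroop(
    subject: VirtualSubject,
    rng: np.random.Generator | None = None,
    *,
    word_mean: float = 85.0,
    color_mean: float = 72.0,
    count_sd: float = 4.0,
    max_interference: float = 40.0,
) -> StroopResult:
    """Simulate the three 45-second sheets at the count level.

    Interference magnitude scales with (1 - distractor_suppression): a child
    who suppresses the written word better loses fewer color-word items.
    """
    rng = rng if rng is not None else np.random.default_rng()

    def draw(mean: float) -> int:
        return int(np.clip(round(rng.normal(mean, count_sd)), 0, STROOP_SHEET_SIZE))

    word = draw(word_mean)
    color = draw(color_mean)
    interference = max_interference * (1 - subject.traits["distractor_suppression"])
    colorword = int(np.clip(round(color - interference + rng.normal(0, count_sd)), 0, color))
    return StroopResult(
        word_correct=word,
        color_correct=color,
        colorword_correct=colorword,
        interference=score_stroop(word, color, colorword),
    )


# --------------------------------------------------------------------------
# SWAN screening and CGI


def swan_screen(mean_item_scores: Mapping[str, float]) -> set[str]:
    """Subtypes whose mean item score strictly exceeds its cutoff
    (>2.11 combined, >2.48 inattentive, >2.00 hyperactive); an empty set is
    a negative screen."""
    unknown = set(mean_item_scores) - set(SWAN_CUTOFFS)
    if unknown:
        raise ValueError(f"unknown SWAN subtypes: {sorted(unknown)}")
    return {
        subtype
        for subtype, score in mean_item_scores.items()
        if score > SWAN_CUTOFFS[subtype]
    }


def emit_cgi(
    symptom_rating: float, rng: np.random.Generator, *, noise_sd: float = 0.5
) -> int:
    """Clinician CGI severity (ordinal 1-7) from overall symptom burden.

    A rough monotone recoding of the 0-54 symptom total onto 1-7 with rater
    noise; the clinician is blind to arm, so only severity enters.
    """
    raw = 1.0 + 6.0 * symptom_rating / 54.0 + rng.normal(0.0, noise_sd)
    return int(np.clip(round(raw), 1, 7))


# --------------------------------------------------------------------------
# Embedded distractor probe


@dataclass(frozen=True)
class ProbeConfig:
    """Fixed-challenge (non-adaptive) distractor block embedded in training."""

    n_trials: int = 80
    challenge: float = 0.5
    fa_ceiling: float = 0.5
    hit_floor: float = 0.5


@dataclass(frozen=True)
class ProbeResult:
    when: str
    n_targets: int
    n_nontargets: int
    hits: int
    false_positives: int

    @property
    def attended_accuracy(self) -> float:
        return self.hits / self.n_targets


def embedded_distractor_probe(
    subject: VirtualSubject,
    when: str,
    config: ProbeConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ProbeResult:
    """Run the distractor-suppression probe at training start or end.

    Half the trials present distractors only; affirmative responses on those
    are the false-positive count whose start-to-end reduction is correlated
    with symptom improvement.  A lapse-free perfect suppressor commits zero
    false positives.
    """
    if when not in ("start", "end"):
        raise ValueError(f"probe 'when' must be start or end, got {when!r}")
    config = config or ProbeConfig()
    rng = rng if rng is not None else np.random.default_rng()
    n_targets = config.n_trials // 2
    n_nontargets = config.n_trials - n_targets
    lam = subject.lapse_rate
    p_fp = lam / 2 + (1 - lam) * config.fa_ceiling * (
        1 - subject.traits["distractor_suppression"]
    )
    p_hit = lam / 2 + (1 - lam) * (
        config.hit_floor + (1 - config.hit_floor) * subject.traits["signal_sensitivity"]
    )
    return ProbeResult(
        when=when,
        n_targets=n_targets,
        n_nontargets=n_nontargets,
        hits=int(rng.binomial(n_targets, p_hit)),
        false_positives=int(rng.binomial(n_nontargets, p_fp)),
    )


# --------------------------------------------------------------------------
# Long-table helpers


def validate_schedule(records: Sequence[AssessmentRecord]) -> None:
    """Raise if any record violates the instrument x timepoint schedule.

    Construction of :class:`AssessmentRecord` already enforces this; the
    function re-validates records parsed from external tables.
    """
    for r in records:
        if r.timepoint not in INSTRUMENT_TIMEPOINTS[r.instrument]:
            raise ValueError(
                f"{r.subject_id}: {r.instrument} not scheduled at {r.timepoint}"
            )


def records_frame(records: Sequence[AssessmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "timepoint": r.timepoint,
                "instrument": r.instrument,
                "value": r.value,
            }
            for r in records
        ]
    )
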