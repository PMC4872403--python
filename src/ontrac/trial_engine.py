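"""In-silico randomized controlled trial: randomization, training, assembly.

Orchestrates the full simulated study: a 2:1 weighted, medication-stratified
blocked randomization in batches of eight; a 30-hour / 60-session / 24-week
home-training course run through the exercise battery and its staircases;
pre-intervention dropout and partial compliance; the four-visit assessment
schedule (baseline, mid at 3 months, post at 6 months, follow-up at 12
months, cognitive tests at baseline/post only); and assembly of everything
into one :class:`TrialDataset`.

Assessment values are computed from a subject's latent traits alone — arm
labels never enter any assessment code path, mirroring the double-blind
design (a dedicated audit test asserts this).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import battery
from .assessments import (
    AssessmentRecord,
    CPTConfig,
    ProbeConfig,
    SpanConfig,
    embedded_distractor_probe,
    emit_cgi,
    records_frame,
    run_cpt,
    run_span,
    simulate_stroop,
)
from .battery import (
    SessionRecord,
    accumulate_curriculum,
    build_registry,
    schedule_session,
)
from .staircase import (
    DEFAULT_INITIAL_CHALLENGE,
    DEFAULT_INITIAL_STEP,
    DEFAULT_STEP_FLOOR,
    update_core,
)
from .virtual_subject import (
    CATEGORY_TRAIT,
    CohortConfig,
    VirtualSubject,
    apply_learning,
    emit_symptom_rating,
    generate_cohort,
    cohort_frame,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ARMS",
    "TrialDesign",
    "TrialDataset",
    "randomize",
    "run_trial",
    "simulate_trial",
]

ARMS = ("ontrac", "control")


@dataclass(frozen=True)
class TrialDesign:
    """Design constants of the emulated study."""

    arms: tuple[str, str] = ARMS
    allocation_ratio: tuple[int, int] = (2, 1)
    block_size: int = 8
    #: visit name -> months from baseline
    timepoint_months: Mapping[str, float] = field(
        default_factory=lambda: {"baseline": 0.0, "mid": 3.0, "post": 6.0, "followup": 12.0}
    )
    dose_hours: float = 30.0
    dose_sessions: int = 60
    max_weeks: int = 24


@dataclass
class TrialDataset:
    """The full simulated (or ingested) trial, as long-format tables."""

    subjects: pd.DataFrame
    assignments: pd.DataFrame  # subject_id, arm, block, medication
    sessions: pd.DataFrame  # subject_id, session_index, start_hours, minutes
    training_log: pd.DataFrame  # per-trial rows (may be empty in summary mode)
    assessments: pd.DataFrame  # subject_id, timepoint, instrument, value
    probes: pd.DataFrame  # subject_id, when, false_positives, hits, ...
    completer_flags: pd.DataFrame  # subject_id, status, hours
    seed: int | None = None

    def arm_of(self, subject_id: str) -> str:
        row = self.assignments.loc[self.assignments.subject_id == subject_id, "arm"]
        if row.empty:
            raise KeyError(subject_id)
        return str(row.iloc[0])

    def subject_ids(self, *, arm: str | None = None, status: str | None = None) -> list[str]:
        ids = self.assignments
        if arm is not None:
            ids = ids[ids.arm == arm]
        out = list(ids.subject_id)
        if status is not None:
            flagged = set(
                self.completer_flags.loc[
                    self.completer_flags.status == status, "subject_id"
                ]
            )
            out = [s for s in out if s in flagged]
        return out


# --------------------------------------------------------------------------
# Randomization


def _block_quotas(n: int, block_size: int, ratio: tuple[int, int]) -> list[tuple[int, int]]:
    """Per-block (ontrac, control) counts tracking the global ratio.

    Blocks of eight cannot hold an integral 2:1 split, so quotas alternate
    around the running target (5:3 and 6:2 at the default ratio); a final
    short block is split proportionally.
    """
    frac = ratio[0] / sum(ratio)
    quotas = []
    cum = cum_a = 0
    while cum < n:
        size = min(block_size, n - cum)
        target = int(round(frac * (cum + size)))
        q = min(size, max(0, target - cum_a))
        quotas.append((q, size - q))
        cum += size
        cum_a += q
    return quotas


def randomize(
    cohort: Sequence[VirtualSubject],
    design: TrialDesign,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Blocked, weighted, medication-stratified arm assignment.

    Subjects are processed in enrollment order in batches of
    ``design.block_size``.  Within each block the trained-arm quota is split
    between medicated and unmedicated subjects proportionally (randomized
    within stratum), so on/off-medication counts stay approximately balanced
    across arms.  If a block is single-stratum the split degenerates to an
    unstratified draw, with a warning.
    """
    if not cohort:
        raise ValueError("cohort must be nonempty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    quotas = _block_quotas(len(cohort), design.block_size, design.allocation_ratio)

    rows = []
    idx = 0
    for block_no, (q_a, q_b) in enumerate(quotas):
        size = q_a + q_b
        block = list(cohort[idx : idx + size])
        idx += size
        med = [s for s in block if s.medication]
        unmed = [s for s in block if not s.medication]
        if not med or not unmed:
            logger.warning(
                "block %d is single-stratum; falling back to unstratified draw",
                block_no,
            )
        q_med = int(round(q_a * len(med) / size))
        q_med = min(len(med), max(q_a - len(unmed), q_med))
        chosen: set[str] = set()
        if q_med > 0:
            chosen |= {
                s.subject_id
                for s in rng.choice(np.array(med, dtype=object), size=q_med, replace=False)
            }
        q_unmed = q_a - q_med
        if q_unmed > 0:
            chosen |= {
                s.subject_id
                for s in rng.choice(np.array(unmed, dtype=object), size=q_unmed, replace=False)
            }
        for s in block:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "arm": "ontrac" if s.subject_id in chosen else "control",
                    "block": block_no,
                    "medication": int(s.medication),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Training execution


def _session_calendar(n_sessions: int, sessions_per_week: int) -> list[float]:
    """Start times (hours from intervention start) for each session."""
    starts = []
    for s in range(n_sessions):
        week, slot = divmod(s, sessions_per_week)
        day = slot * (7.0 / sessions_per_week)
        starts.append(week * 168.0 + day * 24.0 + 18.0)  # evening sessions
    return starts


def _simulate_block_trials(
    subject: VirtualSubject,
    spec: battery.ExerciseSpec,
    challenge: float,
    step: float,
    rng: np.random.Generator,
    n_trials: int,
    log_rows: list | None,
    log_prefix: tuple,
) -> tuple[float, float]:
    """Run one exercise block through the staircase with a tight scalar loop.

    Semantically identical to chaining :func:`ontrac.staircase.update_staircase`
    and :func:`ontrac.virtual_subject.respond` (asserted by tests); rewritten
    on plain scalars because full trial logs dominate the engine's runtime.
    Returns the staircase's (challenge, step) to persist across the session.
    """
    trait = subject.traits[CATEGORY_TRAIT[spec.category]]
    lam = subject.lapse_rate
    go_no_go = spec.response_format == "go_no_go"
    n_correct = 0
    n_rev = 0
    last_dir = "none"
    targets = np.zeros(n_trials, dtype=bool)
    targets[: n_trials // 2] = True
    rng.shuffle(targets)
    uniforms = rng.random(n_trials)
    for t in range(n_trials):
        p = 0.5 + (0.5 - lam) / (1.0 + math.exp(-8.0 * (trait - challenge)))
        correct = bool(uniforms[t] < p)
        if log_rows is not None:
            target = bool(targets[t])
            if target:
                response = ("withhold" if correct else "go") if go_no_go else (
                    "yes" if correct else "no"
                )
                fp = False
            else:
                response = ("go" if correct else "withhold") if go_no_go else (
                    "no" if correct else "yes"
                )
                fp = (not correct) and not go_no_go
            log_rows.append(
                log_prefix
                + (spec.id, t, round(challenge, 6), int(target), response, int(correct), int(fp))
            )
        challenge, step, n_correct, n_rev, last_dir = update_core(
            challenge, step, n_correct, n_rev, last_dir, correct
        )
    return challenge, step


def _train_subject(
    subject: VirtualSubject,
    n_sessions: int,
    rng: np.random.Generator,
    *,
    trials_per_block: int,
    trial_detail: bool,
    registry,
    mid_cutoff_weeks: float = 13.0,
) -> tuple[VirtualSubject, VirtualSubject, list[SessionRecord], list]:
    """Run one subject's curriculum; returns (mid-traits subject,
    final subject, session records, trial log rows).

    Per-trial simulation draws from a dedicated substream spawned here, so
    scheduling, learning and assessments are bit-identical whether or not
    the per-trial log is produced (``trial_detail``).
    """
    rng_blocks = np.random.default_rng(int(rng.integers(2**31)))
    sessions_per_week = int(rng.integers(3, 6))
    starts = _session_calendar(n_sessions, sessions_per_week)
    progress = {s.id: 0.0 for s in registry}
    challenges = {s.id: DEFAULT_INITIAL_CHALLENGE for s in registry}
    records: list[SessionRecord] = []
    log_rows: list = [] if trial_detail else None
    mid_subject = subject
    for s_idx in range(n_sessions):
        plan = schedule_session(progress, registry, rng)
        minutes_by_cat: dict[str, float] = {}
        for spec, minutes in plan:
            if trial_detail:
                challenge, _ = _simulate_block_trials(
                    subject,
                    spec,
                    challenges[spec.id],
                    DEFAULT_INITIAL_STEP,  # step resets each session
                    rng_blocks,
                    trials_per_block,
                    log_rows,
                    (subject.subject_id, s_idx, round(starts[s_idx], 3)),
                )
                challenges[spec.id] = challenge
            progress[spec.id] += minutes
            minutes_by_cat[spec.category] = (
                minutes_by_cat.get(spec.category, 0.0) + minutes
            )
        subject = apply_learning(subject, minutes_by_cat)
        records.append(
            SessionRecord(
                subject_id=subject.subject_id,
                session_index=s_idx,
                start_hours=starts[s_idx],
            )
        )
        if starts[s_idx] < mid_cutoff_weeks * 168.0:
            mid_subject = subject
    return mid_subject, subject, records, (log_rows or [])


# --------------------------------------------------------------------------
# Assessment emission (arm-blind: traits + rng in, values out)


def _emit_visit(
    subject: VirtualSubject,
    timepoint: str,
    rng: np.random.Generator,
    records: list[AssessmentRecord],
    *,
    cognitive: bool,
) -> None:
    adhd = emit_symptom_rating(subject, timepoint, rng)
    records.append(AssessmentRecord(subject.subject_id, timepoint, "adhd_rs", float(adhd)))
    records.append(
        AssessmentRecord(subject.subject_id, timepoint, "cgi", float(emit_cgi(adhd, rng)))
    )
    if not cognitive:
        return
    for phase, instrument in (
        ("sustained_attention", "cpt_sustained"),
        ("response_inhibition", "cpt_inhibition"),
    ):
        res = run_cpt(subject, phase, CPTConfig(), rng)
        records.append(
            AssessmentRecord(subject.subject_id, timepoint, instrument, res.d_prime)
        )
    for domain, instrument in (("spatial", "span_spatial"), ("verbal", "span_verbal")):
        res = run_span(subject, domain, SpanConfig(), rng)
        records.append(
            AssessmentRecord(
                subject.subject_id, timepoint, instrument, res.high_load_mean_speed_s
            )
        )
    stroop = simulate_stroop(subject, rng)
    records.append(
        AssessmentRecord(subject.subject_id, timepoint, "stroop", float(stroop.interference))
    )


# --------------------------------------------------------------------------
# Trial driver


def run_trial(
    design: TrialDesign,
    cohort: Sequence[VirtualSubject],
    seed: int,
    *,
    cohort_config: CohortConfig | None = None,
    trials_per_block: int = battery.TRIALS_PER_BLOCK,
    trial_detail: bool = True,
) -> TrialDataset:
    """Execute the whole trial on an existing cohort.

    Dropout is modeled between baseline and intervention start; the
    configured fraction of trained-arm subjects (those with the lowest
    compliance propensity) truncate their course at a 1-13 hour draw, the
    rest complete the full 60-session dose.  Controls play their assigned
    games for the full dose with no trait change.  ``trial_detail=False``
    skips per-trial staircase simulation (whose outcomes feed nothing
    downstream) for Monte-Carlo loops; all tables except the per-trial log
    are distributionally identical.
    """
    cfg = cohort_config or CohortConfig()
    ss = np.random.SeedSequence(seed)
    rng_rand, rng_comp, rng_train, rng_assess = [
        np.random.default_rng(child) for child in ss.spawn(4)
    ]
    registry = build_registry()

    assignments = randomize(cohort, design, rng_rand)
    arm = dict(zip(assignments.subject_id, assignments.arm))

    # pre-intervention dropout
    dropped = {
        s.subject_id for s in cohort if rng_comp.random() < cfg.dropout_probability
    }

    # partial compliance: the least-compliant fraction of trained subjects
    active = [
        s for s in cohort if arm[s.subject_id] == "ontrac" and s.subject_id not in dropped
    ]
    n_partial = int(round(cfg.partial_compliance_fraction * len(active)))
    by_propensity = sorted(active, key=lambda s: (s.compliance_propensity, s.subject_id))
    partial_ids = {s.subject_id for s in by_propensity[:n_partial]}

    records: list[AssessmentRecord] = []
    probe_rows: list[dict] = []
    session_records: list[SessionRecord] = []
    log_rows: list = []
    flag_rows: list[dict] = []

    for subject in cohort:
        sid = subject.subject_id
        _emit_visit(subject, "baseline", rng_assess, records, cognitive=True)
        if sid in dropped:
            flag_rows.append({"subject_id": sid, "status": "dropout", "hours": 0.0})
            continue

        if arm[sid] == "ontrac":
            if sid in partial_ids:
                hours = float(rng_comp.uniform(*cfg.partial_hours_range))
                n_sessions = max(1, int(round(hours * 2)))
            else:
                n_sessions = design.dose_sessions
            start_probe = embedded_distractor_probe(subject, "start", ProbeConfig(), rng_assess)
            mid_subject, final_subject, sess, rows = _train_subject(
                subject,
                n_sessions,
                rng_train,
                trials_per_block=trials_per_block,
                trial_detail=trial_detail,
                registry=registry,
            )
            end_probe = embedded_distractor_probe(
                final_subject, "end", ProbeConfig(), rng_assess
            )
            session_records.extend(sess)
            log_rows.extend(rows)
            for probe, tp in ((start_probe, "baseline"), (end_probe, "post")):
                probe_rows.append(
                    {
                        "subject_id": sid,
                        "when": probe.when,
                        "false_positives": probe.false_positives,
                        "hits": probe.hits,
                        "n_targets": probe.n_targets,
                        "n_nontargets": probe.n_nontargets,
                    }
                )
                records.append(
                    AssessmentRecord(
                        sid, tp, "embedded_distractor", float(probe.false_positives)
                    )
                )
        else:
            # controls: full game-play dose, configurable (default zero) drift
            n_sessions = design.dose_sessions
            spw = int(rng_train.integers(3, 6))
            for s_idx, start in enumerate(_session_calendar(n_sessions, spw)):
                session_records.append(SessionRecord(sid, s_idx, start))
            if cfg.control_learning_rate > 0:
                drift = {
                    t: cfg.control_learning_rate for t in subject.learning_rates
                }
                final_subject = apply_learning(
                    replace(subject, learning_rates=drift),
                    {"explicit_distractor": n_sessions * 30.0},
                )
            else:
                final_subject = subject
            mid_subject = final_subject

        summary = accumulate_curriculum(
            [r for r in session_records if r.subject_id == sid],
            full_dose_hours=design.dose_hours,
        )
        status = "completer" if summary.completed else "partial"
        flag_rows.append(
            {"subject_id": sid, "status": status, "hours": summary.total_hours}
        )

        _emit_visit(mid_subject, "mid", rng_assess, records, cognitive=False)
        _emit_visit(final_subject, "post", rng_assess, records, cognitive=True)
        # no intervention access between post and follow-up: traits persist
        _emit_visit(final_subject, "followup", rng_assess, records, cognitive=False)

    log_columns = [
        "subject_id",
        "session_index",
        "timestamp",
        "exercise_id",
        "trial_index",
        "challenge",
        "target_present",
        "response",
        "correct",
        "is_false_positive",
    ]
    sessions = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "session_index": r.session_index,
                "start_hours": r.start_hours,
                "minutes": r.minutes,
            }
            for r in session_records
        ]
    )
    return TrialDataset(
        subjects=cohort_frame(cohort),
        assignments=assignments,
        sessions=sessions,
        training_log=pd.DataFrame(log_rows, columns=log_columns),
        assessments=records_frame(records),
        probes=pd.DataFrame(
            probe_rows,
            columns=[
                "subject_id",
                "when",
                "false_positives",
                "hits",
                "n_targets",
                "n_nontargets",
            ],
        ),
        completer_flags=pd.DataFrame(flag_rows, columns=["subject_id", "status", "hours"]),
        seed=seed,
    )


def simulate_trial(
    config: CohortConfig | None = None,
    design: TrialDesign | None = None,
    seed: int = 0,
    **kwargs,
) -> TrialDataset:
    """Generate a cohort and run the full trial in one call.

    The cohort is drawn from a seed spawned off ``seed`` so that a single
    integer reproduces the entire dataset.
    """
    config = config or CohortConfig()
    design = design or TrialDesign()
    ss = np.random.SeedSequence(seed)
    cohort_seed, trial_seed = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2)]
    cohort = generate_cohort(replace(config, seed=cohort_seed))
    return run_trial(design, cohort, trial_seed, cohort_config=config, **kwargs)
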