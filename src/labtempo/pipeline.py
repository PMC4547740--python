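"""Episode mining: from raw event streams to a normalized, sampled corpus.

The extraction funnel has four stages:

1. partition each patient's administration days into maximal runs in
   which consecutive administrations are separated by at most one
   administration-free day;
2. keep only runs isolated by at least 14 administration-free days on
   each side (solitary episodes);
3. for each run and lab parameter, require at least five observations
   in each of three phases — the 7 days before the run, the run itself,
   and the 7 days after — then normalize the retained observations to
   the patient's reference interval and re-anchor them to relative days
   (day 0 = first administration day);
4. sample a fixed-size corpus uniformly without replacement.

All thresholds are configurable; the defaults are the corpus-building
rules stated above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from labtempo.model import (
    AdministrationEvent,
    Episode,
    LabObservation,
    NormalizedPoint,
    ReferenceInterval,
    ValidationError,
)

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """A pipeline or generator configuration is infeasible."""


@dataclass(frozen=True)
class PipelineConfig:
    """Extraction thresholds.

    isolation_days
        Minimum administration-free days required before and after a
        run for it to count as solitary.
    max_internal_gap_days
        Maximum administration-free days tolerated inside a run.
    flank_window_days
        Width of the before/after observation windows, in days.
    min_obs_per_phase
        Minimum lab observations required in each of the three phases.
    sample_size
        Number of episodes sampled into the corpus.
    strict_boundaries
        If True, a run whose isolation window extends beyond the
        patient's recorded span is rejected; by default the absence of
        recorded administrations counts as administration-free.
    """

    isolation_days: int = 14
    max_internal_gap_days: int = 1
    flank_window_days: int = 7
    min_obs_per_phase: int = 5
    sample_size: int = 400
    seed: int = 0
    strict_boundaries: bool = False

    def __post_init__(self) -> None:
        for name in (
            "isolation_days",
            "max_internal_gap_days",
            "flank_window_days",
            "min_obs_per_phase",
            "sample_size",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.isolation_days < self.flank_window_days:
            raise ConfigurationError(
                "isolation_days must be at least flank_window_days, otherwise "
                "flanking observations could overlap a neighbouring episode"
            )


@dataclass(frozen=True)
class AdministrationRun:
    """A maximal run of administration days for one patient."""

    patient_id: str
    admin_days: frozenset[int]

    @property
    def first_day(self) -> int:
        return min(self.admin_days)

    @property
    def last_day(self) -> int:
        return max(self.admin_days)


@dataclass(frozen=True)
class Rejection:
    """A run/parameter pair that failed the phase-count requirement."""

    patient_id: str
    first_day: int
    parameter_id: str
    phase: str
    count: int


def find_administration_runs(
    events: list[AdministrationEvent], max_internal_gap_days: int = 1
) -> list[AdministrationRun]:
    """Partition administration days into maximal runs per patient.

    Two consecutive administration days belong to the same run iff at
    most ``max_internal_gap_days`` administration-free days lie between
    them. Every administration day ends up in exactly one run. Runs are
    returned sorted by (patient_id, first_day).
    """
    by_patient: dict[str, set[int]] = {}
    for ev in events:
        by_patient.setdefault(ev.patient_id, set()).add(ev.day)
    runs: list[AdministrationRun] = []
    for patient_id in sorted(by_patient):
        days = sorted(by_patient[patient_id])
        current = [days[0]]
        for day in days[1:]:
            if day - current[-1] <= max_internal_gap_days + 1:
                current.append(day)
            else:
                runs.append(AdministrationRun(patient_id, frozenset(current)))
                current = [day]
        runs.append(AdministrationRun(patient_id, frozenset(current)))
    return runs


def filter_isolated(
    runs: list[AdministrationRun],
    all_events: list[AdministrationEvent],
    isolation_days: int = 14,
) -> list[AdministrationRun]:
    """Keep runs with no administration within ``isolation_days`` on either side."""
    by_patient: dict[str, set[int]] = {}
    for ev in all_events:
        by_patient.setdefault(ev.patient_id, set()).add(ev.day)
    kept = []
    for run in runs:
        days = by_patient.get(run.patient_id, set())
        lo, hi = run.first_day, run.last_day
        neighbours = [
            d
            for d in days
            if (lo - isolation_days <= d < lo) or (hi < d <= hi + isolation_days)
        ]
        if neighbours:
            logger.info(
                "run %s@%d rejected: administration on day %d inside the "
                "%d-day isolation window",
                run.patient_id,
                lo,
                min(neighbours),
                isolation_days,
            )
            continue
        kept.append(run)
    return kept


def normalize_value(value: float, interval: ReferenceInterval) -> float:
    """Map an absolute lab value onto the reference-interval scale.

    Returns ``(value - lower) / (upper - lower)``: 0 at the lower
    reference bound, 1 at the upper. No clamping — values below the
    interval go negative and values above exceed 1.
    """
    width = interval.upper - interval.lower
    if width <= 0:
        raise ValidationError(
            f"degenerate reference interval [{interval.lower}, {interval.upper}]"
        )
    return (value - interval.lower) / width


def attach_lab_curve(
    run: AdministrationRun,
    observations: list[LabObservation],
    interval: ReferenceInterval,
    config: PipelineConfig = PipelineConfig(),
    episode_id: str = "0",
) -> Episode | Rejection:
    """Attach one parameter's observations to a run, or reject it.

    Counts observations in the three phases (before / during / after);
    if every phase holds at least ``config.min_obs_per_phase`` values,
    returns an :class:`Episode` containing exactly the observations in
    the union of those windows, normalized and re-anchored to relative
    days. Otherwise returns a :class:`Rejection` naming the first
    failing phase. Observations outside the windows are discarded, not
    grounds for rejection.
    """
    first, last = run.first_day, run.last_day
    flank = config.flank_window_days
    phases = {
        "before": (first - flank, first - 1),
        "during": (first, last),
        "after": (last + 1, last + flank),
    }
    obs = sorted(
        (o for o in observations if o.patient_id == run.patient_id),
        key=lambda o: o.day,
    )
    in_phase: dict[str, list[LabObservation]] = {name: [] for name in phases}
    for o in obs:
        for name, (lo, hi) in phases.items():
            if lo <= o.day <= hi:
                in_phase[name].append(o)
                break
    for name in ("before", "during", "after"):
        count = len(in_phase[name])
        if count < config.min_obs_per_phase:
            logger.info(
                "run %s@%d / %s rejected: %d observations in phase %r "
                "(need %d)",
                run.patient_id,
                first,
                interval.parameter_id,
                count,
                name,
                config.min_obs_per_phase,
            )
            return Rejection(run.patient_id, first, interval.parameter_id, name, count)
    points = tuple(
        NormalizedPoint(o.day - first, normalize_value(o.value, interval))
        for name in ("before", "during", "after")
        for o in in_phase[name]
    )
    return Episode(
        episode_id=episode_id,
        administration_days=frozenset(d - first for d in run.admin_days),
        points=points,
    )


def sample_corpus(
    episodes: list[Episode], sample_size: int, seed: int
) -> list[Episode]:
    """Uniform sample without replacement, stable across input orderings."""
    if sample_size > len(episodes):
        raise ConfigurationError(
            f"sample_size {sample_size} exceeds population {len(episodes)}"
        )
    ordered = sorted(episodes, key=lambda e: e.episode_id)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ordered), size=sample_size, replace=False)
    return [ordered[i] for i in sorted(idx)]


@dataclass
class ExtractionResult:
    """Episodes plus the funnel counts and per-curve rejections."""

    episodes: list[Episode]
    rejections: list[Rejection]
    n_runs: int = 0
    n_isolated: int = 0
    truth_by_episode: dict[str, object] = field(default_factory=dict)


def extract_episodes(
    administrations: list[AdministrationEvent],
    observations: list[LabObservation],
    intervals: list[ReferenceInterval],
    config: PipelineConfig = PipelineConfig(),
    truth: dict | None = None,
) -> ExtractionResult:
    """Run the full mining funnel over an event stream.

    Each isolated run is crossed with every reference interval recorded
    for its patient; each (run, parameter) pair that passes the phase
    counts becomes one episode. Episode ids are consecutive integers in
    (patient_id, first_day, parameter_id) order, so the numbering is
    platform-stable. When ``truth`` maps
    ``(patient_id, first_day, parameter_id)`` to a planted-effect
    record (synthetic data), the matching label is attached to each
    episode and collected into ``truth_by_episode``.
    """
    runs = find_administration_runs(administrations, config.max_internal_gap_days)
    isolated = filter_isolated(runs, administrations, config.isolation_days)
    if config.strict_boundaries:
        spans: dict[str, tuple[int, int]] = {}
        for ev in administrations:
            lo, hi = spans.get(ev.patient_id, (ev.day, ev.day))
            spans[ev.patient_id] = (min(lo, ev.day), max(hi, ev.day))
        for o in observations:
            lo, hi = spans.get(o.patient_id, (o.day, o.day))
            spans[o.patient_id] = (min(lo, o.day), max(hi, o.day))
        isolated = [
            r
            for r in isolated
            if spans[r.patient_id][0] <= r.first_day - config.isolation_days
            and r.last_day + config.isolation_days <= spans[r.patient_id][1]
        ]

    obs_by_key: dict[tuple[str, str], list[LabObservation]] = {}
    seen: dict[tuple[str, str, int], float] = {}
    for o in observations:
        key = (o.patient_id, o.parameter_id, o.day)
        if key in seen and seen[key] != o.value:
            # daily scale admits one value; keep the last one read
            logger.warning(
                "duplicate observation for %s/%s day %d: keeping %.6g",
                o.patient_id,
                o.parameter_id,
                o.day,
                o.value,
            )
            group = obs_by_key[(o.patient_id, o.parameter_id)]
            group[:] = [g for g in group if g.day != o.day]
        elif key in seen:
            continue
        seen[key] = o.value
        obs_by_key.setdefault((o.patient_id, o.parameter_id), []).append(o)

    intervals_by_patient: dict[str, list[ReferenceInterval]] = {}
    for iv in intervals:
        intervals_by_patient.setdefault(iv.patient_id, []).append(iv)

    episodes: list[Episode] = []
    rejections: list[Rejection] = []
    result = ExtractionResult([], [], n_runs=len(runs), n_isolated=len(isolated))
    next_id = 1
    for run in sorted(isolated, key=lambda r: (r.patient_id, r.first_day)):
        for iv in sorted(
            intervals_by_patient.get(run.patient_id, []),
            key=lambda i: i.parameter_id,
        ):
            outcome = attach_lab_curve(
                run,
                obs_by_key.get((run.patient_id, iv.parameter_id), []),
                iv,
                config,
                episode_id=str(next_id),
            )
            if isinstance(outcome, Rejection):
                rejections.append(outcome)
                continue
            episode = replace(outcome, parameter_tag=iv.parameter_id)
            if truth is not None:
                key = (run.patient_id, run.first_day, iv.parameter_id)
                planted = truth.get(key)
                if planted is not None:
                    episode = replace(
                        episode, truth_label=bool(getattr(planted, "effect", planted))
                    )
                    result.truth_by_episode[episode.episode_id] = planted
            episodes.append(episode)
            next_id += 1
    result.episodes = episodes
    result.rejections = rejections
    return result
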