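"""Domain types and structural validation.

Every record is day-granular: calendar time is an integer day index,
and episode curves live on a relative-day axis where day 0 is the first
administration day. Lab values inside an episode are dimensionless,
normalized so the patient-specific reference interval maps onto [0, 1];
values outside [0, 1] are meaningful (below/above the reference range)
and are never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

TEMPORAL_CORRELATION = "temporal_correlation"
NO_CHANGE = "no_change"
NO_ASSESSMENT = "no_assessment"

#: The three nominal assessment categories, in canonical order.
CATEGORIES = (TEMPORAL_CORRELATION, NO_CHANGE, NO_ASSESSMENT)

INTRICACY_LEVELS = ("low", "medium", "high")


class ValidationError(ValueError):
    """A structural invariant of the corpus model is violated."""


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)


@dataclass(frozen=True)
class AdministrationEvent:
    """One drug administration, reduced to the pure calendar date.

    Dose is deliberately absent: the corpus models temporal structure
    only.
    """

    patient_id: str
    day: int


@dataclass(frozen=True)
class LabObservation:
    """One absolute lab value for a patient/parameter on a calendar day."""

    patient_id: str
    parameter_id: str
    day: int
    value: float


@dataclass(frozen=True)
class ReferenceInterval:
    """Patient- and parameter-specific normal range [lower, upper]."""

    patient_id: str
    parameter_id: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        _require(
            self.upper > self.lower,
            f"reference interval for ({self.patient_id}, {self.parameter_id}): "
            f"upper ({self.upper}) must exceed lower ({self.lower})",
        )

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class NormalizedPoint:
    """A normalized lab value on the relative-day axis.

    value = 0 at the lower reference bound, 1 at the upper bound; values
    may be negative or exceed 1.
    """

    relative_day: int
    value: float


@dataclass(frozen=True)
class Episode:
    """A solitary administration run with its normalized lab curve.

    ``administration_days`` are relative days (minimum 0).
    ``truth_label`` and ``parameter_tag`` are only populated on
    synthetic data, where the planted effect and source parameter are
    known; on a real corpus both are ``None``.
    """

    episode_id: str
    administration_days: frozenset[int]
    points: tuple[NormalizedPoint, ...]
    truth_label: bool | None = None
    parameter_tag: str | None = None

    @property
    def last_administration_day(self) -> int:
        return max(self.administration_days)

    @property
    def admin_length_days(self) -> int:
        """Inclusive administration length: a run over days 0..9 is 10 days."""
        return self.last_administration_day - min(self.administration_days) + 1

    @property
    def observed_span_days(self) -> int:
        """First-to-last observed lab day, inclusive."""
        days = [p.relative_day for p in self.points]
        return max(days) - min(days) + 1


@dataclass(frozen=True)
class VoteSet:
    """All raters' votes on one episode; one vote per rater."""

    episode_id: str
    votes: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        raters = [r for r, _ in self.votes]
        _require(
            len(raters) == len(set(raters)),
            f"episode {self.episode_id}: duplicate rater in vote set",
        )
        for rater, category in self.votes:
            _require(
                category in CATEGORIES,
                f"episode {self.episode_id}: rater {rater} voted unknown "
                f"category {category!r}",
            )

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for _, category in self.votes:
            out[category] += 1
        return out


@dataclass(frozen=True)
class Classification:
    """Aggregated panel decision for one episode.

    ``concordance`` is the fraction of raters agreeing with the majority
    call (under a standoff: with the tied maximum). A standoff is always
    recorded as ``no_assessment``.
    """

    episode_id: str
    call: str
    concordance: float
    agree_count: int
    n_raters: int
    intricacy: str
    standoff: bool = False

    def __post_init__(self) -> None:
        _require(self.call in CATEGORIES, f"unknown call {self.call!r}")
        _require(
            self.intricacy in INTRICACY_LEVELS,
            f"unknown intricacy {self.intricacy!r}",
        )
        _require(
            0 < self.agree_count <= self.n_raters,
            f"episode {self.episode_id}: agree_count {self.agree_count} out of "
            f"range for {self.n_raters} raters",
        )
        _require(
            abs(self.concordance - self.agree_count / self.n_raters) < 1e-9,
            f"episode {self.episode_id}: concordance {self.concordance} does "
            f"not equal agree_count/n_raters",
        )
        if self.standoff:
            _require(
                self.call == NO_ASSESSMENT,
                f"episode {self.episode_id}: standoff must be called "
                f"{NO_ASSESSMENT}",
            )


@dataclass
class Corpus:
    """Episodes plus their classifications (and, optionally, raw votes)."""

    episodes: list[Episode] = field(default_factory=list)
    classifications: list[Classification] = field(default_factory=list)
    raw_votes: list[VoteSet] | None = None

    def classification_for(self, episode_id: str) -> Classification:
        for c in self.classifications:
            if c.episode_id == episode_id:
                return c
        raise KeyError(episode_id)

    def __len__(self) -> int:
        return len(self.episodes)


@dataclass
class AssessmentSet:
    """One assessor's category per episode (human, simulated, or algorithm)."""

    assessor_id: str
    entries: dict[str, str]

    def __post_init__(self) -> None:
        for episode_id, category in self.entries.items():
            _require(
                category in CATEGORIES,
                f"assessment {self.assessor_id}: episode {episode_id} has "
                f"unknown category {category!r}",
            )


def validate_episode(
    episode: Episode,
    *,
    max_internal_gap_days: int = 1,
    flank_window_days: int = 7,
    min_obs_per_phase: int = 5,
) -> None:
    """Check the five structural episode rules; raise on violation.

    Rules: relative day 0 anchors the first administration; at most
    ``max_internal_gap_days`` administration-free days between
    consecutive administrations; at least ``min_obs_per_phase``
    observations before, during and after the administration run; and
    flanking observations within ``flank_window_days`` of the run.
    """
    eid = episode.episode_id
    _require(len(episode.administration_days) > 0, f"episode {eid}: no administrations")
    days = sorted(episode.administration_days)
    _require(days[0] == 0, f"episode {eid}: first administration day is {days[0]}, not 0")
    for a, b in zip(days, days[1:]):
        _require(
            b - a <= max_internal_gap_days + 1,
            f"episode {eid}: administration gap {b - a - 1} free days between "
            f"day {a} and day {b} exceeds {max_internal_gap_days}",
        )
    last = days[-1]
    before = [p for p in episode.points if p.relative_day < 0]
    during = [p for p in episode.points if 0 <= p.relative_day <= last]
    after = [p for p in episode.points if p.relative_day > last]
    for name, phase in (("before", before), ("during", during), ("after", after)):
        _require(
            len(phase) >= min_obs_per_phase,
            f"episode {eid}: only {len(phase)} observations in phase "
            f"{name!r}, need {min_obs_per_phase}",
        )
    for p in before:
        _require(
            p.relative_day >= -flank_window_days,
            f"episode {eid}: observation on relative day {p.relative_day} "
            f"precedes the {flank_window_days}-day before-window",
        )
    for p in after:
        _require(
            p.relative_day <= last + flank_window_days,
            f"episode {eid}: observation on relative day {p.relative_day} "
            f"exceeds the {flank_window_days}-day after-window",
        )


def validate_corpus(corpus: Corpus, **episode_rules) -> None:
    """Validate every episode and the episode/classification id match."""
    episode_ids = [e.episode_id for e in corpus.episodes]
    _require(len(episode_ids) == len(set(episode_ids)), "duplicate episode ids")
    class_ids = [c.episode_id for c in corpus.classifications]
    # a corpus may be unclassified (no classifications at all); once
    # classifications exist they must cover the episodes one-to-one
    _require(
        not class_ids or sorted(episode_ids) == sorted(class_ids),
        "episode ids and classification ids do not match one-to-one",
    )
    for episode in corpus.episodes:
        validate_episode(episode, **episode_rules)
    if corpus.raw_votes is not None:
        vote_ids = {v.episode_id for v in corpus.raw_votes}
        _require(
            vote_ids <= set(episode_ids),
            "raw votes reference unknown episode ids",
        )
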