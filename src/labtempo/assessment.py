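"""Aggregation of rater votes into per-episode classifications.

An episode's call is the category receiving strictly more votes than
any other. A tie at the maximum is a standoff and is recorded as
``no_assessment``. The concordance value is the fraction of raters
agreeing with the call (with the tied maximum, under a standoff), and
the rule-based intricacy grades how contested the episode was: for an
11-rater panel, low = 10 or 11 raters agreed, medium = 8 or 9,
high = 7 or fewer.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from labtempo.model import (
    NO_ASSESSMENT,
    Classification,
    ValidationError,
    VoteSet,
)


@dataclass(frozen=True)
class IntricacyRule:
    """Agreement-count thresholds for the three intricacy levels.

    By default the thresholds are absolute counts for an 11-rater
    panel. ``fractional=True`` rescales them to other panel sizes
    (low: at least (n-1)/n of raters, medium: at least round(8n/11)).
    """

    low_min_agree: int = 10
    medium_min_agree: int = 8
    n_raters: int = 11
    fractional: bool = False

    def __post_init__(self) -> None:
        if not (self.n_raters >= self.low_min_agree > self.medium_min_agree >= 1):
            raise ValidationError(
                "intricacy thresholds must satisfy "
                "n_raters >= low_min_agree > medium_min_agree >= 1"
            )

    def for_panel(self, n_raters: int) -> "IntricacyRule":
        if n_raters == self.n_raters or not self.fractional:
            return self
        low = n_raters - round(
            (self.n_raters - self.low_min_agree) * n_raters / self.n_raters
        )
        medium = round(self.medium_min_agree * n_raters / self.n_raters)
        return IntricacyRule(low, medium, n_raters, fractional=True)


def intricacy(agree_count: int, rule: IntricacyRule = IntricacyRule()) -> str:
    """Classify an agreement count as low / medium / high intricacy."""
    if not 1 <= agree_count <= rule.n_raters:
        raise ValidationError(
            f"agree_count {agree_count} out of range 1..{rule.n_raters}"
        )
    if agree_count >= rule.low_min_agree:
        return "low"
    if agree_count >= rule.medium_min_agree:
        return "medium"
    return "high"


def majority_call(
    votes: VoteSet, rule: IntricacyRule = IntricacyRule()
) -> Classification:
    """Aggregate one episode's votes into a classification.

    The concordance denominator is always the full panel size —
    abstentions (``no_assessment`` votes) count in the denominator.
    """
    if not votes.votes:
        raise ValidationError(f"episode {votes.episode_id}: empty vote set")
    counts = votes.counts()
    n_raters = len(votes.votes)
    top = max(counts.values())
    winners = [c for c, n in counts.items() if n == top]
    standoff = len(winners) > 1
    call = NO_ASSESSMENT if standoff else winners[0]
    effective = rule.for_panel(n_raters)
    # absolute thresholds apply unchanged to any panel size: a small
    # panel simply cannot reach the low band
    if top >= effective.low_min_agree:
        level = "low"
    elif top >= effective.medium_min_agree:
        level = "medium"
    else:
        level = "high"
    return Classification(
        episode_id=votes.episode_id,
        call=call,
        concordance=float(Fraction(top, n_raters)),
        agree_count=top,
        n_raters=n_raters,
        intricacy=level,
        standoff=standoff,
    )


def classify_corpus(
    votesets: list[VoteSet], rule: IntricacyRule = IntricacyRule()
) -> list[Classification]:
    """Apply :func:`majority_call` to every vote set."""
    return [majority_call(v, rule) for v in votesets]
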