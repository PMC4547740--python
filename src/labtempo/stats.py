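"""Evaluation statistics for ground-truth corpora and external assessments.

Three estimators matter here:

* the difficulty-weighted Concordance Score
  ``S_C = sum(m_i * c_i) / sum(c_i)`` comparing an external assessment
  with the ground-truth calls, where ``m_i`` is 1 on a match and
  ``c_i`` is the episode's concordance value — so disagreeing with the
  panel on an episode the panel itself found hard costs little;
* Krippendorff's alpha for nominal data (coincidence-matrix
  formulation, tolerant of missing votes), the chance-corrected
  agreement across the whole rater panel;
* the uncorrected Pearson chi-squared statistic on a 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from labtempo.model import (
    CATEGORIES,
    AssessmentSet,
    Corpus,
    ValidationError,
    VoteSet,
)


class UndefinedAlphaError(ValueError):
    """Krippendorff's alpha is undefined (expected disagreement is zero)."""


class CoverageError(ValidationError):
    """An external assessment does not cover the whole corpus."""

    def __init__(self, missing: list[str]):
        self.missing = missing
        preview = ", ".join(missing[:10])
        suffix = "…" if len(missing) > 10 else ""
        super().__init__(
            f"external assessment missing {len(missing)} episode(s): "
            f"{preview}{suffix}"
        )


@dataclass(frozen=True)
class ComparisonReport:
    """Outcome of comparing an external assessment with the ground truth."""

    n_compared: int
    n_matched: int
    concordance_score: float
    match_rate_by_intricacy: dict[str, float] = field(default_factory=dict)


def concordance_score(
    external: AssessmentSet, corpus: Corpus, restrict: bool = False
) -> ComparisonReport:
    """Difficulty-weighted agreement of an external assessment with the corpus.

    Every corpus episode must be covered unless ``restrict`` is set, in
    which case the score runs over the covered episodes only.
    """
    ids = [c.episode_id for c in corpus.classifications]
    missing = [i for i in ids if i not in external.entries]
    if missing and not restrict:
        raise CoverageError(missing)
    covered = [c for c in corpus.classifications if c.episode_id in external.entries]
    if not covered:
        raise ValidationError("no overlapping episodes to compare")
    num = 0.0
    den = 0.0
    matched = 0
    by_level: dict[str, list[int]] = {"low": [], "medium": [], "high": []}
    for cls in covered:
        m = int(external.entries[cls.episode_id] == cls.call)
        matched += m
        num += m * cls.concordance
        den += cls.concordance
        by_level[cls.intricacy].append(m)
    return ComparisonReport(
        n_compared=len(covered),
        n_matched=matched,
        concordance_score=num / den,
        match_rate_by_intricacy={
            level: float(np.mean(ms)) for level, ms in by_level.items() if ms
        },
    )


def krippendorff_alpha(votesets: list[VoteSet]) -> float:
    """Nominal-metric Krippendorff's alpha over a panel's votes.

    Uses the coincidence-matrix estimator: each episode (unit) with
    ``m`` votes contributes each ordered pair of its votes with weight
    ``1/(m - 1)``. Units with fewer than two votes are ignored.
    Raises :class:`UndefinedAlphaError` when every pairable vote is the
    same category, since chance-corrected agreement is then undefined.
    """
    index = {c: i for i, c in enumerate(CATEGORIES)}
    k = len(CATEGORIES)
    coincidence = np.zeros((k, k))
    usable = 0
    for vs in votesets:
        values = [index[cat] for _, cat in vs.votes]
        m = len(values)
        if m < 2:
            continue
        usable += 1
        counts = np.bincount(values, minlength=k)
        pair = np.outer(counts, counts) - np.diag(counts)
        coincidence += pair / (m - 1)
    if usable < 2:
        raise ValidationError("need at least two episodes with >=2 votes")
    n_c = coincidence.sum(axis=1)
    n = n_c.sum()
    observed = n - np.trace(coincidence)
    expected = (n * n - (n_c * n_c).sum()) / (n - 1)
    if expected <= 0:
        raise UndefinedAlphaError(
            "all pairable votes fall in a single category; expected "
            "disagreement is zero and alpha is undefined"
        )
    return float(1.0 - observed / expected)


def pearson_chi2_2x2(table) -> tuple[float, int]:
    """Pearson chi-squared on a 2x2 table, no continuity correction.

    Returns ``(statistic, df)`` with ``df = 1``, using the closed form
    ``N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValidationError("cell counts must be non-negative")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValidationError("chi-squared undefined: a table margin is zero")
    statistic = n * (a * d - b * c) ** 2 / margins
    return float(statistic), 1


@dataclass
class SummaryTable:
    """Corpus composition and episode-length summary.

    ``counts`` is a calls x intricacy table (rows: low/medium/high plus
    an ``all`` row); the two percentage frames recompute from it.
    Episode lengths are reported in days: ``admin_length`` is the
    inclusive administration-run length, ``span_fixed_flank`` adds both
    flanking windows to it, and ``span_observed`` is the first-to-last
    observed lab day. Means are paired with sample standard deviations.
    """

    n_episodes: int
    counts: pd.DataFrame
    percent_of_total: pd.DataFrame
    percent_within_intricacy: pd.DataFrame
    length_stats: dict[str, tuple[float, float]]
    per_parameter: pd.DataFrame | None = None


def _mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def summarize_corpus(corpus: Corpus, flank_window_days: int = 7) -> SummaryTable:
    """Tabulate calls x intricacy and episode-length statistics."""
    if not corpus.episodes:
        empty = pd.DataFrame(
            0, index=["low", "medium", "high", "all"], columns=list(CATEGORIES)
        )
        return SummaryTable(0, empty, empty.astype(float), empty.astype(float), {})
    records = []
    for cls in corpus.classifications:
        records.append({"call": cls.call, "intricacy": cls.intricacy})
    df = pd.DataFrame.from_records(records)
    counts = (
        pd.crosstab(df["intricacy"], df["call"])
        .reindex(index=["low", "medium", "high"], columns=list(CATEGORIES))
        .fillna(0)
        .astype(int)
    )
    counts.loc["all"] = counts.sum(axis=0)
    n = len(corpus.classifications)
    percent_total = counts / n * 100.0
    row_sums = counts.sum(axis=1)
    percent_within = counts.div(row_sums.replace(0, np.nan), axis=0) * 100.0

    admin_lengths = [e.admin_length_days for e in corpus.episodes]
    spans_fixed = [l + 2 * flank_window_days for l in admin_lengths]
    spans_observed = [e.observed_span_days for e in corpus.episodes]
    length_stats = {
        "admin_length": _mean_sd(admin_lengths),
        "span_fixed_flank": _mean_sd(spans_fixed),
        "span_observed": _mean_sd(spans_observed),
    }

    per_parameter = None
    tags = {e.episode_id: e.parameter_tag for e in corpus.episodes}
    if any(tag is not None for tag in tags.values()):
        rows = [
            {
                "parameter": tags[c.episode_id] or "unknown",
                "call": c.call,
                "intricacy": c.intricacy,
            }
            for c in corpus.classifications
        ]
        pdf = pd.DataFrame.from_records(rows)
        per_parameter = pd.crosstab(pdf["parameter"], pdf["call"]).reindex(
            columns=list(CATEGORIES), fill_value=0
        )

    return SummaryTable(
        n_episodes=n,
        counts=counts,
        percent_of_total=percent_total,
        percent_within_intricacy=percent_within,
        length_stats=length_stats,
        per_parameter=per_parameter,
    )
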