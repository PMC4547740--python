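from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from labtempo.model import (
    CATEGORIES,
    NO_CHANGE,
    TEMPORAL_CORRELATION,
    AssessmentSet,
    Corpus,
    VoteSet,
)
from labtempo.stats import (
    CoverageError,
    UndefinedAlphaError,
    concordance_score,
    krippendorff_alpha,
    pearson_chi2_2x2,
    summarize_corpus,
)

from conftest import make_classified_corpus, make_episode, make_votes


# --- independent oracles ----------------------------------------------------


def oracle_alpha(units):
    """Exact-fraction pairwise-disagreement formulation of nominal alpha."""
    o = {}
    for unit in units:
        m = len(unit)
        if m < 2:
            continue
        w = Fraction(1, m - 1)
        for i in range(m):
            for j in range(m):
                if i != j:
                    o[(unit[i], unit[j])] = o.get((unit[i], unit[j]), Fraction(0)) + w
    n_c = {}
    for (c, _), v in o.items():
        n_c[c] = n_c.get(c, Fraction(0)) + v
    n = sum(n_c.values())
    observed = sum(v for (c, k), v in o.items() if c != k)
    expected = (n * n - sum(v * v for v in n_c.values())) / (n - 1)
    if expected == 0:
        return None
    return 1 - observed / expected


def oracle_score(matches, weights):
    return sum(m * c for m, c in zip(matches, weights)) / sum(weights)


# --- Concordance Score ------------------------------------------------------


def perfect_external(corpus):
    return AssessmentSet(
        "perfect", {c.episode_id: c.call for c in corpus.classifications}
    )


def test_perfect_agreement_scores_one():
    corpus = make_classified_corpus([(7, 3, 1), (11, 0, 0), (2, 8, 1)])
    report = concordance_score(perfect_external(corpus), corpus)
    assert report.concordance_score == 1.0
    assert report.n_matched == report.n_compared == 3


def test_two_episode_hand_example_scores_two_thirds():
    from labtempo.model import Classification

    # concordances 1.0 and 0.5; the external assessor matches only the first
    corpus = Corpus(
        episodes=[make_episode("1"), make_episode("2")],
        classifications=[
            Classification("1", TEMPORAL_CORRELATION, 1.0, 11, 11, "low"),
            Classification("2", NO_CHANGE, 0.5, 1, 2, "high"),
        ],
    )
    external = AssessmentSet(
        "half", {"1": TEMPORAL_CORRELATION, "2": TEMPORAL_CORRELATION}
    )
    report = concordance_score(external, corpus)
    assert report.concordance_score == pytest.approx(1.0 / 1.5)
    assert report.n_matched == 1


def test_score_equals_straight_summation_oracle_on_random_corpus(rng):
    comps = []
    for _ in range(400):
        tc = int(rng.integers(0, 12))
        nc = int(rng.integers(0, 12 - tc))
        comps.append((tc, nc, 11 - tc - nc))
    corpus = make_classified_corpus(comps)
    entries = {
        c.episode_id: CATEGORIES[int(rng.integers(0, 3))]
        for c in corpus.classifications
    }
    report = concordance_score(AssessmentSet("rand", entries), corpus)
    matches = [int(entries[c.episode_id] == c.call) for c in corpus.classifications]
    weights = [c.concordance for c in corpus.classifications]
    assert report.concordance_score == pytest.approx(
        oracle_score(matches, weights), abs=1e-12
    )


def test_missing_episodes_raise_coverage_error_unless_restricted():
    corpus = make_classified_corpus([(11, 0, 0), (0, 11, 0)])
    partial = AssessmentSet(
        "p", {corpus.classifications[0].episode_id: TEMPORAL_CORRELATION}
    )
    with pytest.raises(CoverageError) as err:
        concordance_score(partial, corpus)
    assert corpus.classifications[1].episode_id in err.value.missing
    report = concordance_score(partial, corpus, restrict=True)
    assert report.n_compared == 1 and report.concordance_score == 1.0


def test_flipping_a_mismatch_to_a_match_strictly_increases_score(rng):
    corpus = make_classified_corpus([(7, 4, 0), (9, 2, 0), (6, 5, 0)])
    entries = {c.episode_id: NO_CHANGE for c in corpus.classifications}
    low = concordance_score(AssessmentSet("x", entries), corpus).concordance_score
    entries[corpus.classifications[0].episode_id] = TEMPORAL_CORRELATION
    high = concordance_score(AssessmentSet("x", entries), corpus).concordance_score
    assert high > low


def test_equal_weights_reduce_score_to_percent_agreement():
    corpus = make_classified_corpus([(8, 3, 0), (3, 8, 0), (8, 0, 3), (0, 8, 3)])
    assert len({c.concordance for c in corpus.classifications}) == 1
    entries = {c.episode_id: TEMPORAL_CORRELATION for c in corpus.classifications}
    report = concordance_score(AssessmentSet("x", entries), corpus)
    assert report.concordance_score == pytest.approx(
        report.n_matched / report.n_compared
    )


# --- Krippendorff's alpha ---------------------------------------------------


def votes_from_matrix(matrix):
    return [
        VoteSet(str(i + 1), tuple((f"r{j}", CATEGORIES[v]) for j, v in enumerate(row)))
        for i, row in enumerate(matrix)
    ]


def test_alpha_is_one_on_perfect_agreement_across_two_categories():
    votes = votes_from_matrix([[0] * 11, [1] * 11, [0] * 11])
    assert krippendorff_alpha(votes) == pytest.approx(1.0)


def test_alpha_undefined_when_only_one_category_ever_used():
    votes = votes_from_matrix([[1] * 11, [1] * 11])
    with pytest.raises(UndefinedAlphaError):
        krippendorff_alpha(votes)


def test_alpha_zero_on_chance_level_construction():
    # brute-force-found minimal matrix with observed == expected disagreement
    votes = votes_from_matrix([[0, 0], [0, 0], [0, 1]])
    assert krippendorff_alpha(votes) == pytest.approx(0.0, abs=1e-12)


def test_alpha_matches_exact_pairwise_oracle_on_random_panels(rng):
    for _ in range(25):
        n_units = int(rng.integers(2, 40))
        matrix = rng.integers(0, 3, size=(n_units, 11))
        units = [tuple(row) for row in matrix]
        expected = oracle_alpha(units)
        if expected is None:
            continue
        assert krippendorff_alpha(votes_from_matrix(matrix)) == pytest.approx(
            float(expected), abs=1e-9
        )


def test_alpha_tolerates_missing_votes_and_matches_oracle(rng):
    units, votesets = [], []
    for i in range(30):
        m = int(rng.integers(1, 12))
        row = rng.integers(0, 3, size=m)
        units.append(tuple(row))
        votesets.append(
            VoteSet(
                str(i + 1),
                tuple((f"r{j}", CATEGORIES[v]) for j, v in enumerate(row)),
            )
        )
    assert krippendorff_alpha(votesets) == pytest.approx(
        float(oracle_alpha(units)), abs=1e-9
    )


def test_alpha_invariant_under_rater_permutation_and_unit_duplication(rng):
    matrix = rng.integers(0, 3, size=(20, 11))
    base = krippendorff_alpha(votes_from_matrix(matrix))
    permuted = matrix[:, rng.permutation(11)]
    assert krippendorff_alpha(votes_from_matrix(permuted)) == pytest.approx(base)
    # duplication invariance holds only up to the (n-1) finite-sample
    # correction in the expected-disagreement term
    doubled = np.vstack([matrix, matrix])
    assert krippendorff_alpha(votes_from_matrix(doubled)) == pytest.approx(
        base, abs=0.01
    )
    assert base <= 1.0


# --- Pearson chi-squared ----------------------------------------------------


def test_chi2_on_very_common_vs_rare_contingency_table():
    stat, df = pearson_chi2_2x2([[63, 44], [11, 127]])
    assert df == 1
    assert round(stat, 2) == 74.09


def test_chi2_zero_on_proportional_rows():
    stat, _ = pearson_chi2_2x2([[10, 10], [20, 20]])
    assert stat == 0.0


def test_chi2_matches_scipy_without_continuity_correction(rng):
    for _ in range(100):
        table = rng.integers(1, 60, size=(2, 2))
        stat, df = pearson_chi2_2x2(table)
        ref = sps.chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref.statistic, abs=1e-9)
        assert df == ref.dof


def test_chi2_invariant_under_transpose_and_row_column_swap(rng):
    table = rng.integers(1, 60, size=(2, 2))
    stat, _ = pearson_chi2_2x2(table)
    assert pearson_chi2_2x2(table.T)[0] == pytest.approx(stat)
    assert pearson_chi2_2x2(table[::-1, ::-1])[0] == pytest.approx(stat)


def test_chi2_zero_margin_rejected():
    from labtempo.model import ValidationError

    with pytest.raises(ValidationError):
        pearson_chi2_2x2([[0, 0], [5, 7]])


# --- corpus summary ---------------------------------------------------------


def test_single_cell_corpus_summary():
    corpus = make_classified_corpus([(0, 11, 0)] * 4)
    table = summarize_corpus(corpus)
    assert table.counts.loc["low", NO_CHANGE] == 4
    assert table.counts.loc["all"].sum() == 4
    assert table.percent_of_total.loc["low", NO_CHANGE] == pytest.approx(100.0)


def test_headline_split_percentages_recompute_from_counts():
    """A 400-episode corpus with calls split 220/133/47 yields the
    55.00 / 33.25 / 11.75 percent breakdown."""
    comps = [(0, 11, 0)] * 220 + [(11, 0, 0)] * 133 + [(0, 0, 11)] * 47
    corpus = make_classified_corpus(comps, with_votes=False)
    table = summarize_corpus(corpus)
    row = table.counts.loc["all"]
    assert row[NO_CHANGE] == 220 and row[TEMPORAL_CORRELATION] == 133
    pct = table.percent_of_total.loc["all"]
    assert pct[NO_CHANGE] == pytest.approx(55.00)
    assert pct[TEMPORAL_CORRELATION] == pytest.approx(33.25)
    assert pct["no_assessment"] == pytest.approx(11.75)


def test_summary_counts_match_independent_tally(small_cohort):
    from labtempo.assessment import classify_corpus
    from labtempo.pipeline import PipelineConfig, extract_episodes
    from labtempo.synth import make_panel, simulate_raters

    _, (admins, observations, intervals, truth) = small_cohort
    result = extract_episodes(admins, observations, intervals, PipelineConfig(), truth)
    votes = simulate_raters(
        result.episodes, result.truth_by_episode, make_panel(), seed=11
    )
    corpus = Corpus(result.episodes, classify_corpus(votes))
    table = summarize_corpus(corpus)
    for call in CATEGORIES:
        expected = sum(1 for c in corpus.classifications if c.call == call)
        assert table.counts.loc["all", call] == expected
    assert table.counts.loc["all"].sum() == len(corpus)


def test_length_statistics_definitions():
    corpus = Corpus(
        episodes=[make_episode("1", last_admin=9), make_episode("2", last_admin=4)],
        classifications=make_classified_corpus([(11, 0, 0), (0, 11, 0)]).classifications,
    )
    table = summarize_corpus(corpus)
    mean_admin, _ = table.length_stats["admin_length"]
    assert mean_admin == pytest.approx((10 + 5) / 2)
    mean_fixed, _ = table.length_stats["span_fixed_flank"]
    assert mean_fixed == pytest.approx(mean_admin + 14)
    mean_obs, _ = table.length_stats["span_observed"]
    assert mean_obs == pytest.approx((24 + 19) / 2)
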