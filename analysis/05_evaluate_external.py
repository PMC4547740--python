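"""Score external assessments against the ground truth.

Demonstrates the evaluation statistics on two mock external assessors:
a 'naive' algorithm that always answers no-change, and a 'noisy oracle'
that knows the planted truth but errs on 15% of episodes. Reports the
difficulty-weighted Concordance Score S_C for both, and a 2x2
chi-squared contrast of temporal-correlation rates between truly
planted and null episodes among the low/medium-intricacy calls.
"""

from pathlib import Path

import numpy as np

from labtempo.io_xml import read_corpus, write_external_assessment
from labtempo.model import NO_CHANGE, TEMPORAL_CORRELATION, AssessmentSet
from labtempo.stats import concordance_score, pearson_chi2_2x2

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 2028


def main() -> None:
    corpus = read_corpus(ROOT / "corpus.xml")
    ids = [c.episode_id for c in corpus.classifications]

    naive = AssessmentSet("always_no_change", {i: NO_CHANGE for i in ids})
    rng = np.random.default_rng(SEED)
    noisy = {}
    for episode in corpus.episodes:
        call = TEMPORAL_CORRELATION if episode.truth_label else NO_CHANGE
        if rng.random() < 0.15:
            call = NO_CHANGE if call == TEMPORAL_CORRELATION else TEMPORAL_CORRELATION
        noisy[episode.episode_id] = call
    noisy_set = AssessmentSet("noisy_oracle", noisy)
    write_external_assessment(noisy_set, ROOT / "external_noisy_oracle.xml")

    for assessment in (naive, noisy_set):
        report = concordance_score(assessment, corpus)
        print(f"{assessment.assessor_id}:")
        print(f"  S_C = {report.concordance_score:.4f} "
              f"(raw agreement {report.n_matched}/{report.n_compared})")
        for level, rate in report.match_rate_by_intricacy.items():
            print(f"  match rate, {level:6s} intricacy: {rate:.3f}")

    # among confident calls (low/medium intricacy), do planted curves get
    # called 'temporal correlation' more often than null curves?
    table = np.zeros((2, 2), dtype=int)
    truth = {e.episode_id: bool(e.truth_label) for e in corpus.episodes}
    for cls in corpus.classifications:
        if cls.intricacy == "high":
            continue
        row = 0 if truth[cls.episode_id] else 1
        col = 0 if cls.call == TEMPORAL_CORRELATION else 1
        table[row, col] += 1
    stat, df = pearson_chi2_2x2(table)
    n = int(table.sum())
    print("\nplanted vs null x temporal-correlation call "
          "(low/medium intricacy only):")
    print(table)
    print(f"chi2(df={df}, N={n}) = {stat:.2f}")


if __name__ == "__main__":
    main()
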