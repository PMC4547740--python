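"""Simulate the 11-rater panel and classify every episode.

Each simulated rater sees each sampled episode once and votes one of
the three nominal categories; reliability is attenuated by curve
difficulty (small planted amplitudes split the panel). Votes are then
aggregated into the majority call, the concordance value and the
rule-based intricacy, and the classified corpus (with raw votes) is
written out.
"""

from pathlib import Path

from labtempo import io_tables
from labtempo.assessment import classify_corpus
from labtempo.io_xml import read_corpus, write_corpus
from labtempo.model import Corpus
from labtempo.synth import make_panel, simulate_raters

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 2027


def main() -> None:
    corpus = read_corpus(ROOT / "corpus_unclassified.xml")
    truth = {
        eid: planted
        for (eid, _, _), planted in io_tables.read_truth(
            ROOT / "corpus_truth.tsv"
        ).items()
    }

    panel = make_panel(n_raters=11, reliability=0.9, abstain_propensity=0.25)
    votes = simulate_raters(corpus.episodes, truth, panel, seed=SEED)
    classifications = classify_corpus(votes)
    classified = Corpus(corpus.episodes, classifications, raw_votes=votes)
    write_corpus(classified, ROOT / "corpus.xml")

    n = len(classifications)
    standoffs = sum(1 for c in classifications if c.standoff)
    correct = sum(
        1
        for c, e in zip(classifications, corpus.episodes)
        if (c.call == "temporal_correlation") == bool(e.truth_label)
        and c.call != "no_assessment"
    )
    print(f"episodes classified:  {n}")
    print(f"standoffs:            {standoffs}")
    print(f"majority call agrees with planted truth: {correct}/{n} "
          f"({correct / n:.1%})")
    print(f"classified corpus written to {ROOT / 'corpus.xml'}")


if __name__ == "__main__":
    main()
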