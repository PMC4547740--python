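"""Mine solitary administration episodes from the raw event stream.

Applies the extraction funnel — run finding (at most one internal
administration-free day), 14-day isolation, five observations in each
of the before/during/after phases — then normalizes the retained lab
values to each patient's reference interval, re-anchors curves to
relative days, and samples 400 episodes into the corpus.
"""

from collections import Counter
from pathlib import Path

from labtempo import io_tables
from labtempo.io_xml import write_corpus
from labtempo.model import Corpus
from labtempo.pipeline import PipelineConfig, extract_episodes, sample_corpus

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 2026


def main() -> None:
    cohort = ROOT / "cohort"
    admins = io_tables.read_administrations(cohort / "administrations.tsv")
    observations = io_tables.read_observations(cohort / "observations.tsv")
    intervals = io_tables.read_intervals(cohort / "intervals.tsv")
    truth = io_tables.read_truth(cohort / "truth.tsv")

    config = PipelineConfig(seed=SEED)
    result = extract_episodes(admins, observations, intervals, config, truth)
    episodes = sample_corpus(result.episodes, config.sample_size, SEED)
    truth_rows = {
        e.episode_id: result.truth_by_episode[e.episode_id] for e in episodes
    }

    print(f"administration runs found:    {result.n_runs}")
    print(f"runs isolated (>=14 d free):  {result.n_isolated}")
    print(f"candidate curves (runs x parameters): "
          f"{len(result.episodes) + len(result.rejections)}")
    print(f"episodes accepted:            {len(result.episodes)}")
    by_phase = Counter(r.phase for r in result.rejections)
    for phase, n in sorted(by_phase.items()):
        print(f"  rejected for phase {phase!r}: {n}")
    print(f"episodes sampled into corpus: {len(episodes)}")

    write_corpus(Corpus(episodes=episodes), ROOT / "corpus_unclassified.xml")
    # episode-keyed truth for the assessment stage (patient/day no longer
    # meaningful on the relative-day corpus, so the key is the episode id)
    io_tables.write_truth(
        {(eid, 0, "episode"): t for eid, t in truth_rows.items()},
        ROOT / "corpus_truth.tsv",
    )
    print(f"unclassified corpus written to {ROOT / 'corpus_unclassified.xml'}")


if __name__ == "__main__":
    main()
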