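"""Tabulate the classified corpus.

Produces the calls x intricacy breakdown (counts, percent of total,
percent within each intricacy level), the episode-length statistics
under both span definitions, and the panel's Krippendorff alpha.
"""

from pathlib import Path

from labtempo.io_xml import read_corpus
from labtempo.stats import krippendorff_alpha, summarize_corpus

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    corpus = read_corpus(ROOT / "corpus.xml")
    table = summarize_corpus(corpus)

    print(f"episodes: {table.n_episodes}\n")
    print("counts (calls x intricacy):")
    print(table.counts.to_string(), "\n")
    print("percent of total:")
    print(table.percent_of_total.round(2).to_string(), "\n")
    print("percent within intricacy level:")
    print(table.percent_within_intricacy.round(2).to_string(), "\n")
    for name, (mean, sd) in table.length_stats.items():
        print(f"{name:18s} {mean:6.2f} ± {sd:.2f} days")
    alpha = krippendorff_alpha(corpus.raw_votes)
    print(f"\nKrippendorff alpha (11 raters, nominal): {alpha:.3f}")

    table.counts.to_csv(ROOT / "summary_counts.tsv", sep="\t")
    table.percent_of_total.round(4).to_csv(ROOT / "summary_percent.tsv", sep="\t")
    if table.per_parameter is not None:
        table.per_parameter.to_csv(ROOT / "summary_per_parameter.tsv", sep="\t")
    print(f"tables written to {ROOT}")


if __name__ == "__main__":
    main()
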