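"""Generate the synthetic study cohort.

Emits day-granular event tables for 60 patients over one year: drug
administration dates arranged in solitary episodes, dense-but-gappy lab
observations for three parameters on different scales, per-patient
reference intervals, and the planted ground truth (which episode/
parameter curves carry a drug response, at what amplitude).
"""

from pathlib import Path

from labtempo import io_tables
from labtempo.synth import GeneratorConfig, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 2026


def main() -> None:
    config = GeneratorConfig(seed=SEED)
    admins, observations, intervals, truth = generate_cohort(config)

    OUT.mkdir(parents=True, exist_ok=True)
    io_tables.write_administrations(admins, OUT / "administrations.tsv")
    io_tables.write_observations(observations, OUT / "observations.tsv")
    io_tables.write_intervals(intervals, OUT / "intervals.tsv")
    io_tables.write_truth(truth, OUT / "truth.tsv")

    n_effect = sum(1 for t in truth.values() if t.effect)
    print(f"patients:              {config.n_patients}")
    print(f"administration events: {len(admins)}")
    print(f"lab observations:      {len(observations)}")
    print(f"planted curves:        {len(truth)} ({n_effect} with drug response, "
          f"{n_effect / len(truth):.1%})")
    print(f"event tables written to {OUT}")


if __name__ == "__main__":
    main()
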