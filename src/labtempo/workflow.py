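"""End-to-end corpus construction: generate → extract → assess → classify.

:func:`run_pipeline` chains the synthetic generator, the episode miner,
the simulated rater panel and the vote aggregation into one
reproducible run, writing the corpus XML, the summary tables and a JSON
manifest of the stage-by-stage funnel counts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from labtempo import io_tables
from labtempo.assessment import IntricacyRule, classify_corpus
from labtempo.io_xml import write_corpus
from labtempo.model import Corpus
from labtempo.pipeline import PipelineConfig, extract_episodes, sample_corpus
from labtempo.stats import summarize_corpus
from labtempo.synth import GeneratorConfig, RaterProfile, generate_cohort, make_panel, simulate_raters


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is attached."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    generator_config: dict
    pipeline_config: dict
    n_administrations: int = 0
    n_observations: int = 0
    n_runs_found: int = 0
    n_runs_isolated: int = 0
    n_episodes_accepted: int = 0
    n_episodes_sampled: int = 0
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc

    return wrap


def run_pipeline(
    gen_config: GeneratorConfig,
    pipe_config: PipelineConfig,
    out_dir: str | Path,
    profiles: list[RaterProfile] | None = None,
    rule: IntricacyRule = IntricacyRule(),
    write_events: bool = False,
) -> RunManifest:
    """Build a classified synthetic corpus in ``out_dir``.

    The corpus is sampled down to ``pipe_config.sample_size`` when more
    episodes are accepted (and left whole otherwise), votes are
    simulated with ``profiles`` (an 11-rater default panel if omitted),
    and everything is fully determined by the two config seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles = profiles if profiles is not None else make_panel()

    admins, observations, intervals, truth = _stage("generate")(
        generate_cohort, gen_config
    )
    extraction = _stage("extract")(
        extract_episodes, admins, observations, intervals, pipe_config, truth
    )
    episodes = extraction.episodes
    if pipe_config.sample_size < len(episodes):
        episodes = _stage("sample")(
            sample_corpus, episodes, pipe_config.sample_size, pipe_config.seed
        )
    episode_truth = {
        e.episode_id: extraction.truth_by_episode[e.episode_id] for e in episodes
    }
    votes = _stage("assess")(
        simulate_raters, episodes, episode_truth, profiles, pipe_config.seed + 1
    )
    classifications = _stage("classify")(classify_corpus, votes, rule)
    corpus = Corpus(episodes=episodes, classifications=classifications, raw_votes=votes)

    manifest = RunManifest(
        generator_config=dataclasses.asdict(gen_config),
        pipeline_config=dataclasses.asdict(pipe_config),
        n_administrations=len(admins),
        n_observations=len(observations),
        n_runs_found=extraction.n_runs,
        n_runs_isolated=extraction.n_isolated,
        n_episodes_accepted=len(extraction.episodes),
        n_episodes_sampled=len(episodes),
    )

    corpus_path = out / "corpus.xml"
    _stage("write")(write_corpus, corpus, corpus_path)
    manifest.outputs["corpus"] = str(corpus_path)

    summary = summarize_corpus(corpus, pipe_config.flank_window_days)
    summary_path = out / "summary_counts.tsv"
    summary.counts.to_csv(summary_path, sep="\t")
    manifest.outputs["summary_counts"] = str(summary_path)

    if write_events:
        io_tables.write_administrations(admins, out / "administrations.tsv")
        io_tables.write_observations(observations, out / "observations.tsv")
        io_tables.write_intervals(intervals, out / "intervals.tsv")
        io_tables.write_truth(truth, out / "truth.tsv")
        manifest.outputs["administrations"] = str(out / "administrations.tsv")

    (out / "manifest.json").write_text(manifest.to_json())
    manifest.outputs["manifest"] = str(out / "manifest.json")
    return manifest
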