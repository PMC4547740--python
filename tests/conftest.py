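import numpy as np
import pytest

from labtempo.model import (
    NO_ASSESSMENT,
    NO_CHANGE,
    TEMPORAL_CORRELATION,
    Classification,
    Corpus,
    Episode,
    NormalizedPoint,
    VoteSet,
)
from labtempo.assessment import majority_call


def make_episode(episode_id="1", last_admin=9, truth_label=None, parameter_tag=None):
    """A minimal structurally valid episode: daily observations on
    [-7, last_admin + 7], administrations on every day 0..last_admin."""
    # values on the 1e-6 grid so XML round-trips are exact
    points = tuple(
        NormalizedPoint(d, round(0.5 + 0.01 * d, 6)) for d in range(-7, last_admin + 8)
    )
    return Episode(
        episode_id=str(episode_id),
        administration_days=frozenset(range(last_admin + 1)),
        points=points,
        truth_label=truth_label,
        parameter_tag=parameter_tag,
    )


def make_votes(episode_id, n_tc=0, n_nc=0, n_na=0):
    votes = (
        [(f"r{i:02d}", TEMPORAL_CORRELATION) for i in range(n_tc)]
        + [(f"r{i + n_tc:02d}", NO_CHANGE) for i in range(n_nc)]
        + [(f"r{i + n_tc + n_nc:02d}", NO_ASSESSMENT) for i in range(n_na)]
    )
    return VoteSet(episode_id=str(episode_id), votes=tuple(votes))


def make_classified_corpus(compositions, with_votes=True):
    """Corpus with one episode per (n_tc, n_nc, n_na) vote composition."""
    episodes, classifications, votesets = [], [], []
    for i, (tc, nc, na) in enumerate(compositions, start=1):
        episodes.append(make_episode(i))
        vs = make_votes(i, tc, nc, na)
        votesets.append(vs)
        classifications.append(majority_call(vs))
    return Corpus(
        episodes=episodes,
        classifications=classifications,
        raw_votes=votesets if with_votes else None,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort shared by pipeline-level tests."""
    from labtempo.synth import GeneratorConfig, generate_cohort

    config = GeneratorConfig(n_patients=15, span_days=200, seed=42)
    return config, generate_cohort(config)
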