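"""Synthetic EHR event streams and simulated rater panels.

The generator emulates the statistical shape the extraction pipeline
assumes, on an integer day grid:

* per patient, alternating solitary administration episodes (5-14
  administration days, at most one internal administration-free day)
  and long administration-free gaps;
* per patient and lab parameter, a patient-specific reference interval
  jittered around population bounds, and a wandering baseline modelled
  as first-order autoregressive noise around a mean inside the
  interval;
* with probability ``p_effect`` per (episode, parameter) curve, a drug
  response: a signed shift of configurable amplitude (in units of the
  reference-interval width) ramping up over two days after a short lag,
  holding while administration continues, and decaying exponentially
  (half-life three days) afterwards.

Rater simulation replaces the human expert panel: each rater votes the
correct substantive category with probability
``reliability * (1 - difficulty)``, abstains out of the remaining mass
in proportion to an abstention propensity, and otherwise votes the
wrong substantive category. Difficulty falls linearly with planted
amplitude and reaches zero at ``amp_easy``, so large effects are
unambiguous while marginal ones split the panel — which is what
produces a spread of intricacy levels downstream.

None of the defaults are estimates of any real corpus; they are chosen
to exercise the pipeline under plausible conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from labtempo.model import (
    NO_CHANGE,
    TEMPORAL_CORRELATION,
    NO_ASSESSMENT,
    AdministrationEvent,
    Episode,
    LabObservation,
    ReferenceInterval,
    VoteSet,
)
from labtempo.pipeline import ConfigurationError


@dataclass(frozen=True)
class ParameterSpec:
    """Population reference bounds for one lab parameter.

    ``jitter_frac`` scales the per-patient perturbation of both bounds,
    as a fraction of the population interval width.
    """

    parameter_id: str
    lower: float
    upper: float
    jitter_frac: float = 0.1


def _default_parameters() -> list[ParameterSpec]:
    # three generic parameters on different scales
    return [
        ParameterSpec("PAR_A", 30.0, 120.0),
        ParameterSpec("PAR_B", 3.5, 5.1),
        ParameterSpec("PAR_C", 135.0, 145.0),
    ]


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generation settings; all day quantities are integers.

    Probabilities are per-day (``p_obs``) or per-curve (``p_effect``);
    ``effect_amplitude`` is in units of the reference-interval width.
    """

    n_patients: int = 60
    span_days: int = 365
    parameters: list[ParameterSpec] = field(default_factory=_default_parameters)
    admin_episode_length: tuple[int, int] = (5, 14)
    admin_gap_rate: float = 0.15
    inter_episode_gap: tuple[int, int] = (20, 45)
    p_obs: float = 0.7
    p_effect: float = 0.33
    effect_amplitude: tuple[float, float] = (0.5, 1.5)
    effect_lag_days: tuple[int, int] = (0, 3)
    ar_coefficient: float = 0.7
    noise_sd_frac: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("admin_gap_rate", "p_obs", "p_effect"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        for name in ("admin_episode_length", "inter_episode_gap", "effect_lag_days"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} range ({lo}, {hi}) is empty")
        if self.span_days < 2 * 14 + self.admin_episode_length[1]:
            raise ConfigurationError(
                f"span_days={self.span_days} too short: need at least "
                f"{2 * 14 + self.admin_episode_length[1]} days for one "
                "isolated episode"
            )
        if not self.parameters:
            raise ConfigurationError("at least one lab parameter required")


@dataclass(frozen=True)
class PlantedEffect:
    """Ground truth for one (episode, parameter) curve."""

    effect: bool
    amplitude: float = 0.0
    lag_days: int = 0
    sign: int = 1


@dataclass(frozen=True)
class RaterProfile:
    rater_id: str
    reliability: float
    abstain_propensity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.reliability <= 1.0:
            raise ConfigurationError("reliability must be in [0, 1]")
        if not 0.0 <= self.abstain_propensity <= 1.0:
            raise ConfigurationError("abstain_propensity must be in [0, 1]")


def make_panel(
    n_raters: int = 11, reliability: float = 0.9, abstain_propensity: float = 0.25
) -> list[RaterProfile]:
    """A homogeneous rater panel (defaults mirror an 11-expert panel)."""
    return [
        RaterProfile(f"r{i + 1:02d}", reliability, abstain_propensity)
        for i in range(n_raters)
    ]


def _episode_days(rng: np.random.Generator, start: int, config: GeneratorConfig) -> list[int]:
    lo, hi = config.admin_episode_length
    length = int(rng.integers(lo, hi + 1))
    days = list(range(start, start + length))
    if length >= 3 and rng.random() < config.admin_gap_rate:
        # at most one internal administration-free day
        skip = int(rng.integers(1, length - 1))
        days.remove(start + skip)
    return days


def _effect_curve(
    days: np.ndarray, first: int, last: int, planted: PlantedEffect, width: float
) -> np.ndarray:
    """Additive drug response on absolute-day grid ``days``."""
    if not planted.effect or planted.amplitude == 0.0:
        return np.zeros(len(days), dtype=float)
    onset = first + planted.lag_days
    full = planted.sign * planted.amplitude * width
    shift = np.zeros(len(days), dtype=float)
    for i, d in enumerate(days):
        if d < onset:
            continue
        if d <= last:
            ramp = min(1.0, (d - onset + 1) / 2.0)  # 2-day linear ramp
            shift[i] = full * ramp
        else:
            shift[i] = full * math.exp(-math.log(2.0) * (d - last) / 3.0)
    return shift


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[
    list[AdministrationEvent],
    list[LabObservation],
    list[ReferenceInterval],
    dict[tuple[str, int, str], PlantedEffect],
]:
    """Generate a reproducible synthetic cohort.

    Returns administration events, lab observations, per-patient
    reference intervals, and the planted ground truth keyed by
    ``(patient_id, episode first day, parameter_id)``. Every planted
    episode is isolated by construction when ``inter_episode_gap``
    starts at 15 or more.
    """
    rng = np.random.default_rng(config.seed)
    administrations: list[AdministrationEvent] = []
    observations: list[LabObservation] = []
    intervals: list[ReferenceInterval] = []
    truth: dict[tuple[str, int, str], PlantedEffect] = {}

    gap_lo, gap_hi = config.inter_episode_gap
    for p in range(config.n_patients):
        patient_id = f"p{p + 1:04d}"
        # place administration episodes along the span
        episodes: list[list[int]] = []
        cursor = 15 + int(rng.integers(0, 11))
        while True:
            days = _episode_days(rng, cursor, config)
            if days[-1] + 15 > config.span_days:
                break
            episodes.append(days)
            cursor = days[-1] + 1 + int(rng.integers(gap_lo, gap_hi + 1))
        for days in episodes:
            administrations.extend(AdministrationEvent(patient_id, d) for d in days)

        all_days = np.arange(config.span_days)
        for spec in config.parameters:
            width = spec.upper - spec.lower
            jitter = spec.jitter_frac * width
            lower = spec.lower + rng.uniform(-jitter, jitter)
            upper = spec.upper + rng.uniform(-jitter, jitter)
            if upper - lower < 0.5 * width:
                upper = lower + 0.5 * width
            w = upper - lower
            intervals.append(ReferenceInterval(patient_id, spec.parameter_id, lower, upper))

            mean = rng.uniform(lower + 0.2 * w, upper - 0.2 * w)
            noise = np.empty(config.span_days)
            noise[0] = rng.normal(0.0, config.noise_sd_frac * w)
            innovations = rng.normal(
                0.0, config.noise_sd_frac * w, size=config.span_days - 1
            )
            for t in range(1, config.span_days):
                noise[t] = config.ar_coefficient * noise[t - 1] + innovations[t - 1]
            baseline = mean + noise

            shift = np.zeros(config.span_days)
            for days in episodes:
                first, last = days[0], days[-1]
                if rng.random() < config.p_effect:
                    planted = PlantedEffect(
                        effect=True,
                        amplitude=float(
                            rng.uniform(*config.effect_amplitude)
                        ),
                        lag_days=int(
                            rng.integers(
                                config.effect_lag_days[0],
                                config.effect_lag_days[1] + 1,
                            )
                        ),
                        sign=int(rng.choice([-1, 1])),
                    )
                else:
                    planted = PlantedEffect(effect=False)
                truth[(patient_id, first, spec.parameter_id)] = planted
                shift += _effect_curve(all_days, first, last, planted, w)

            observed = rng.random(config.span_days) < config.p_obs
            values = baseline + shift
            for day in np.nonzero(observed)[0]:
                observations.append(
                    LabObservation(
                        patient_id, spec.parameter_id, int(day), float(values[day])
                    )
                )
    return administrations, observations, intervals, truth


def _difficulty(
    planted: PlantedEffect | None,
    difficulty_max: float,
    amp_easy: float,
    null_difficulty: float,
) -> float:
    if planted is None or not planted.effect:
        return null_difficulty
    return difficulty_max * max(0.0, 1.0 - planted.amplitude / amp_easy)


def simulate_raters(
    episodes: list[Episode],
    truth: dict[str, PlantedEffect],
    profiles: list[RaterProfile],
    seed: int,
    *,
    difficulty_max: float = 0.6,
    amp_easy: float = 1.0,
    null_difficulty: float = 0.15,
) -> list[VoteSet]:
    """Simulate a rater panel voting on every episode.

    ``truth`` maps episode id to its planted effect; the correct
    substantive category is ``temporal_correlation`` for a planted
    effect and ``no_change`` otherwise. Each rater votes correctly with
    probability ``reliability * (1 - difficulty)``; of the remaining
    probability mass, a fraction ``abstain_propensity`` abstains
    (``no_assessment``) and the rest votes the wrong substantive
    category. Abstention therefore rises with the propensity and falls
    with planted amplitude.
    """
    if not profiles:
        raise ConfigurationError("need at least one rater profile")
    missing = [e.episode_id for e in episodes if e.episode_id not in truth]
    if missing:
        raise ConfigurationError(
            f"episodes without a truth flag: {missing[:5]}"
        )
    rng = np.random.default_rng(seed)
    votesets: list[VoteSet] = []
    for episode in episodes:
        planted = truth[episode.episode_id]
        correct = TEMPORAL_CORRELATION if planted.effect else NO_CHANGE
        wrong = NO_CHANGE if planted.effect else TEMPORAL_CORRELATION
        d = _difficulty(planted, difficulty_max, amp_easy, null_difficulty)
        votes = []
        for profile in profiles:
            p_correct = profile.reliability * (1.0 - d)
            p_abstain = (1.0 - p_correct) * profile.abstain_propensity
            u = rng.random()
            if u < p_correct:
                category = correct
            elif u < p_correct + p_abstain:
                category = NO_ASSESSMENT
            else:
                category = wrong
            votes.append((profile.rater_id, category))
        votesets.append(VoteSet(episode_id=episode.episode_id, votes=tuple(votes)))
    return votesets
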