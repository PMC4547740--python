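# Methods

## The corpus model

A ground-truth corpus is a set of *episodes*, each one solitary run of
drug administration days together with one lab parameter's normalized
curve on a relative-day axis, plus a per-episode panel classification.
The structural rules an episode must satisfy are:

- relative day 0 is the first administration day;
- consecutive administration days are separated by at most one
  administration-free day (one tolerated skip inside a run);
- the run is isolated: no administration within 14 days before its
  first or after its last day (enforced at extraction time, not
  recorded in the episode itself);
- at least 5 lab observations in each phase — *before* (relative days
  −7…−1), *during* (0…last administration day), and *after* (the 7
  days following the last administration day);
- no retained observation outside the union of those windows.

The 14-day isolation and 7-day flanks mean the corpus can only express
drug responses that begin within a week of the exposure window; slower
reactions are out of scope of this data model by construction.

Normalization is the affine map `(value − lower) / (upper − lower)`
per patient and parameter. It is deliberately not clamped: values
below the reference interval are negative, values above exceed 1, and
because the map is affine it preserves curve shape exactly (this is
property-tested). Serialized curves carry six decimal places; that is
a file-format resolution, far below any clinically meaningful
difference on this scale.

### Vote aggregation

With 11 raters and 3 categories a strict majority call always has at
least 5 agreeing votes, so the concordance value c_i lies in
[5/11, 1] for any non-standoff call (verified by enumerating all 78
vote compositions). Standoffs are recorded as `no_assessment` with the
tied maximum as the concordance numerator and a separate flag — the
call type must be total even though a tie is rare in practice. The
concordance denominator is always the full panel size; abstaining
raters are not removed.

Intricacy thresholds are absolute counts (low ≥ 10, medium 8–9, high
≤ 7 of 11). For reuse with other panel sizes an optional fractional
mode rescales them proportionally; the absolute mode is the default
because the thresholds are defined, not estimated.

### Evaluation statistics

- **Concordance Score** `S_C = Σ m_i·c_i / Σ c_i`. When all c_i are
  equal it reduces to raw percent agreement; flipping any mismatch to a
  match strictly increases it. By default the external assessment must
  cover every corpus episode (partial coverage is a hard error, with an
  explicit `restrict` opt-out) so scores are never silently computed on
  a subset.
- **Krippendorff's α**, nominal metric, coincidence-matrix estimator.
  Units with fewer than two votes are skipped; α is reported as
  *undefined* (an exception, never a number) when every pairable vote
  falls in one category, since the expected-disagreement denominator is
  then zero. The test suite cross-checks the estimator against an
  independent exact-fraction pairwise-disagreement implementation and
  against a brute-force-constructed matrix with α exactly 0. Note that
  duplicating all units changes α slightly (the finite-sample n−1
  correction); invariance under duplication is only asymptotic.
- **Pearson χ²** on 2×2 tables uses the closed form
  `N(ad−bc)² / ((a+b)(c+d)(a+c)(b+d))` with df = 1 and *no* continuity
  correction; the uncorrected form is the one consistent with the
  reference contingency analyses this package mirrors, and scipy with
  `correction=False` is the test oracle.

### Episode length

"Administration length" is counted inclusively (a run over days 0–9 is
10 days). For the overall episode span two definitions are reported,
because they genuinely differ on gappy data: `span_fixed_flank`
(administration length + both 7-day windows) and `span_observed`
(first to last retained observation day, inclusive). Corpus summaries
always print both.

## The synthetic cohort generator

The generator exists to exercise the pipeline under known ground
truth, not to estimate any real population. Defaults (all exposed on
`GeneratorConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_patients` / `span_days` | 60 / 365 | cohort size and record span |
| `admin_episode_length` | 5–14 d | administration-run length (uniform) |
| `admin_gap_rate` | 0.15 | probability a run contains its one tolerated internal skip |
| `inter_episode_gap` | 20–45 d | administration-free gap between runs (≥ 15 guarantees isolation) |
| `p_obs` | 0.7 | per-day lab-sampling probability (dense but gappy) |
| `p_effect` | 0.33 | probability a (run × parameter) curve carries a drug response |
| `effect_amplitude` | 0.5–1.5 | response size in reference-interval widths |
| `effect_lag_days` | 0–3 d | onset delay after day 0 |
| `ar_coefficient`, `noise_sd_frac` | 0.7, 0.15 | baseline AR(1) dynamics |

Baselines are AR(1) around a patient-specific mean drawn inside the
(jittered) reference interval; the coefficient 0.7 with innovation s.d.
0.15 interval-widths produces visually plausible wandering curves. A
planted response ramps linearly to full amplitude over 2 days
(starting after the lag), holds while administration continues, and
decays exponentially with a 3-day half-life afterwards — any monotone
on/off shape would do for testing temporal-correlation detectors, and
this one is simple and smooth. Response sign is random, since drugs
can push parameters in either direction. The 33% effect rate was
chosen as the regime of interest for a corpus in which roughly a third
of curves show a correlation; 0.7 daily sampling makes phase-count
rejections common enough that the funnel is actually exercised.

The generator emulates: solitary episode structure, daily-scale
observation gaps, reference-interval heterogeneity across patients,
and effect-size-dependent assessability. It does **not** emulate dose,
confounders (co-medication, therapies), within-day dynamics,
parameter-specific pharmacology, or informative sampling (sicker
patients being measured more often). Tests passing on this generator
therefore certify the pipeline's bookkeeping and statistics, not
clinical validity on real EHR data.

### Simulated raters

Each rater votes the correct substantive category
(`temporal_correlation` if an effect was planted, else `no_change`)
with probability `reliability × (1 − d)`, where the difficulty `d`
falls linearly with planted amplitude, `d = d_max·max(0, 1 −
amplitude/amp_easy)` with `d_max = 0.6`, `amp_easy = 1.0`: a one
interval-width response is unambiguous (`d = 0`), marginal responses
split the panel — which is what generates the spread of concordance
values and intricacy levels downstream. The linear ramp (rather than a
logistic) is deliberate so that difficulty reaches exactly zero for
large effects and a perfectly reliable panel is exactly unanimous.
Null curves get a small fixed difficulty `d_null = 0.15`, reflecting
that baseline wander occasionally imitates a response. Of the
non-correct probability mass, a fraction `abstain_propensity`
(default 0.25) abstains; abstention thus rises with the propensity and
falls with amplitude.

## Numerical and design choices

- Duplicate lab values on one (patient, parameter, day): the
  last-read value wins, with a logged warning — daily-scale data
  admits one value per day and the inputs carry no timestamps to
  arbitrate with.
- Record boundaries: absence of recorded administrations counts as
  administration-free when checking isolation (anonymized extracts
  have no enrollment notion); `strict_boundaries` mode instead
  requires the isolation window to lie inside the patient's observed
  record span.
- Corpus sampling sorts episodes by id before seeding the RNG, so the
  selection is independent of input order and platform.
- XML output is deterministic (fixed element order, fixed decimal
  formatting): writing the same corpus twice is byte-identical, and
  write→read→write is a fixed point.
- No minimum administration length is enforced; it arises implicitly
  from requiring 5 during-phase observations.
- Seeds: every stochastic stage (generation, sampling, rater
  simulation) takes an explicit integer seed; the workflow derives the
  rater seed as pipeline seed + 1 so stages are decoupled but jointly
  reproducible.

Problem sizes in the shipped analyses and tests — 60 patients × 1
year × 3 parameters, 400-episode corpora, 500-stream oracle
comparisons — keep the full suite in the seconds range while leaving
every funnel stage non-trivially populated.

## Known limitations

- Single-drug semantics: isolation is evaluated against the one
  administration stream; multi-drug interaction windows are out of
  scope.
- The rater model is homogeneous per panel by default and ignores
  rater covariates; systematic rater bias (e.g. one rater always
  abstaining on negative-going curves) is not modeled.
- α on corpora with strongly varying item difficulty is hard to
  interpret — that is precisely the motivation for the
  difficulty-weighted S_C, and the package reports α for completeness
  rather than as a quality gate.
- The synthetic generator's parameters are package choices, not
  estimates of any real corpus; numbers computed on synthetic corpora
  (call rates, α, length statistics) characterize the simulation
  conditions only.
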