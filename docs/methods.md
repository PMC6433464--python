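# Methods

## Data model

An **ethogram** is one subject-trial's per-second label series over a trial
phase (default 1200 s = 20 min). Seconds are 0-based and each second
carries exactly one label: a catalogue behavior or the reserved `NONE`
token for unscored time. `NONE` is never a state of the sequence analysis;
it only separates bouts. Bout spans are half-open `[start_s, end_s)` in
integer seconds, which makes durations exact differences and removes
off-by-one ambiguity. Simultaneous behaviors are treated as an input error
unless the caller supplies an explicit priority ordering, since manual
scoring of this kind is mutually exclusive by construction but no tie rule
is standard.

Four built-in seven-behavior catalogues cover the scored roles of the
paradigm (resident vs. female intruder, female intruder, resident vs. male
intruder, male intruder); each has four interactive and three individual
behaviors (drinking, grooming, eating). Catalogue order is load-bearing:
it fixes matrix axis order and the layout of flattened vectors, so vectors
are elementwise comparable across subjects and conditions. When food is
absent, `eating` is dropped and all analyses run over the remaining
six-behavior alphabet.

The keystroke-log adapter (`from_jwatcher_events`) collapses timestamped
onset events to per-second labels by onset-persistence: an event starts a
state that persists until the next event or an explicit stop code, and a
second takes the state active at its start. This rule is a documented
convention of the adapter, not a property of the source format.

## Sequence analysis

The analysis is deliberately **time-agnostic**: bout durations and
inter-bout intervals are discarded, leaving only the order of bouts.
Transitions are counted **per bout pair** (not per second); a sequence of
`n` bouts yields exactly `n − 1` transitions. Observed same-behavior
"self-transitions" are a direct consequence of bout segmentation: two
eating bouts separated by an unscored gap count as an eating→eating
transition.

Normalization is within-animal, removing inter-animal variability in bout
number. The default mode is **row-conditional** (each observed row is the
probability distribution over the next behavior): stereotyped chains such
as chasing→attack can then approach 1.0, which matches how near-1.0
transition frequencies are naturally read. A **global** mode (all entries
sum to 1) is provided and selectable. Subjects with fewer than two bouts
have no transitions; their matrix is flagged *undefined* and excluded from
group averages and divergences with a logged count, rather than entering
as a spurious all-zero pattern.

**Divergence** is the cosine distance between row-major flattened matrices,
computed within subject against that subject's Fed-state matrix (one
distance per non-Fed condition). Cosine distance ignores vector magnitude,
so it compares the *pattern* of transitions rather than their volume; for
nonnegative frequency vectors it lies in `[0, 1]`. A zero-norm vector has
no direction, so its distance is an error, not 0 or 1. Per-subject
matrices come from the single trial per condition; averaging multiple
trials per subject before the distance is available through
`average_matrices` but is not the default.

## Feeding metrics

Pellet mass is fixed at 0.02 g (configurable), so five pellets equal the
0.1 g homeostatic threshold. Only video-confirmed, subject-attributed
pellets count by default. Latency-to-threshold is the retrieval time of
the threshold-th confirmed pellet, right-censored at phase end; censored
animals keep the censor time as their reported latency and are **excluded
from latency means but retained in fraction-reached curves**, which is the
only convention that leaves the curve's denominator stable. The group
curve is the fraction of subjects past threshold as a non-decreasing step
function; a mean-cumulative-pellet-count curve is provided as an
alternative summary. Phase tables enforce structural zeros: no pellets in
the pre phase (food inaccessible) and none in food-absent trial contexts.

## Statistics

Duration regressions are ordinary least squares with Pearson `r` and a
two-sided p-value from the t transform of `r` (via `scipy.stats.linregress`),
reported per panel without multiplicity correction; a Bonferroni helper
exists for callers who test families of pairs. Inter-rater reliability is
the second-by-second confusion matrix over the alphabet plus `NONE`;
**coherence** is 100 × diagonal/total. Seconds both scorers left unscored
are excluded by default (`include_none=False`): agreeing that nothing
scorable happened inflates agreement, and the appropriate denominator is
genuinely ambiguous, so both variants are computable.

## Synthetic generator

The generator is **semi-Markov at the bout level**: a Markov chain over
behaviors (the exact quantity the transition analysis estimates), with
geometric bout durations (support ≥ 1 s, per-behavior mean) and geometric
`NONE`-gap durations (support ≥ 0 s). Geometric is the discrete memoryless
family — the minimal one-parameter choice; the distribution family is an
implementation detail behind the kernel interface. A transition is
gap-mediated with probability `gap_prob`; because two same-label bouts are
only distinct across a gap, kernels with diagonal mass require
`gap_prob = 1`, and a drawn self-transition whose gap came out 0 s is given
a 1 s gap so that it remains observable (otherwise recovery of diagonal
mass would be biased low). Single-behavior kernels are exempt: with one
state there is nothing to transition to, and a gapless single-state kernel
legitimately produces one continuous bout.

Pellet events are a Bernoulli thinning of eating-labeled seconds (rate =
probability per eating second, default 0.06), with the event time uniform
inside its second — at the sated baseline this yields intake on the order
of five pellets per 20 min trial.

**Condition presets** encode hunger as a scalar intensity per condition
(Fed 0, Fasted18 0.35, Fasted48 0.70, FedAgRP_CS 0.85, FedAgRP_PS 0.45).
Each kernel row shares a vector of behavior-attraction weights: the eating
weight and eating bout duration rise with hunger, interactive weights fall
steeply with hunger when food is present and barely when it is absent, and
eating has a hunger-scaled self-transition boost. These parameter values
are this package's own choices — no generative parameters exist to fit —
and they target *qualitative orderings only*: intake ordered
Fed < Fasted18 < Fasted48, social duration negatively related to intake,
and Fed-divergences smaller without food than with it. Without an intruder
the scored repertoire shrinks to the three individual behaviors and gaps
lengthen to a 12 s mean (rest and locomotion are unscored), keeping sated
home-cage intake near the five-pellet level. Passing tests on these
cohorts show the *pipeline* recovers the structure the generator put in;
they cannot certify effect sizes in real scored data, which the generator
does not model (no drift within trial, no animal-specific repertoires, no
scorer noise except where explicitly injected).

Seeding: one master seed spawns independent per-subject × per-condition
streams (`numpy` `SeedSequence.spawn`), so cohorts are reproducible
subject-by-subject and enlarging the cohort does not reshuffle existing
subjects' data.

## Numerical choices

- Row sums and global mass are validated to 1 ± 1e-9; cosine distance
  clips the negative rounding error at 0 for identical directions.
- Kernel-recovery error is the **mean absolute elementwise error over the
  estimate's observed rows** (unvisited rows carry no information and are
  excluded). On this statistic, 7-state kernels recover to < 0.05 by 10⁴
  bouts and the error decreases from 10² to 10⁴ bouts.
- The identical-kernel cosine noise floor depends on kernel concentration:
  diffuse kernels sit near 0.03–0.06 at 10³ bouts, stereotyped kernels
  (dominant next-behavior probability ≈ 0.8) below 0.01.
- Flattening is row-major in catalogue order, fixed across the package.
- The pipeline's `summary.json` is written with sorted keys and rounded
  floats, so a fixed config + seed reproduces it byte-identically.

## Problem sizes

Unit and property tests run on barcodes of 10²–10³ s and sequences up to
500 labels; recovery experiments use 10²–10⁴ bouts; cohort-level checks
use n = 16 subjects × 5 conditions × 1200 s, the cohort size and trial
length of the paradigm. The acceptance script uses these same sizes.

## Known limitations

- Higher-order (k > 1) dependence, dwell-time-resolved transition models,
  and omnibus multi-condition hypothesis tests are out of scope.
- The intruder's behavior is simulated independently of the resident's; no
  two-agent coupling.
- Preset realism cannot be calibrated against deposited data; only the
  qualitative orderings above are claimed.
- The keystroke adapter's onset-persistence rule is one of several
  defensible collapses of event logs to per-second labels.
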