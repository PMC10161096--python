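# Methods

`setshift` is a simulation-plus-analytics pipeline for a two-task touchscreen
battery used to separate cognitive flexibility from attentional filtering in
nonhuman primates. It generates the tasks' trial-level structure, simulates a
dose-modulated reinforcement-learning agent in place of the animals, and
computes the behavioral metrics and dose-condition statistics of such studies.
This note documents the models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic data can and cannot show.

## Task models

**Feature-reward learning (FRL).** A daily session holds 21 blocks. In each
block a single feature value (e.g. `red`) is the target; choosing the object
that carries it is rewarded with probability 0.85 (incorrect choices are
never rewarded by default; the complement probability is configurable via
`reward_prob_other`). Every trial shows 3 objects that vary in one feature
dimension (low distractor load) or two (high load, default probability 0.5
per block) and share no feature values; non-varying dimensions are held at a
neutral block context and omitted from the symbolic objects. Blocks switch
once at least `min_trials` (35, 40 or 45, re-jittered uniformly per block)
are complete and accuracy over the previous 10 trials is >= 80%, or
unconditionally after 60 trials. Between consecutive blocks the new target
dimension is drawn with equal weight from the previous target dimension
(intradimensional switch), a previous distractor dimension (extradimensional
— only available after high-load blocks), or an unseen dimension
(novel-dimension); the new target value always differs from the old one.
Novel-dimension transitions are generated but excluded from headline switch
contrasts.

**Visual search (VS).** One block precedes and one follows the FRL blocks.
A target defined by exactly 3 features from 3 dimensions is shown alone for
10 familiarization trials and then hidden among 3, 6, 9 or 12 distractors
for 100 search trials. Set sizes are counterbalanced in shuffled groups of
four, so each occurs exactly 25 times per block. Each distractor shares 0, 1
or 2 of the target's features (drawn uniformly by default). Trial similarity
is the mean shared-feature count, binned at tercile edges 2/3 and 4/3 into
low/medium/high. The two blocks use backgrounds drawn without replacement
from a set of five. Stimuli are symbolic feature bundles; rendering, touch
physics and reward magnitudes are out of scope, and trial timing constants
(0.3–0.5 s hold, 5 s response window) are carried as metadata only.

The feature space defaults to four dimensions (color, pattern, shape, arms)
with nine values each; every value belongs to exactly one dimension and each
dimension needs at least three values so that disjoint three-object displays
exist.

## The synthetic agent

The agent is a generative stand-in for the animals, not a mechanistic claim
about muscarinic physiology. Its learning rule is a feature-value delta rule
with attention-augmented forgetting: after choosing an object, each of its
feature values `f` updates as `v[f] += eta * (reward - v[f])`, while the
features of non-chosen displayed objects decay as `v[f] *= (1 - omega)`.
With rewards in {0, 1} and values initialized in [0, 1] all values stay in
[0, 1]. Values carry over across blocks by default (`carry_values`), which
is what makes perseveration on the previous block's target possible.

Choice is softmax with inverse temperature `beta` over object utilities
(summed feature values plus a perseveration bias), mixed with a uniform
lapse of probability `epsilon_lapse`. The perseveration bias is
`kappa_persev` times a choice trace: an exponentially decaying memory of
chosen features (decay `persev_decay` per trial; at `persev_decay = 1` the
trace reduces to the classic one-previous-trial repetition count).

**Response times.** `rt = rt_base + rt_conflict * g * H + noise`, where `H`
is the entropy of the lapse-free softmax distribution normalized to [0, 1]
and `g` is a deliberation gate — a running average of unrewarded outcomes
updated at rate `rt_outcome_rate` and initialized at 1 (so a fresh agent's
RT is exactly `rt_base + rt_conflict * H`). The gate implements post-error
slowing: responding stays fast while the current policy keeps paying off,
slows as errors accumulate after an uncued block switch, and speeds up once
the new rule is learned. Without it, conflict alone cannot produce the
characteristic fast–slow–fast within-block RT trajectory, because entropy is
maximal at the ignorant block start; with it, the smoothed mean RT curve has
an interior maximum around trials 5–10 and declines thereafter (verified as
a simulation property). Gaussian noise (`rt_noise_sd`) is truncated at a
100 ms floor.

**Visual search behavior** is a minimal model sufficient to exercise the VS
metrics: the familiarized target is recognized unless the agent lapses or is
captured by a distractor, with per-distractor capture probability
`vs_confusion * (1 + shared features)`; search time is linear in set size
(`vs_rt_per_distractor`, default 57 ms per distractor) plus a similarity
term and noise; familiarization trials have their own fast RT distribution.

**Defaults.** `eta = 0.08`, `omega = 0.10`, `beta = 3.0`,
`kappa_persev = 0.4`, `persev_decay = 0.3`, `epsilon_lapse = 0.05`,
`rt_base = 820 ms`, `rt_conflict = 350 ms`, `rt_outcome_rate = 0.2`. These
were chosen once so that the vehicle condition reproduces the qualitative
profile of healthy macaques on this battery: median trials-to-criterion
about 11 at low load and 13–14 at high load, nearly all blocks reaching
criterion, plateau accuracy about 0.8, an RT inflection around trials 6–9,
and search accuracy declining from the mid-90s to the mid-80s percent as
set size grows from 3 to 12.

**Dose modulation.** A dose condition multiplies `(eta, omega)` through a
configurable `DoseMap`. The default is an inverted-U over the labels
vehicle/0.3/1/3 with multipliers (1.0, 1.10, 1.70, 1.05): the middle dose
markedly accelerates both learning from chosen features and unlearning of
unattended ones, flanked by small (0.3) and negligible (3) effects. The
flank magnitudes matter: session-median trials-to-criterion has an SD of
about 3 trials across sessions, so at the study design's cell sizes (4
subjects x 7 sessions per condition) a flank effect larger than roughly 1.5
trials would itself reach Tukey significance and destroy the selective
middle-dose pattern the map is meant to emulate. The map is an emulation
device, not a pharmacokinetic model, and is fully configurable.

## Metrics

* **Trials-to-criterion**: the smallest trial `t` such that accuracy over
  the *complete* window of the 10 subsequent trials exceeds 70%. Blocks too
  short to host the window at `t` cannot certify criterion there; blocks
  with no qualifying trial are censored — excluded from medians but counted
  in the proportion-reaching-criterion metric.
* **Learning curves**: across-block mean accuracy per trial since block
  start; trials 1–3 raw, later trials smoothed with a centered 5-trial
  moving average (width configurable; edges truncated).
* **Plateau accuracy**: mean accuracy over trials strictly after
  `t + 10`; undefined for censored blocks or when no post-window trials
  exist.
* **RT inflection**: on a smoothed RT curve, the first trial `t >= 3`
  (trial 2 is excluded by convention) where the curve falls below its
  predecessor and keeps falling for 2 consecutive steps (run truncated at
  the end of the data); censored for flat or rising curves.
* **Switch costs**: trials-to-criterion grouped by transition type; first
  blocks always excluded, novel-dimension transitions excluded from
  headline contrasts by default.
* **Perseverative errors**: an error trial is perseverative when the chosen
  object repeats a feature value chosen-and-unrewarded earlier in the same
  block, classified by whether that feature's dimension is the block's
  target dimension or a distractor dimension (a trial repeating both kinds
  counts in both classes). Because the field is inconsistent about the
  denominator, both conventions are always computed — proportion of all
  trials (default) and proportion of error trials.
* **Search metrics**: per-set-size accuracy and correct-trial search time
  with ordinary least-squares set-size slopes (per session and block
  position; sessions missing a set size are fitted on the available sizes
  and flagged), similarity-condition means, and speed of processing (mean
  familiarization RT).
* **Session thirds**: blocks 1–7, 8–14, 15–21.

## Statistics

Dose contrasts use a one-way ANOVA across the four conditions with
`eta^2 = SS_between / SS_total`, Tukey HSD over all pairs (vehicle contrasts
highlighted), and Cohen's d versus vehicle with pooled (n−1)-weighted SD and
sign condition − vehicle, so improvements that reduce a metric are negative.
Tables with zero variance everywhere are flagged degenerate rather than
fitted. The mixed model on per-block trials-to-criterion fits dose (vehicle
reference) and dose x session-third fixed effects with a subject random
intercept plus a session-within-subject variance component; this
random-effects structure is a documented package choice, and on a singular
fit the session component is dropped with a flag. Fisher's r-to-z compares
two independent correlations with the standard normal reference.

Under a simulated null the ANOVA's type-I error is calibrated at 5% and the
Tukey-adjusted vehicle contrasts stay at or below the nominal familywise
level (1,000-replicate check in the test suite).

## What the synthetic data do and do not show

The generator reproduces the statistical structure the analyses assume:
criterion-crossing learning curves, jittered block lengths, ID/ED/novel
transition taxonomy, perseverative repeats, non-monotonic RT trajectories,
counterbalanced set sizes, similarity-graded search errors, and an
inverted-U dose response. Passing tests therefore certify the *operators
and pipeline*, not any animal result: the agent is one convenient generative
model, its dose map is invented, and real behavioral data would add
features the generator omits (motivational drift, session-level
autocorrelation, motor variability, aborted trials, individual strategy
differences). Headline numbers from the animal study (e.g. specific F
statistics or trial counts) are not reproduction targets of this package.

## Problem sizes and numerics

Simulation-based tests use 5–30 sessions per check and 12 sessions for
likelihood-based parameter recovery (coarse grid seeding a Nelder–Mead
polish over bounded `(eta, beta)`); the end-to-end dose-response check runs
five replicate experiments of 4 subjects x 7 sessions x 4 conditions. All
randomness flows through seeded NumPy generators; identical configuration
and seed reproduce identical trial logs byte-for-byte. Ties in the softmax
are resolved by sampling; RT floors at 100 ms avoid non-physical values;
empty outcome sequences leave a block in the `continue` state.
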