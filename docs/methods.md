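# Methods

## The model

`attachinf` simulates the formation of infant attachment as *active
inference*: the infant is a discrete-state agent that perceives, acts
and learns by minimising (expected) variational free energy under a
generative model of its exchanges with a caregiver. The generative
model is the formal counterpart of the internal working model of
attachment theory: a probabilistic description of how the caregiver's
hidden regulatory stance produces the infant's interoceptive (and,
optionally, exteroceptive) observations, and of how the infant's own
actions steer those exchanges.

### Environment (the generative process)

The caregiver is a fixed stochastic process, not an agent. On every
exchange it **Attends** (effectively lowers infant stress) with
probability `q` — the *responsiveness* — independently of history. The
infant chooses one of three actions per exchange: **Seek**,
**GuardedSeek** (resistant proximity seeking that dampens the
caregiver's effect) or **Avoid**.

*Interoceptive model (6 hidden states).* States are (control state ×
caregiving stance). Observations are the control state plus one of
five interoceptive outcomes reflecting the stress change: `g` (Seek
attended), `h` (GuardedSeek attended), `−m` (Seek ignored), `−n`
(GuardedSeek ignored), `0` (Avoid). Emission is deterministic given
the state; an avoiding infant's outcome carries no information about
the caregiver. Each episode starts with the infant in the Avoid
states, Attend vs Ignore weighted `q : 1−q` (a normalised, not
softmaxed, distribution: starting mass is confined to Avoid by
construction).

*Exteroceptive model (12 hidden states).* The caregiving component
becomes a pair (current stance, subsequent stance), and the caregiver
additionally emits an affective cue about its *subsequent* stance: an
attend-cue (accurate with probability `a`), no cue (accurate before
Ignore with probability `b`) or an ambiguous cue (rate `c`), with the
complementary mass delivered misleadingly. Misleading and ambiguous
cues model affective-communication errors on the AMBIANCE scale. An
avoiding infant always observes no cue. We read the state's pair as
(current, subsequent) behaviour: under the alternative
(previous, current) reading a cue about upcoming behaviour would be
unobservable from the current state.

### Infant (the generative model)

Beliefs over the likelihood, transition and initial-state
distributions are Dirichlet-parameterised; expected log-parameters use
the digamma function. Perception, policy evaluation and precision
follow the standard discrete-state variational updates:

* **State inference**: softmax of expected log-likelihood of the
  observation plus the propagated previous belief (or the expected log
  initial distribution at the first step).
* **Policy evaluation**: for each remaining action sequence, the
  expected negative free energy `Q(π) = extrinsic + epistemic`, where
  extrinsic is the expected log prior preference of predicted
  outcomes (always ≤ 0) and epistemic is the expected information gain
  about hidden states (always ≥ 0). Preferences are the softmax of the
  payoff vector `(g, h, −m, −n, 0)`, tiled so the infant is
  indifferent to control and cue components.
* **Precision**: `γ = α / (β − Q·π̂)` with a Gamma(α, β) prior;
  policy beliefs are `σ(γ Q)`. The three inference updates are swept
  `N` times per observation.
* **Action**: the policy posterior is marginalised over first actions
  and sampled.
* **Learning**: after each episode, Dirichlet concentrations are
  incremented by outcome×belief outer products (likelihood),
  belief×belief outer products per action (transitions) and the
  first-step belief (initial state). Learning rates are implicit in
  accumulated mass. Likelihood learning is off by default; transition
  and initial-state learning are on.

Perfectly informed infants encode each true probability `p > 0` as a
concentration `δ·p` (δ = 10³) and impossible events as a floor
ε = 10⁻¹⁰; uninformative infants place unit concentration on both
caregiving responses to each action, equivalent to an uncertain
expectation of a `q = 0.5` caregiver.

## Conventions and numerical choices

* **Matrix orientation**: columns = conditioning state, rows =
  outcome / next state, throughout.
* **Decisions per episode**: an episode has `T = 4` time steps and,
  by default, an action at *every* step (`decisions_per_episode = T`);
  the final decision's policy predictions extend one step past the
  last observation. The alternative `T−1` convention (no action after
  the final observation) is available as a config switch. The
  T-decision default is the package's reading of "one action per
  exchange" and is what reproduces the reference organisation
  statistic (≈ 1.3 distinct actions per episode in the secure
  condition; `T−1` gives ≈ 1.1).
* **Predictive matrices** are the column-renormalised exponentials of
  the expected log-parameters (the raw exponential is sub-stochastic).
  The alternative convention (Dirichlet means) was evaluated and
  changes none of the reported behaviours.
* **Policy evaluation sharing**: all `L^depth` policies are evaluated
  in one prefix-sharing tree pass; per-policy evaluation is exposed
  separately and tested against the tree.
* **Zero handling**: `0·ln 0 := 0` in the value sums; log-preferences
  are floored at `ln 1e−16`; Dirichlet concentrations at `1e−10`
  (keeping digamma finite on "impossible" entries).
* **Precision guard**: a non-positive denominator in the precision
  update raises rather than clamps. With extrinsic value dominating at
  the shipped payoff scales this does not trigger in practice.
* **Within-sweep caching**: the state-belief update has fixed inputs
  within a time step, so it reaches its fixed point in one sweep; the
  policy-value recomputation is skipped when the refreshed belief is
  numerically unchanged (< 1e−14), which only short-circuits an
  identical computation.
* **Seeding**: every run consumes `numpy.random.default_rng` streams;
  repetition `r` of a run seeded `s` uses the counter-based stream
  `SeedSequence((s, r))`, so any repetition is reproducible in
  isolation and distinct master seeds share no streams.

## The infant's cue likelihood

The infant's prior associations between cues and subsequent caregiving
are fixed (not learned): the attend-cue is expected only before
Attend, no cue only before Ignore (and always while avoiding), and the
ambiguous cue under both. The weight on the ambiguous cue is
`cue_model_split`, default **0.1** (the congruent cue carries 0.9 of
the likelihood mass). This default is the package's own choice, made
once: the congruent association must dominate for caregiver cues to be
epistemically potent, and 0.1 is the setting under which *every*
shipped caregiver configuration yields its expected phenotype —
including persistent disorganisation under a stress-increasing
caregiver whose cues falsely promise attention. With an even 0.5/0.5
split, half the cue information is destroyed and that infant instead
organises into avoidance; the split is exposed in the config precisely
so this sensitivity can be swept.

## Parameters

| name | meaning | default | units |
|------|---------|---------|-------|
| `q` | caregiver responsiveness P(Attend) | 0.9 | probability |
| `g`, `h` | stress reduction, (Guarded)Seek attended | 2, 0.75 | stress change (log-preference) |
| `m`, `n` | stress increase, (Guarded)Seek ignored | 2, 0.9 | stress change |
| `a`, `b`, `c` | accurate attend-cue / accurate no-cue / ambiguous-cue rates | 1, 1, 0 | probability |
| `delta`, `epsilon` | confident / floor concentration | 10³, 10⁻¹⁰ | Dirichlet mass |
| `cue_model_split` | infant's prior weight on the ambiguous cue | 0.1 | probability |
| `alpha`, `beta` | Gamma prior on policy precision | 250, 1 | shape, rate |
| `variational_iters` | inference sweeps per observation (N) | 4 | count |
| `horizon` | time steps per episode (T) | 4 | count |
| `repetitions`, `iterations` | independent runs × episodes per run | 100, 500 | count |

The payoff constraints `0 < h < g` and `0 < n < m` (comfort from
guarded approach is intermediate; so is the sting of guarded
rejection) are enforced at construction, as is cue composability
(`a + c ≤ 1`, `b + c ≤ 1`).

## Experiment protocols and problem sizes

* **Perfect-model sweep**: 405 cells (9 `q` × 5 `h` × 9 `(m, n)`
  pairs with `g·n/m` rising 0.1…1.7), perfect-model episodes without
  learning, 100 repetitions per cell by default.
* **Learning runs**: fresh uninformative priors per repetition;
  100 repetitions × 500 episodes (interoceptive) or × 1000 episodes
  (exteroceptive); traces averaged over repetitions first, then
  summarised over a trailing window — 100 iterations (interoceptive)
  or 10 iterations (exteroceptive) by default.
* **Classifier**: over the trailing window, one action with
  proportion ≥ 0.6 labels the organised types (Seek → secure,
  GuardedSeek → ambivalent, Avoid → avoidant); otherwise mean
  distinct-actions ≥ 1.8 labels disorganisation. These thresholds are
  reporting conventions for the package, not model quantities, and
  are configurable.

The test suite runs the same protocols at desk scale (typically 6–20
repetitions, and 60-episode perfect-model runs); the reproduction
script (`scripts/acceptance.py`) runs the secure-condition learning
protocol at the full 100 × 500 scale.

## What the simulator does and does not emulate

The environment generates exactly the stylised dyad the model family
assumes: a memoryless caregiver with stationary responsiveness,
deterministic interoception, fixed-length episodes in which the
attachment system is always active, and cue errors drawn
independently per exchange. Passing tests therefore demonstrate the
internal consistency of the inference/learning scheme and the
emergence of the four phenotypes *within this model family* — not
fidelity to real dyads: real caregiving is non-stationary and
context-sensitive, real interoception is noisy, episodes vary in
length, stress returns to baseline, and attachment classifications
rest on far richer behaviour than action proportions.

## Known limitations

* No baseline (attachment-deactivated) state or secure-base
  exploration; episodes are fixed-length with the attachment system
  active throughout.
* The caregiver does not adapt; dyadic (two-agent) dynamics are out of
  scope.
* No habit learning, hierarchical/deep temporal models or continuous
  states.
* The exteroceptive cue likelihood of the infant is fixed, not
  learned; its ambiguous-cue weight is a declared package choice (see
  above).
* The classifier's thresholds are heuristics for summarising traces;
  they do not implement any empirical coding protocol.
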