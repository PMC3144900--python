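# Methods

## Learning rule

The learner is a discrete-trial Rescorla–Wagner model. State is a matrix
V(cue, outcome) of predictive values, zero-initialized. On a trial with cue
set C and outcome set O, for every outcome o in the *fixed lexicon* (the
union of outcomes over the whole stream, not just the outcomes of this
trial) and every cue c ∈ C:

    ΔV(c, o) = α β (λ_o − Σ_{j∈C} V(j, o)),   λ_o = λ if o ∈ O else 0.

All deltas on a trial are computed from the pre-update state (simultaneous
update); sequential within-trial updating would make results depend on cue
enumeration order. Updating *every* lexicon outcome, not only those with
nonzero prediction, is what implements unlearning: an absent outcome whose
prediction is positive is driven down. Weights may go negative
(conditioned inhibition) and are never clipped. Cues absent from a trial
are untouched.

Parameters: α (cue saliency) = 1, β (learning rate) = 0.2, λ (outcome
asymptote) = 100 by default. On a single-cue, consistently reinforced
stream the recurrence solves to V(t) = λ(1 − (1 − αβ)^t), which the
implementation matches to 1e−9; this closed form, plus the blocking and
overexpectation signatures, are the engine's unit oracles.

**Stability.** With m co-present cues the summed prediction moves by
m·αβ·(λ − ΣV) per trial, so the discrete update is a contraction only when
m·αβ < 2; beyond that it oscillates divergently. This matters for the
nested cue coding, where a set of n objects co-activates n cues (plus up
to three feature cues). The small-set simulations (m ≤ 10) run at the
default β = 0.2. The sets-1–20 simulation would have gain up to 4 at that
rate, so its config defaults to β = 0.05 (gain ≤ 1, monotone damped for
every set size). This is a stability requirement of the discrete rule,
declared in `Sim2Config` and overridable there.

**Intermittent reinforcement.** When a single cue's outcome occurs with
probability p, the weight oscillates in steady state but its *time
average* equals λ·p exactly (mean ΔV = 0 implies mean λ_t = mean V).
Accordingly, all conditional-probability read-outs of Label→Feature
learning use `tail_mean_matrix`, the snapshot average over the last third
of training, rather than the final state.

## The synthetic environment

`number_world` generates the learning events. An object set has a count
(1–20) and categorical color/shape/size values drawn from 3×3×3 pools.
Cue coding is purely nested: size n activates `num1..num_n`, nothing else
— the minimal structure under which a learner that can tell objects apart,
and can tell members of larger sets apart from singletons, sees every
smaller numerosity inside every larger one. No "exactly-n" cue exists;
discriminability must come from learning, which is the point.

Temporal arrangement maps one world event to a trial two ways:
Feature→Label (features as cues, the word as outcome; postnominal) or
Label→Feature (the mirror; prenominal). The two streams built from one
event list are exact mirrors, which is what makes the sequencing
comparison clean.

Schedules fix the set-size composition: `equal` (uniform counts),
`weighted-deterministic` (largest-remainder apportionment of the weights,
then a seeded shuffle — used for headline runs so composition is exact),
and `weighted-sampled` (i.i.d. draws — used where 18 trials cannot honor a
20-support distribution, as in the facilitation baseline). Feature values
rotate per label in a Latin-square-like pattern (the shape and size cycles
shift phase each color cycle), so over a schedule every feature value
co-occurs with every label as evenly as divisibility allows; features are
deliberately unreliable cues, with P(value | label) ≤ 1/2 for pools of ≥ 2
values on full schedules.

The spoken-frequency weights come from the embedded English/Spanish
per-million counts for the words one–seven (the two languages' relative
frequencies correlate at r = .999). Sizes 8–20 take extrapolated weights
w(n) = f(7)·(n/7)^(−b), where b ≈ 1.15 is the log-log OLS exponent fitted
to 1–7. The tail is anchored at the *observed* f(7) rather than the fitted
curve because f(7) = 87 sits well below the fit (the raw fit predicts
104.6 at n = 8), and an unanchored tail would make sets of 8 more frequent
than sets of 7; anchoring keeps the 1–20 weight vector continuous and
strictly decreasing.

What the generator does not emulate: visual noise (no Weber-fraction
magnitude estimation — confusability is discrete, from shared cues),
referential ambiguity, social/joint-attention cues, and the multiples-of-
ten usage spikes of real number-word distributions. Passing tests
therefore speak to the information-structure account under idealized
perception, not to perceptual limits on numerosity itself.

## Read-outs

`activate` sums weights of the present cues per label — the learner's
total prediction. Three discrimination scores per set size n are
implemented, all computed from featureless probes (numerosity cues only,
so features cannot leak information):

* **relative** — activation of the correct label over the summed
  positive-part activations of all in-scope labels; in [0, 1],
  scale-invariant. The in-scope label set is the full trained lexicon, so
  mid-training confusions with larger-set labels count against a probe.
* **raw** — the single weight V(num_n, label_n), the direct strength of
  the criterial mapping.
* **share** — cue informativity: V(num_n, label_n)⁺ over the summed
  positive-part support of label_n across all cues. This is the read-out
  that moves when *competing* cues to a label are unlearned even though
  the criterial cue itself was never presented — the mechanism behind
  facilitation of untrained numbers — and it is the default for the
  facilitation analysis. The probe-based variants cannot register that
  effect: an 18-trial block on sets 2/4/6 never presents `num7`, so
  V(num7, "seven") is bit-identical before and after, and probe
  activations of untrained labels only fall.

Negative activations are floored at zero inside normalizations only; raw
values are reported unfloored. The forced choice scores three candidate
set sizes by the activation each lends the target label; `argmax` breaks
ties uniformly at random under the seed, `luce` samples proportionally to
positive parts (uniform when none are positive), so an all-zero matrix
performs at exactly 1/3 in expectation.

A learnability index, trials-to-half-maximum, is the first trial a score
curve reaches half its *asymptote* (λ/2 for raw weights, 0.5 for the
normalized scores). Using half the curve's own final value instead is
ill-conditioned for near-zero curves and was rejected.

## Simulation designs and problem sizes

* **sim1** (sequencing): sets {2, 4, 6}, equal frequency, features on, 600
  trials (200 per size — comfortably past the FL asymptote at β = 0.2),
  one shared event list trained FL and LF. Snapshots every trial.
* **sim2** (subitization): sets 1–20, weighted-deterministic composition
  from the frequency weights, FL, numerosity cues only, 1000 trials,
  snapshots every 10, β = 0.05 (see Stability). Scores are evaluated for
  sizes 1–7 against the full 20-label lexicon. A comparison arm trains
  sizes 1–8 with equal frequency; its final-score spread across 1–8 is
  much smaller than the weighted arm's. The feature-cue variant is
  runnable via `include_features=True`.
* **sim3** (facilitation): 110 weighted-deterministic trials on sizes 1–7
  with features on (β = 0.2), shared bit-for-bit by both arms; then either
  six FL blocks of 2→4→6 with one item (feature bundle) per block (18
  trials), or 18 further natural trials sampled from the same weights,
  replicated with 5 seeds and averaged. Improvement is score(128) −
  score(110) per size and arm, on the share metric.

Replicate and master seeds derive from one seed via `SeedSequence`; all
drivers are bit-reproducible given their config, and outputs log seeds and
parameters in their headers.

## Known limitations

* The λ = 100 scale is a convention; scores that matter are normalized.
* The facilitation effect size for size 7 is small and its sign can flip
  at some master seeds when measured against a single baseline replicate;
  the 5-replicate averaged design is the supported comparison.
* The equilibrium of the nested-cue system is exact identity mapping
  (each probe activates only its own label), so all discrimination scores
  approach ceiling in the infinite-data limit; the subitization gradient
  is a statement about learning *rates* under the frequency distribution,
  and is read at the default run lengths above.
* Sequential within-trial updating, attentional learning-rate models and
  configural cues are out of scope.
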