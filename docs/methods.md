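# Methods

This note records the modeling conventions, default parameters, and
design choices behind `seqlot`, and what the synthetic-data experiments
do and do not establish.

## The sequence language and its evaluation

Expressions are built from two primitives — *stay* `+0` and *change*
`b` — by concatenation and repetition-with-variation.  Execution threads
a current state (one of the two tones) through the program:

* `+0` emits the current state; `b` flips it, then emits;
* `Concat` runs its children in order;
* `Repeat(body, n, variation)` runs `body` n times.  Repetition k ≥ 2
  starts from a state set by the variation: *none* continues from
  wherever the previous repetition ended; `<+0>` resets to the previous
  repetition's start state; `<b>` resets to its flip.

The first instruction executes from the supplied start state, so every
program denotes two mirror-image item strings (the two experimental
"versions").  These rules were fixed because they reproduce all three
attested evaluations — `[+0]^4 → AAAA`, `[+0]^16<b> → ABAB…` (15
alternations), and `[A²B²[AB]²]² → AABBABABAABBABAB` — and no simpler
state-threading rule does.  Variations are restricted to a single
operation; longer variation programs are out of scope.

Items are 1-based; bracket (segmentation) intervals are 0..N, so a
16-item sequence has a 17-interval profile.  The predicted profile
counts, at each interval, the group edges of the expression: the whole
expression plus every Concat child and every individual repetition span
of emitted length ≥ 2, accumulated across nesting.  Length-1 spans mark
no group, which is what makes `[+0]^16<b>` "a single group of 16 items".

## MDL cost schedule

Description length is a weighted sum over the *text* of the expression
(a repeated token is charged once): per-instruction costs, a repetition
operator cost, a repetition-count cost equal to the number of decimal
digits of n (the digit count is used where a rounded logarithm would
disagree at exact powers of ten), a variation cost, and an optional
per-Concat cost (default 0).

Defaults: stay 1, change 2, operator 1, variation 1, digits(n) for the
count.  The published primitive weights live in an antecedent study's
supplement and are not reproduced here; instead the schedule is
calibrated by two hard constraints that the present design states: the
minimal encoding of the alternation sequence must be the single group
`[+0]^16<b>`, and complexity must be non-decreasing along the
experimental sequence hierarchy with the Repeat sequence strictly
minimal.  With stay = change = 1 both constraints fail (`[b]^16` costs 4
and ties `[+0]^16`); change = 2 is the smallest integer charge that
satisfies them.  All costs are configurable (`CostSchedule`).

## Chunk-preserving search

Only chunk-preserving expressions compete for the minimum: a grouping
span must either lie entirely inside one maximal run of identical items
or have both edges on run boundaries.  This allows `[+0]^4` for `AAAA`
(its single-item repetition spans live inside the run) while forbidding
`[AB][BA]` for `ABBA`.

The search is a memoized dynamic program over (subsequence span,
incoming state): primitives for single items; concatenation via a
prefix DP over admissible split points; repetitions via factorizations
of the span length whose item pattern is consistent with one body
executed under one variation (equal op-strings under continuation,
identical items under `<+0>`, alternating flips under `<b>`).  Interior
repetition cuts must themselves respect the run geometry, which also
guarantees that a body valid in the first repetition is valid in all of
them.  Nesting of composite nodes is capped (default depth 4; Concat
arity unbounded so the primitive-by-primitive fallback always exists).
Both start states are tried; ties break deterministically by fewer AST
nodes, then notation string.  The test suite proves the search equal to
an independent brute-force enumerator on every sequence of length ≤ 8.

## Competitor metrics

* **Transition entropy**: Shannon entropy (bits) of the N−1 ordered
  adjacent pairs over {AA, AB, BA, BB}.
* **Lempel–Ziv**: LZ76 exhaustive-history phrase count, final partial
  phrase included.
* **Subsymmetries**: contiguous palindromic substrings of length ≥ 2
  (length-1 substrings are trivially symmetric and excluded;
  configurable).  Note this counts *regularities*: the constant sequence
  maximizes it, and it enters behavioral models with a negative slope.
* **Chunk complexity**: sum over maximal runs of `1 + digits(length)`,
  mirroring the MDL repetition charge; the weighting is configurable
  because the published variant lives in a supplement.
* **Change complexity**: the mean, over all contiguous windows of length
  ≥ 2, of the fraction of unequal adjacent pairs in the window.  The
  definitional brute force over all windows is frozen as the test oracle
  for this aggregation.

## Transition-probability observer

Leaky counts of the four transitions decay by `exp(−1/ω)` per observed
item (ω = 100 items by default; a perfect integrator is available via
`decay_window=None`), then the observed transition gains one count.
Decay is applied per item rather than per transition event; the
difference is a one-step offset.  Prediction is the posterior mean under
a Beta(1, 1) prior per transition row; the first item, lacking context,
is predicted at 1/2.  Surprise is −log2 of the predicted probability of
the item that occurred.  The bracketing analysis instead uses a
no-decay, no-prior profile pooled over the sequence's own 15 transitions
("fully learned" probabilities); sequences whose transitions are all
equally predictable (Repeat, Alternate) are flagged degenerate and
excluded from surprise correlations.

## Experiment designs and roster

Mini-sessions: 10 habituation trials, then a test phase of 18 trials
(1/3 deviant; arranged 2×5 habituation + 3×6 test blocks) for the
deviant-detection design, or 36 trials (2/3 deviant) for the
passive-listening design.  Tones last 50 ms at a 250 ms SOA (4000 ms
per trial, 500 ms ITI); presses between 200 and 2500 ms after a deviant
count as hits.  Each sequence runs twice, once per tone-assignment
version.  Deviants replace a single item at one of 4 positions in 9..15,
drawn uniformly; exact counterbalancing across test blocks is not
modeled.  Rest-period and tone-frequency details are carried as
metadata only.

Five roster item strings are attested in text.  The other five are
bundled *synthetic stand-ins*, chosen at design time to (a) respect each
name's motif — shrinking run lengths (`AAAABBAABBABABAB`), an
alternation/pairs nesting (`AABBABABABABAABB`), runs of three and two
(`AAABBBAABBAAABBB`), a mirror-symmetric layout (`AABABBABBABBABAA`) —
and (b) realize the documented complexity hierarchy.  `Complex`
(`AAABAAABBABAAABA`) was selected by exhaustive scan as the
lexicographically first highest-MDL length-16 string with maximal run
≤ 3 and near-balanced transition counts, mirroring the stated design
goal of a maximally incompressible control.  The bundled complexities
are 4, 5, 5, 6, 11, 12, 14, 17, 18, 24 MDL units in roster order.
Deviant positions default to a reproducible per-name hash choice and
are configurable, as the published positions are figure-only.

## Behavioral generator and estimator

Latent sensitivity is linear in complexity with a subject random
intercept: d'(s, q) = 3.39 − 0.092·C(q) + u_s, u_s ~ N(0, 0.4), for 23
subjects — the group-level fitted coefficients serve as ground truth.
Because those coefficients were fitted to *estimated* d' values, the
generator defines its link on the estimator's scale: responding uses a
fixed criterion (c = 1.645, i.e. ≈5% false alarms on standards,
overridable), the analysis pools false alarms per subject across
sequences, and the per-cell hit probability is obtained by numerically
inverting the expectation of the log-linear d' estimator at the cell's
12 deviant trials.  This makes the estimator unbiased for the latent
linear model by construction — at 12 trials per cell the naive link
(per-trial probabilities at a symmetric criterion, per-cell false
alarms) attenuates the recovered slope by roughly 8%, so exact recovery
is a property of the generator–estimator pair, not of either half
alone.  Cells whose target exceeds the estimator's attainable range
(|probit| of the adjusted extreme proportions) are clipped; at the
default parameters this affects only the easiest sequence for the most
sensitive subjects and shifts the recovered intercept by well under one
across-seed standard error.

Correct detections get RT = 475.4 + 17.4·C + v_s + ε ms, v_s ~ N(0, 80),
ε truncated-normal with sd 120 within the 200–2500 ms response window.
The noise scales are typical for speeded auditory detection and keep the
window truncation rarely binding, so the cell-mean RT estimator stays
unbiased.  False-alarm presses are placed late in standard trials,
outside every deviant's response window, so outcome-level scoring and
press-time scoring agree.

Sensitivity summaries use the log-linear adjustment (add 0.5 to counts,
1 to totals) before the normal-quantile transform.  Mixed models have a
participant random intercept only (no random slopes) and are fitted by
maximum likelihood whenever AIC or likelihood-ratio comparisons are
made; conditional R² follows the variance-partition definition for
random-intercept models; denominator degrees of freedom are not matched
to any particular convention.  The model grid crosses the six metrics
with ±surprise (12 models per outcome), ranked by ΔAIC; the surprise
regressor is the block-mean deviant surprise for d' and the mean
surprise of detected deviants for RT.  Sequences are unweighted.

## Bracketing generator and analysis

Per subject and sequence, each predicted bracket of the minimal
program's profile is emitted with probability 0.9 and Poisson(0.1) noise
brackets are added per interval; for the alternation sequence half the
subjects (configurable) instead produce the "eight pairs" profile, the
strategy split observed empirically.  Analysis correlates the group-mean
17-interval vector with the LoT profile (for Repeat and Alternate the
single-group and item-wise encodings are both accepted; the better
correlating non-degenerate one is reported with a flag) and, over
interior intervals 1..15, with the pooled transition surprise.
Correlation p-values use the t approximation; raw counts are
correlated, without smoothing.

## Evoked-response generator and sensor statistics

Epochs are item-locked (−50..350 ms) or deviant-locked (−50..600 ms) at
250 Hz, baselined to the pre-onset mean.  Each trial sums a fixed
auditory template (raised-cosine bump, 50–150 ms), a habituation
component with amplitude 0.06·C over 100–210 ms, on deviants a mismatch
component with amplitude 2.4 − 0.08·C over 130–250 ms — complexity thus
raises the habituation response and lowers the violation response, the
reciprocal signature the analyses look for — each on its own random
unit-norm sensor topography, plus white sensor noise (sd 1).  The sensor
"helmet" is a ring graph supplied explicitly as the adjacency.

Cluster-based permutation tests threshold point-wise one-sample t maps
(default threshold: two-tailed t critical at p < 0.05, config-exposed),
join suprathreshold points contiguous in time and across the sensor
graph, score clusters by summed t, and build the null from subject
sign flips with p = (1 + #{null max ≥ observed}) / (1 + n_permutations).
The implementation is cross-checked against the MNE cluster test on
shared inputs, and its empirical family-wise error over 500 pure-noise
simulations (20 subjects, 30 sensors, 100 time points) falls within
[0.03, 0.07] at nominal 0.05.

Decoding: logistic regression with L2 penalty (fixed default strength,
no nested cross-validation) per time point on channels z-scored across
training trials; standards are matched in number to deviants per
(sequence, run); two folds split the tone-assignment versions so item
identity cannot carry the label; performance is the mean decision-value
difference between deviants and standards (an AUC option exists).
Temporal generalization evaluates every training time at every testing
time; its diagonal equals the time-resolved performance exactly under
the matched design.  Projection time courses can come from a single
decoder trained on a fixed post-deviant window (e.g. 130–210 ms).

## Problem sizes, seeds, determinism

All generators are pure functions of (parameters, seed); seeds split
through `numpy.random.SeedSequence`, one child per pipeline stage in a
fixed order.  The test suite and the acceptance script run the
behavioral recovery at the full design size (23 subjects × 10 sequences
× 20 seeds) and the sensor-level validations at reduced sizes chosen
for desk-scale runtimes (4–8 subjects, 10–15 sensors, the designed
trial counts per sequence scaled to 8–24); the statistical properties
checked (sign structure, ordering, error control) are size-free.

## Known limitations

* The five stand-in sequences are synthetic: analyses depending only on
  the complexity hierarchy transfer to the published stimuli, but any
  value tied to a specific item string (its metric values, surprise
  profile) does not.
* The generators draw independent Gaussian noise; real recordings have
  correlated sensor noise, drifts, and artifacts, so passing recoveries
  here demonstrate estimator correctness, not robustness to real-world
  noise structure.
* No hemodynamic modeling, source reconstruction, or audio synthesis;
  recordings-based statistics (real-data R², cluster windows, ROI
  effects) are out of scope by design.
* The behavioral generator's SDT link is defined on the estimator's
  scale (see above); a different analysis pipeline applied to the same
  synthetic data would recover slightly attenuated coefficients.
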