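# Methods

## The analysis

`spinfill` analyses serial-order recall in the *spin-list* paradigm, where
the same six items are practiced under three repetition schedules: **same**
lists (identical order every repetition), **spun** lists (rotated right by
one step each repetition, so neighbours — including the cyclic wrap from
the last item to the first — are preserved while serial positions change),
and **scrambled** lists (a Williams balanced Latin square, so each item
occupies each position exactly once and each ordered item pair is adjacent
exactly once across the set). The schedules dissociate *item-independent*
(positional) retrieval cues from *item-dependent* (chaining-like) cues.

The dependent measure is the **lag-conditional response probability
(lag-CRP)**: for a transition between consecutively recalled items, the lag
is the signed difference of their input positions, and the CRP at lag L is
the count of L-lag transitions divided by the count of opportunities for
one (an opportunity exists when the target position lies inside the list).
The **postanticipation** conditionalisation scores exactly one response per
eligible trial: the first response after an anticipation error, on trials
whose responses before the anticipation were all correct. At that
conditioning, crp(−1) estimates the **fill-in** rate (going back for the
skipped item), crp(+1) the **infill** rate (pressing on), and crp(−5) in
six-item lists the wrap transition from the final to the first item. The
**error ratio** is P(fill-in)/P(infill); a ratio above 1 is the fill-in
tendency.

### Counting rules

* Overall mode scores every transition between consecutively emitted list
  items; lags run −5..+5. An intervening intrusion or omission voids both
  adjacent transitions — a transition is only defined between consecutive
  responses. Postanticipation mode uses lags −5..+4 (the anticipated item
  can never be the first list item).
* Numerators and denominators are pooled over trials within participant ×
  list type before dividing (ratio of sums), yielding one lag-CRP per
  participant × list type. Group curves are means over participants with a
  defined value at each lag, with SEM; a participant missing at one lag is
  excluded at that lag only.
* Repeat policy. Under `scored`, transitions into already-recalled items
  count like any other. Under `excluded`, a repeat response increments no
  numerator, and denominators skip lags that would land on an
  already-recalled item (those lags are not opportunities for a non-repeat
  response). The transition itself still contributes denominators at the
  remaining lags; this is what makes postanticipation crp(−1) and crp(+1)
  provably identical under both policies (a ±1 transition from the
  anticipated item can never be a repeat when the prefix was correct),
  which the test suite asserts on randomized data.
* A postanticipation response that is an intrusion or omission has no lag;
  the trial then contributes neither numerators nor denominators, by
  analogy with the overall-mode voiding rule.
* Labels partition responses with precedence omission → intrusion → repeat
  → correct/anticipation/postponement. A re-report of an item that happens
  to land on its own position counts as a repeat: an item is credited at
  most once per trial.

### False-start screen

First keystrokes are ordinarily much slower than later ones, so a *fast*
first-position anticipation is more plausibly a motor error (a mistimed or
premature keystroke) than a memory error. Per participant, the screen
computes the 75th percentile of all second-response RTs — linear
interpolation between closest ranks, the common default in scientific
software, since no particular percentile definition is canonical — and
flags any first-position anticipation with RT *strictly below* that cutoff
("shorter than" is read strictly). Flagged trials are removed from
postanticipation scoring. With fewer than 4 second-response RTs the cutoff
is considered inestimable and nothing is flagged (logged).

### Statistics

Contrasts are paired t tests on participant-level postanticipation CRPs at
the theoretically loaded lags −5, −1 and +1: within each list type −1 vs
+1 (the fill-in tendency), and across each available pair of list types at
+1, −1 and −5. Two list types yield 5 contrasts, three yield 12.
Participants missing a value at an analyzed lag are deleted pairwise for
that test only. Frequentist tests delegate to scipy (Student forms; a
zero-variance difference degenerates to t = 0, p = 1 for a zero mean).
One-way between-subjects ANOVA supports homogeneity checks across
experiments or sites.

Each t test carries a two-sided default-prior **JZS Bayes factor**,
computed here by numerical integration: a Cauchy prior of width r on the
standardized effect size, expressed as a Jeffreys mixture over the
relative prior variance g, with the integrand formed relative to the null
marginal so that the quotient of two astronomically small marginals never
materialises in floating point. The default width is r = √2/2, the
"medium" default of the common Bayes-factor software family; it is exposed
as a parameter. The implementation agrees with pingouin's independent
implementation to ~13 digits (test-suite cross-check) and reproduces
published BF tables from their printed t and df up to the interval induced
by the t values' two-decimal rounding — a printed t of 15.30 determines
BF10 only to roughly ±1.5%, so agreement is asserted by interval
containment rather than digit-for-digit.

Error-ratio aggregation level is an explicit, logged parameter
(`participant`, `experiment`, `group`) because published ratios mix
aggregation orders; `group` computes the ratio of mean probabilities over
participants.

## The generative model

The analysis stages need data with the assumed structure, so the package
includes a small simulator. It is an artifact of this package (not a
published model), is never fitted to data, and claims no cognitive
fidelity beyond the qualitative signatures below.

At output position p, each list item i (input position q_i) receives

    a_i = exp(−λ_prim (q_i − 1))
          · [ w_pos exp(−λ_pos |q_i − p|) + w_posmem P̂[p→i] + w_chain Ĉ[prev→i] ]
          · (1 − s · 1{i already recalled})

where P̂ and Ĉ are row-normalized position→item and item→item association
strengths accumulated across presentations (each presentation adds η to
every adjacent input pair and every position–item pair), and the chaining
term is zero on the first response. The response is a Luce draw over
a_i^(1/temperature) (temperature → 0 is argmax with ties to the lowest
input position). Omissions (which end the trial) and extra-list intrusions
are independent per-response noise channels; intrusions come from a
reserved symbol alphabet disjoint from all list sets. RTs are lognormal
with a slower first response; with probability `p_false_start` the first
two responses are swapped and the first RT resampled fast (mean one
log-sd below the second-response scale), emulating the motor error the
false-start screen targets.

### Defaults and what they emulate

Defaults (`SimParams`) encode one fixed study regime, chosen to mirror the
task the pipeline targets: six-letter lists drawn from nonoverlapping
random letter sets per participant, 10 repetitions of each list (sessions
cycle through all lists of all sets, order shuffled per cycle; 40
repetitions reproduces the longer archival-style sessions), recall
accuracy around 0.7–0.8 with order errors dominating, first responses
~3× slower than later ones (log-means ln 1100 vs ln 380 ms, σ = 0.35),
and 3% false starts.

The cue weights (w_pos = 1, w_chain = 0.16, w_posmem = 0.2, λ_pos = 1.3,
λ_prim = 0.30, s = 0.6, temperature = 0.6) place the model in the regime
the analysis is about, and were fixed once from the model's structure:

* the primacy gradient plus response suppression produce a fill-in
  tendency (crp(−1) > crp(+1)) in **every** list type, even with
  w_chain = 0 — earlier items are more active, so after a skip the
  skipped (earlier) item beats the next (later) item;
* a positive chaining weight adds infill selectively where neighbours are
  consistent across repetitions (spun and same lists), shrinking the
  error ratio there, and produces wrap (−5) responses in spun lists,
  because rotation teaches the final→first association — these −5 events
  are mostly re-reports of the first item, which is why they require the
  repeats-scored policy and a temperature warm enough to leave mass on
  suppressed items;
* scrambled lists spread the item–item associations uniformly (each
  ordered pair adjacent exactly once), so chaining confers no directional
  advantage there.

Determinism: every source of randomness flows from `SimParams.seed`;
per-participant substreams are derived from (seed, SHA-256 of the
participant label), so sessions are independent, order-insensitive and
exactly reproducible.

### What the simulator does not emulate

No learning-curve dynamics beyond linear association growth, no
speed–accuracy trade-offs, no typing-specific keystroke confusions, no
output-position-dependent omission rates, no participant heterogeneity in
the cue weights. Passing tests therefore show that the *pipeline* measures
the intended quantities on data with the assumed structure — not that the
generative model is a correct account of human serial recall.

## Numerical and design choices

* Percentile: linear interpolation (rank 1 + 0.75(n−1)); strict `<` at
  the cutoff.
* Williams construction for scrambled sets: first row 1, 2, n, 3, n−1, 4,
  …, subsequent rows add 1 mod n; defined for even n. Any balanced square
  with both properties is acceptable — the published example square is
  verified by the same exhaustive balance check, not reproduced
  row-for-row.
* JZS integration: scipy `quad` on (0, ∞) with the null-relative
  integrand; non-convergence (relative error estimate > 1e−4) raises.
* Ties in argmax choice break toward the lowest input position, for
  deterministic tests.
* Degenerate inputs: empty trial sets give tables with all-zero
  denominators (CRP = NaN); P(infill) = 0 makes the error ratio NaN (never
  infinity), with a warning; a participant with no second responses gets
  no false-start screen.
* Problem sizes in the test suite and acceptance script (120–200 simulated
  participants for signature recovery, 500 replicates × 12 participants
  for null calibration) are the package's own choices: large enough that
  the qualitative orderings are stable across seeds, small enough to keep
  the default runs quick.

## Known limitations

* The pipeline is specified and tested for list length 6; constructors
  generalise (Williams squares for even n) but the CRP lag ranges assume
  the six-item geometry only in their documentation, not in code.
* Conversion from archival deposits (Excel / E-Prime exports) to the trial
  CSV dialect is out of scope; the dialect defined in `spinfill.io` is
  normative for this package.
* Only the first response after an anticipation is scored; more liberal
  fill-in/infill scoring schemes are not implemented.
* The false-start screen addresses fast first-position anticipations only;
  a slow-first-keystroke motor error that finishes after the second
  keystroke is indistinguishable in these data and is not filtered.
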