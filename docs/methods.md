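# Methods

## From annotations to series

Input is one interval annotation per participant — a Praat TextGrid
interval tier (long text format) or a CSV of (onset, offset, label) in
seconds — with a label map to binary speech/silence (default: Praat's
`sounding` → 1, `silent`/empty → 0). Binarization resamples onto fixed
1-second bins, half-open [t, t+1); a partial trailing bin is dropped,
never padded, so every bin represents a full second. Two aggregation
rules are exposed: `majority` (bin is speech iff speech overlap ≥ 0.5 s,
tie → speech; the default) and `any_speech` (any positive overlap).
Majority is a convention, not a claim about any particular upstream
pipeline; the two rules bracket reasonable choices and `majority` never
exceeds `any_speech` elementwise. Partners of a dyad are aligned by
truncating both series to the shorter length.

## Recurrence measures

All measures are defined on the complementary-matching (XOR)
cross-recurrence plot with partner A on the horizontal axis and B on
the vertical. No Theiler window is applied and the line of synchrony is
included: for categorical cross-recurrence between two *different*
speakers, lag-zero matches are signal, not tautology. The XOR structure
lets every rate be counted in O(n) per diagonal without materialising
the n × n grid; the dense matrix is built only for plots and line
extraction, and exact agreement with a naive cell-by-cell recount is
enforced in the test suite.

Conventions and tie-breaks:

- Diagonal profile rates are normalised per lag by n − |k|, so short
  series and wide windows remain comparable. The window default is
  ±30 s; it is a parameter (`max_lag`) because the appropriate range
  depends on how slowly coordination decays in the data at hand.
- Half-window means RR_left/RR_right are accumulated with exact
  summation (`math.fsum`), so a profile that is mirror-symmetric lag by
  lag yields Q_DCRP = 0 exactly rather than ~1e-16.
- Q_DCRP, LAM_ARD and TT_ARD are defined as 0 when their denominator is
  0 (empty plot, or no qualifying lines): a degenerate interaction is
  reported as "balanced" and flagged by the zero line counts rather
  than propagating NaNs.
- Line extraction uses minimum line length `l_min = 2` (the recurrence
  convention that a "line" is more than a point); lines touching the
  plot border count at their visible length. Laminarity divides by the
  total count of recurrent points. Trapping time for a direction with
  no qualifying line is 0.
- Attribution: vertical lines (a run over B's time at fixed A-second)
  are read as A's sustained influence over B. The ARD measures are
  absolute, so downstream results do not depend on this attribution;
  swapping partners transposes the plot, exchanges the directional
  statistics and leaves all five dyad-level measures unchanged.

## Surrogates

"Chance" is estimated by shuffling each partner's 1-s bins independently
while keeping the real pairing and lengths; every surrogate preserves
each partner's total speech seconds exactly. A `block` mode instead
permutes speech runs among themselves and silence runs among themselves,
preserving the full dwell-time distribution and alternation while
destroying alignment — useful when the run-length structure itself
should be held fixed.

One structural fact matters for test design: under XOR matching,
RR_global = [s_a(n − s_b) + s_b(n − s_a)] / n² depends only on the
marginal speech counts, which every permutation preserves. Real-minus-
surrogate differences for RR_global are therefore identically zero and
`compare_to_chance` raises a zero-variance error for them (the check
uses a 1e-12-scaled tolerance to absorb float accumulation). Surrogate
tests should target RR_LOS, the profile, or the line measures; the
package's calibration checks use RR_LOS. `compare_to_chance` is a
paired two-sided t-test across dyads of (real − mean surrogate), with
the 95% CI of the mean real value reported alongside.

## The turn-taking generator

`simulate_dyad` is a coupled two-state chain in 1-s steps: each partner
has start/stop hazards (`p_start`, `p_stop`), and the other partner's
state `delay_d` seconds earlier multiplies them — the stop hazard by
`yield_gain` while the partner was speaking, the start hazard by
`initiative_gain` while the partner was silent, clipped to [0, 1].
Uncoupled, each partner is a two-state Markov chain with stationary
speech share p_start/(p_start + p_stop). Annotation noise is modelled
as an independent per-second state flip (`noise_eps`).

Defaults (chosen once as a realistic conversational regime): 300 s per
task, p_start = 0.08 and p_stop = 0.12 per second (speech share 0.40,
mean dwell ~8–12 s, leaving room for mutual silences), symmetric gains
2.5, delay 1 s, noise 0.02. Under these, RR_global sits in the high
0.40s and RR_LOS near 0.65, i.e. clearly above the analytic chance
level for the realised speech shares.

Properties of this family worth knowing before designing studies with
it:

- Raising both partners' gains raises RR_LOS monotonically (tested).
- Lengthening one partner's dwell times (lower `p_stop`) raises TT_ARD
  monotonically (tested).
- Leader–follower (profile) asymmetry requires a *responsiveness*
  asymmetry: scaling one partner's start-hazard gain alone does not
  move Q_DCRP — the extra early starts add recurrence mass on both
  sides of the LOS about equally. `with_lead_asymmetry(factor)`
  therefore scales both of a partner's gains oppositely to the other's.
  Two further regimes limit the effect: with a 1-s delay the off-LOS
  peak sits 1 s from the LOS and 30-lag half-window means barely
  resolve it (use delay ≥ 2–3 s for asymmetry studies), and extreme
  gains drive near-deterministic following, which makes one series a
  lagged complement of the other — a profile symmetric about the
  shifted peak, collapsing the quotient again. The monotonicity tests
  use delay 3 s and factors 1–3.

`simulate_study` wraps this into a full design: 50 dyads × 3
conversation tasks (introduction, self-disclosure, argumentative) by
default. Standard-normal Extraversion and Agreeableness scores per
participant map log-linearly onto the coupling gains (Extraversion →
initiative, coefficient 0.25 per SD; Agreeableness → yield, 0.15), task
offsets scale coupling (1.0 / 1.1 / 1.25, the argumentative task most
coupled), and a per-dyad log-normal coupling multiplier (SD 0.4) gives
measures the within-dyad clustering (ICC well above 0) that two-level
models are built for. Appraisal items (1–5 Likert, clipped) are
generated from the traits and the *computed* dyad-mean RR_LOS of the
simulated series — not from latent parameters — so the appraisal-model
stage is testable end to end.

What the generator does not emulate: utterance content, backchannels,
overlap-resolution conventions, non-stationarity within a conversation,
and recording/VAD artefacts beyond the iid flip noise. Passing tests on
this synthetic family shows the pipeline recovers the structures the
generator encodes; it does not validate any substantive claim about
human conversation.

## Statistical stage

The dyad-task measures are assembled into a long table (one row per
dyad × task, complete grid enforced) joined with trait scores that are
standardized across the whole sample. Within each dyad the higher
scorer on a trait is role "A", the lower "B" (tie → first listed), so
traits enter as ordered continuous covariate pairs. Descriptive dyad
types use a ±0.5 SD threshold ("++", "--", "+-", "mid"); they are for
plotting and stratified description only, never model input.

Mixed models are linear with a dyad random intercept, estimated by
maximum likelihood through statsmodels `MixedLM` (ML rather than REML so
AIC is comparable across fixed-effect structures). Conversation task is
categorical with the introduction as baseline. The module owns the
design construction (trait main effects plus two- and three-way
trait × task interactions via formula fragments), the reporting
contract — raw B, standardized β, SE, t, df, p, ICC = between-dyad /
total variance, marginal and conditional R² (fixed-effects variance
over total, and fixed-plus-random over total), AIC — and the
Benjamini–Hochberg correction. Standardized β come from refitting after
z-scoring the response and all continuous predictors; task dummies stay
binary. Degrees of freedom are residual (n_obs − fixed parameters), a
deliberate approximation: finite-sample df corrections are out of scope
here, and with 150 observations the difference to Satterthwaite-style
df is small. Estimates whose SE is exactly 0 (degenerate exact fits)
report |t| = ∞ and p = 0 instead of NaN. A between-dyad variance
estimated at ~0 is carried as a "singular fit" warning on the result,
not an error.

Appraisal items are modelled one item at a time by OLS with the same
reporting contract; designs are checked for zero-variance predictors
and rank deficiency before fitting. BH correction is applied within a
configurable family: across the non-intercept terms of one model by
default, or jointly across a set of per-item fits via `bh_adjust_fits`
(the family boundary is a reporting choice, so it is explicit rather
than hidden). The BH implementation delegates to statsmodels and is
verified against a textbook step-up oracle.

## Problem sizes in the checked properties

The test suite's stochastic checks use sizes chosen to make their
statistical tolerances meaningful at desk scale: 300-s series (one task
at 1 Hz), 100–1000 replicates for Monte-Carlo means against 3-standard-
error bands, 100 seeded replicates per level for median monotonicity,
200 simulated null studies for type-I calibration against a 3-SE
binomial band, and 100 mixed-model replicates (50 dyads × 3) for ICC
recovery with bias below 0.05. Exact (non-stochastic) properties —
oracle equivalence, transpose duality, partner-swap symmetry, BH — are
asserted with equality or 1e-6-level tolerances.

## Known limitations

- The 1 Hz binarization erases sub-second timing (latencies < 1 s);
  measures here cannot resolve faster turn-taking phenomena.
- Q_DCRP's half-window means depend on `max_lag`; comparisons are only
  meaningful at a fixed window.
- TT_ARD is undefined-by-convention (0) when a direction has no lines;
  with very sparse plots the ARD measures are noisy.
- The mixed-model stage assumes the complete dyad × task grid; missing
  cells must be handled upstream.
- `MixedLM` occasionally reports boundary/convergence warnings on
  near-singular fits; these are surfaced on the `ModelFit` rather than
  suppressed, and estimates at the boundary coincide with OLS.
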