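# Methods

`songctx` analyzes how a songbird's variable syllable sequencing changes
under light-cued contexts, and ships a generator that simulates the whole
training protocol so that every estimator can be validated by parameter
recovery. This note records the models, conventions, parameter choices and
limitations.

## The measurement model

The unit of analysis is the song bout: an annotated string of syllable
tokens assigned to one context block (a contiguous period under one light
color, of type `wn` — reinforced with white noise, `probe` — same cue
without reinforcement, or `neutral` — a third cue, never reinforced).

**Sequence probability.** Within each bout, p = n_Y / (n_Y + n_G), where
n_Y and n_G count renditions of the yellow-context and green-context target
sequences. Motif occurrences are counted with overlap allowed (sliding
window); real targets cannot self-overlap, so this choice is observationally
neutral there while remaining order-independent. Bouts containing neither
target are discarded — they carry no information about the targeted branch.
Pooled estimates (e.g. per day) carry the normal-approximation interval
p ± z·sqrt(p(1−p)/n), z = 1.96, n = n_Y + n_G. Probabilities are fractions
everywhere in the library; percent appears only in reports. SEM across
bouts uses the n−1 sample standard deviation and is reported absent for a
single bout.

**Switches.** Admissible context switches are boundaries between adjacent
same-day blocks, after (1) merging blocks without song into an adjacent
same-color block (backward when both neighbors match — a tie rule we had to
choose), and (2) discarding junctions where the light changed two or more
times with no intervening song. Overnight boundaries are never switches; a
day that starts with the previous day's closing color is a fresh context.
Adjacent same-color periods that survive merging are coalesced, since the
bird never saw a color change. Bouts are assigned to the block containing
their start time: sequencing is initiated under the starting context.

**Shift magnitude** is mean(first five post-switch bouts) − mean(last five
pre-switch bouts), computed only when each side has at least three bouts;
the five-bout window shrinks to what is available so that three- and
four-bout blocks still contribute. The first-song/last-song difference is
reported alongside. Both use only bouts with a defined p (an assumption:
target-free bouts do not count as "songs" for this purpose, since they have
no probability to contribute).

**Switch-triggered averages** align bout series at the switch (position 0 =
first post bout, −1 = last pre bout) and drop positions supported by fewer
than half of the switches, so the tails are never driven by a few long
blocks.

**Acquisition fits.** Per switch, the post-switch bout series is
sign-inverted for switches into the yellow context (so the adaptive
direction is positive for both directions), the mean pre-switch value is
subtracted, and an ordinary least-squares line is fit against post-bout
index. The intercept estimates the immediate cue-driven shift; the slope
the within-block learning rate. Fits always use the raw, unsmoothed series;
the nine-bout boxcar and seven-switch binning exist for display only.
Trends over training ("slope of intercepts", "slope of slopes") are OLS
against switch index, with standard errors from the residuals. Plain OLS is
used throughout; no robust alternative is offered.

## Transition-matrix analysis

Raw sequences are collapsed before any matrix is built, so stereotyped
structure does not masquerade as variability:

1. leading introductory notes (a per-bird token set) become one intro state;
2. any syllable that ever repeats in the corpus becomes a repeat state, and
   *all* its runs — including length-1 runs — map to that state, so a
   phrase sung once and a phrase sung four times are the same state;
3. fixed chunks are found by greedily chaining transitions with probability
   ≥ 0.97 (the branch-point complement) and merged into single states.
   Chunks can instead be supplied explicitly per bird: the original
   identification also used gap durations, which label-only data lack;
4. chunk states are named by their member tokens, with numeric suffixes
   disambiguating distinct chunks that would share a name — the renaming
   that stops a duplicated syllable (as in the fixed run "abbc") from
   faking a 50%/50% branch.

From collapsed sequences, first-order transition counts (each bout
terminated by an explicit end state; bout boundaries never create
transitions) give a row-stochastic matrix p(y|x) and preceding-state
frequencies p(x). Branch points are states with at least two outgoing
probabilities strictly inside (3%, 97%), evaluated per context and unioned
when two contexts are compared (a choice; the thresholds themselves are the
field's convention for "variable sequencing").

**Context difference and specificity.** The difference matrix is green −
yellow (transitions more frequent under green are positive), computed over
the unioned state set, preferring probe-context corpora (reinforcement-free
singing) and falling back to WN blocks with a logged notice. Specificity is
the share of the summed absolute difference over branch-point rows that
falls in the rows of the targeted branch point(s). Restricting the
denominator to branch-point cells is deliberate: near-deterministic
transitions cannot meaningfully differ, and including them would only
dilute the ratio with noise. The targeted branch points themselves are
located automatically: a branch row is targeted when the minimal token
expansion of the row state followed by one successor contains a target
motif crossing the state boundary (i.e. producing the target requires that
particular transition). Minimal expansion treats a repeat state as one
token, so targets that span a variable-length repeat phrase must be
supplied explicitly.

**Transition entropy** is H = Σ_x p(x) Σ_y −p(y|x) log₂ p(y|x), the
preceding-state-frequency-weighted conditional entropy in bits, computed
after the same collapsing. The base-2 logarithm and the p(x) weighting are
this package's definitional choices (the customary form for song-syntax
work); zero for a deterministic chain, log₂(k) for a uniform k-way branch.

**Group comparisons** use the Wilcoxon rank-sum (unpaired) and signed-rank
(paired) tests via scipy; with cross-bird samples of n ≈ 8, assuming
normality would be optimistic. Identical paired samples are reported as a
no-difference outcome (p = 1) rather than an error.

## The synthetic experiment generator

The generator's defaults encode the training protocol: block durations
uniform on 60–90 min tiling a 14-h singing day, strict green/yellow
alternation, each block independently a probe with probability 1/3 (so on
average every third switch enters a probe block), an optional neutral
(white) context, Poisson bout counts around 240/day placed uniformly in
time, intro notes of 0–3 tokens with geometric stopping, and imperfect WN
targeting — each rendition of the active target is hit on its final token
with sensitivity 0.913, other syllables with a 0.005 false-alarm rate
(matching the protocol's measured template accuracy).

Learning follows a deliberately minimal two-process model in units of the
yellow-target branch probability p:

    p = clamp(p0 + D(color)·delta_max·(1 − exp(−B/tau_blocks)) + drift,
              eps, 1 − eps)

with D(green) = +1 (the yellow target escapes WN under green light, so its
probability adaptively rises), D(yellow) = −1, D(neutral) = 0, and B the
number of WN blocks experienced. Inside WN blocks, drift moves away from
the active target by s_within per bout — whether or not that bout was
actually hit, since reinforcement acts on average — capped at ±l_max and
reset to zero at every block boundary. This reproduces the qualitative
structure the analysis is meant to detect (an immediate shift that grows
with a saturating time course, plus a constant-rate within-block
adjustment that never accumulates across blocks); it is a model we chose,
not an estimate from real birds. In particular s_within = 0.005/bout,
tau_blocks = 20 and l_max = 0.2 are arbitrary defaults picked to produce
realistic-looking acquisition curves, and delta_max = 0.25 yields the
saturated two-context separation of 0.5 used in recovery tests.

The default song diagram is compact but structurally faithful: intro notes,
a fixed chunk "aab" acting as the reinforced branch point (targets "abd"
vs "abc"), a repeat phrase, a second context-independent branch point, and
a loop back so that bouts contain ~6–7 target renditions and ~60 syllables,
comparable to real bouts. All randomness flows from one integer seed
through named substreams (schedule / song / WN), so runs are bit-identical
given a seed and components are independently reproducible.

What the generator does *not* emulate: acoustics, gap durations and
amplitudes, autolabeling errors, bout-length or singing-rate changes with
training, inter-bird diagram diversity, or any coupling between WN delivery
and the very next bout. Passing recovery tests therefore show that the
estimators are correct for data of this structure — not that real birds
satisfy the model.

## Numerical and edge-case conventions

- Probabilities are clamped to [eps, 1 − eps] (eps = 0.01) in the
  generator; row-stochasticity is validated to 1e-9.
- 0·log 0 = 0 in entropy; rows with no outgoing transitions are absent from
  the matrix rather than zero-filled.
- Degenerate fits (fewer than two post-switch bouts, or no pre bouts) are
  skipped; trend estimation requires at least three fits.
- Boxcar smoothing shrinks its window at the edges and is never used in
  estimation.
- File round trips preserve float timestamps via `repr` and treat labels as
  token sequences (single characters by default, or separator-joined
  multi-character tokens such as renamed states like `b_2`).

## Test and simulation sizes

Recovery and calibration tests run the generator at 6–30 simulated days
(roughly 1,400–7,200 bouts, 60–320 switches), sizes at which the standard
error of each recovered quantity is several times smaller than the asserted
tolerance, so the checks are informative rather than lucky. The binomial-CI
coverage check uses 2,000 replicates per true probability at n = 500
renditions. Published cross-bird summary statistics can be recomputed with
`songctx.summary_tables` once the per-bird summary tables are converted to
the documented CSV schemas; those tables are not redistributable here, so
the corresponding check reports its requirement instead of silently
passing.

## Known limitations

- Chunk detection from labels alone cannot use gap durations; birds with
  ambiguous chunking need explicit chunk lists.
- The automatic targeted-branch locator assumes targets do not span a
  variable-length repeat phrase (supply targeted states explicitly then).
- Specificity is undefined (raised as an error) when two contexts do not
  differ at any branch point — e.g. at baseline; callers decide how to
  report that.
- The merge rule for songless blocks keeps the earlier block's identity and
  type; when a songful WN block absorbs a songless probe, the coalesced
  period counts as WN.
- `blocks_experienced` counts only WN blocks in which the bird sang; probe
  and neutral blocks do not advance acquisition.
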