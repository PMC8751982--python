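# Methods

## Data model

A video is a `FrameSequence`: one behavior label per frame at a fixed
frame rate (default 29.97 fps), for one animal in one feed state (0–4
prey items consumed). The 12-bin vocabulary distinguishes the hunting
regime (successful strike SS, missed strike MS, specific translation ST,
rotation SR, monitoring SM), neutral general monitoring (GM), the
nonhunting regime (general rotation GR, translation GT, grooming GROOM,
deimatic display DEIM, escape ESC), and the absorbing arena-reset marker
RESET. Strikes are instantaneous events: they occupy a single time step
and carry no dwell duration.

Frame indexing is 0-based; bout intervals are half-open `[start, end)` so
durations sum without off-by-one corrections. `segment_subsequences`
splits a video at RESET frames (which belong to no subsequence); the
termination of each subsequence is read off the frame preceding the
reset — SS → `capture`, ESC → `escape_reset`, anything else →
`experimenter` — and trailing frames form a `timeout` subsequence. A
multi-frame strike run in an input file is kept in the frame stream (so
frame indices stay contiguous) but run-length-encodes to a single bout,
i.e. one strike event, with a warning at read time. Consequently strike
tallies count strike *bouts*, which equals strike frames for well-formed
single-frame-strike input.

## Time budgets

Behavior probability is a time fraction per subsequence: frames in a
behavior divided by the subsequence's non-strike frames. Excluding the
strike frames from the denominator keeps strikes purely event-like
(counts, not durations); with one-frame strikes the numerical effect on
the other fractions is below 0.1%, but it preserves the semantics that a
probability row sums to exactly 1 over the nine duration behaviors.
Escape is included in the normalization of its own subsequence but is
best summarized as a count across subsequences, because how long an
escape lasts is set by how quickly the experimenter intervenes, not by
the animal.

Bout-duration summaries report the sample mean and SD (n−1 denominator;
a single-bout group reports SD 0, and empty groups are omitted).
Capture percentages round half away from zero. `StrikeTally` reports two
distinct rates on purpose: captures / total subsequences (the capture
percentage) and captures / (captures + missed strikes) (the per-attempt
success rate). They answer different questions and need not agree; both
are exposed rather than committing to either.

Group comparisons delegate to standard implementations: one-way ANOVA
(`scipy.stats.f_oneway`), Tukey HSD (`statsmodels` `pairwise_tukeyhsd`)
run only when the ANOVA p-value is below 0.05, and chi-square on the
capture-vs-no-capture contingency (`scipy.stats.chi2_contingency`,
df = number of states − 1, no continuity correction).

## Transition analysis

Transitions are counted at bout boundaries — one count per change of
behavior — rather than per frame. Per-frame counting would put nearly all
mass on the diagonal (self-dwell) and make the transition table redundant
with the time budget; dwell is already modeled by the bout-duration
statistics. The diagonal is therefore structurally zero. A
`per_frame=True` switch preserves the alternative convention. With
`include_reset=True` (default) a non-timeout subsequence contributes a
final transition from its last behavior into RESET.

Rows of behaviors never exited in a subsequence stay all-zero after
normalization instead of being imputed (e.g. to uniform): imputation
would inject identical artificial mass into every feature vector and
bias Euclidean comparisons toward similarity for behaviors that simply
were not visited.

The feature vector is the row-major flattening of the 12×12 probability
matrix (144 cells; `unvectorize(vectorize(M)) == M` exactly). Regime
blocks partition its cells: hunting side = the 5 prey-directed behaviors,
nonhunting side = the 5 nonhunting behaviors plus GM. GM is neutral in
the vocabulary but is grouped with nonhunting for display and block
pooling, mirroring how it is treated in the field; `regime_blocks(
gm_as_nonhunting=False)` gives the strict 5×5 partition. RESET row and
column cells (23 cells) belong to no block. Block sizes are then
HH 25, HN 30, NH 30, NN 36.

Block-probability densities use a Gaussian KDE with Silverman's
bandwidth, reflected at the 0 and 1 boundaries (the estimate on [0,1] is
`f(x) + f(−x) + f(2−x)`), then renormalized so the trapezoid integral is
1 to numerical precision. Reflection prevents the familiar mass leak at
the boundaries that a plain KDE exhibits for probabilities concentrated
near 0. An all-equal sample (zero variance) falls back to a fixed narrow
bandwidth of 0.01 so the density still concentrates at the common value.

## Sequence distances

Euclidean distance between feature vectors compares behavior
*repertoires*; the editing penalty cost (PC) compares behavior *order*.
PC is computed by exact dynamic programming over the
(len A + 1) × (len B + 1) grid with configurable substitution and indel
costs (unit costs = Levenshtein distance). The inner loop is vectorized
with a prefix-minimum scan, which is exact — no banding or heuristic
shortcuts, since the analysis depends on minimal costs. A traceback
reports substitution/indel counts of one optimal script (scripts are not
unique; the cost is).

Sequences can be encoded per frame (duration-expanded), per bout
(order only), or decimated — one symbol per k-frame window, majority
label, ties to the earliest label in the window. The pipeline default is
decimation with k chosen so no sequence exceeds ~2,000 symbols: a full
per-frame comparison of two 7-minute videos is ~1.6×10⁸ DP cells per
pair, which is feasible but wasteful when windows of a fraction of a
second carry the same information. Both raw and length-normalized
(cost / longer length) PC are reported, because subsequences of very
different lengths are compared and neither convention is canonical.

Distance distributions follow the "a:b" group-pair convention:
intra-state pairs are all unordered pairs within a state excluding
self-comparisons (which would deflate intra-state means with structural
zeros); inter-state pairs are the full cross product.

## Synthetic generator

The generator is semi-Markov rather than per-frame Markov: an embedded
chain over behaviors (zero diagonal) chooses *what* happens next, and an
explicit per-behavior dwell distribution chooses *how long* it lasts.
A per-frame chain with self-transitions would tie time fractions and
transition counts to a single parameter; separating them lets bout
durations and transition structure be controlled independently.

Dwell defaults are gamma distributions on seconds, rounded to at least
one frame. The reported per-state bout summaries have SDs comparable to
or exceeding their means, which rules out near-deterministic dwells; a
gamma accommodates that overdispersion with nonnegative support. The
per-state dwell means/SDs are taken directly from the reported summaries
(e.g. GM 4.99 s ± 7.08 when starved rising to 11.49 s ± 17.26 at 4-fed);
ESC, which has no reported dwell, uses 2.0 s ± 1.5 — an experimenter
reaction time, since escapes end when intervention occurs.

Transition defaults interpolate linearly between a starved and a sated
anchor as feed state runs 0 → 4: strike-attempt hazard from hunting rows
0.30 → 0.06, total hunting-side retention of hunting rows 0.92 → 0.45,
GM's pull back into hunting 0.60 → 0.15. Nonhunting behaviors re-enter
hunting with constant probability 0.008 (regime re-entry is rare), and
DEIM/ESC receive small constant hazards from the nonhunting side
(deimatic displays are rarely deployed). Strike attempts are carried on
the SS column of the chain; an attempt resolves to capture (emit SS, then
RESET — capture is absorbing) with probability `p_capture_given_strike`
(defaults 0.73/0.74/0.66/0.69/0.37 across states, following the reported
per-attempt success rates), otherwise to a single MS frame after which
the chain continues from the MS row. The MS row carries no strike mass
by default — after a miss the animal repositions — which also keeps
bout-boundary transition counts off-diagonal. An ESC bout ends the
subsequence with probability `p_escape_reset` (default 0.25).

`simulate_dataset` reproduces the study design: one video per animal per
feed state, subsequences concatenated with RESET separators until the
7-minute trial is filled, the last subsequence truncated as a timeout.
Each (animal, state) cell draws from its own `SeedSequence(seed,
spawn_key=(animal, state))` child stream, so one global seed yields a
byte-identical dataset that is also reproducible piecewise.

`SemiMarkovParams.observed_transition_matrix()` maps the generating
parameters to the bout-level transition probabilities an estimator sees
(strike attempts split into SS/MS by the capture probability, ESC mass
rescaled by the escape-reset hazard); this is the ground truth used in
parameter-recovery checks.

### What the generator does and does not emulate

It emulates: the 12-bin vocabulary with regime structure, absorbing
resets with capture/escape/timeout terminations, feed-state-dependent
transition structure and dwell times, overdispersed bout durations, and
declining capture success with satiety. It does not emulate: spatial
structure (prey positions, strike distances), within-trial
nonstationarity (fatigue, learning), between-animal heterogeneity
(all simulated animals share one parameter set per state), or scorer
disagreement. Passing tests on synthetic data therefore validate the
*estimators and pipelines* — that they recover known generating
structure — not claims about real mantises. With the default anchors the
simulated contrast between starved and sated states is somewhat stronger
than in the real animals (e.g. hunting occupancy falls from ~80% to ~3%
across states rather than 64% to 25%); the monotone direction of every
trend, not its magnitude, is the property the defaults guarantee.

## Numerical choices and degenerate inputs

- Probability normalization tolerance 1e-9; KDE integral tolerance 1e-3.
- Zero-variance KDE samples: fixed bandwidth 0.01 (see above).
- Decimation ties: earliest label in the window, making the encoding
  deterministic.
- A subsequence of only strike frames has no probability denominator and
  raises `DegenerateSubsequence` rather than returning NaNs.
- Single-bout subsequences yield a zero count matrix (plus at most the
  RESET transition); they contribute a zero feature vector, not an error.
- CSV output carries 6 significant digits; durations recomputed from
  frame indices are exact in memory and agree with written files to that
  precision.
- Test problem sizes: recovery checks run at ≥200–600 bouts per state and
  trend checks at 10 replicates of 3 animals × 240 s trials — large
  enough that the monotone statistics are stable across seeds, small
  enough to keep the suite quick.

## Known limitations

- The two independent human scorers of the original protocol are out of
  scope: the reader accepts one label stream per video and performs no
  reconciliation or agreement scoring.
- Transition counting at bout boundaries is a modeling commitment; the
  per-frame switch exists but the two conventions are not mixed.
- The editing-cost model is global alignment with linear (per-symbol)
  indel costs; affine gaps and local alignment are intentionally absent.
- Tukey HSD inherits the balanced-variance assumptions of the standard
  implementation; with the small per-state sample sizes typical here its
  pairwise p-values are indicative, not exact.
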