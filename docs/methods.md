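# Methods

This note documents the models and procedures implemented in
`triadtalk`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not demonstrate.

## Speech-activity detection

The detector works on short-term sound levels (block mean-square in dB
SPL; the default block of 5.8 ms matches a real-time renderer running
256 samples at 48 kHz).  The processing order is: first-order
Butterworth low-pass (10 Hz cutoff) applied *causally to linear power*,
conversion to dB, then a centred rolling 100 ms Hann window applied to
the dB series.  Operating the Butterworth on power mirrors an RC level
meter; whether the Hann stage should run on dB or linear power is not
uniquely determined by the analysis tradition, so `hann_on_db` exposes
the switch (dB is the default).  Edges of the Hann window are truncated
and re-normalised, preserving DC.

The noise floor is estimated per speaker and condition from the sorted
level distribution: an OLS line through the (rank fraction, level)
pairs in the 5%-40% band, evaluated at the band midpoint.  The band
makes the estimate robust to the speech-activity fraction — for a
bimodal quiet/speech distribution it reduces to the floor mode.  The
top of the dynamic range is the 99th percentile rather than the maximum
(outlier robustness); the activity threshold sits at the 25% point of
the dynamic range above the floor.  Thresholding is strict (`>`); ties
are inactive.  Traces whose dynamic range stays under 3 dB are flagged
"no speech detectable" — a silent channel only shows the floor's own
fluctuation, and any threshold inside it would fire randomly.

Supra-threshold runs separated by pauses shorter than 1.25 s are merged
in a single left-to-right pass (transitively equivalent to merging to
convergence, which the test suite verifies against an exhaustive
pairwise oracle); merged segments shorter than 0.05 s are discarded.
Raising the threshold never increases total detected speech time; this
monotonicity is property-tested.

## Turn taking

Floor transfers are extracted by following the floor holder through the
merged utterances: when the holder's segment ends, another speaker
already talking past that point captures the floor (overlap; offset =
incoming onset minus outgoing offset, negative), otherwise the first
onset at or after it takes the floor (gap, non-negative offset), unless
it belongs to the holder (resumption — no event).  Incomers who stop
before the floor holder (failed interjections, backchannels) never
produce events.  Triadic ambiguity — two candidates available — is
resolved in favour of the earlier starter, then the longer segment,
then lexicographic speaker id; none of these rules is dictated by the
measure definitions, so they are documented here and frozen by the
oracle-equivalence tests.  Long within-speaker silences produce no
event (transfers join *different* speakers).  No maximum |FTO| cutoff
is applied by default.

## Head movement

Only yaw (rotation about the vertical axis) is analysed.  Angular
distance to the speaker uses samples where exactly one confederate is
active and the other confederate and the participant are silent.  The
per-avatar reference is the yaw toward the avatar's face; the
"between eyes and mouth" reference point collapses to the seat angle in
the yaw plane.  For the overall measure, the participant's median
distance to each avatar *across all conditions* is subtracted from the
per-sample distances before the cumulative median; this baseline
removes the systematic asymmetry toward one avatar and makes the
referenced value signable.  The unreferenced variant is stored
alongside (`angular_distance_raw`).  An alternative reading of the
baseline — subtracting the signed median yaw rather than the median
distance — is available via the `baseline` argument.

The orientation range is P95 - P5 of yaw, split by participant
speaking/listening; "listening" means "not inside an own utterance"
regardless of confederate activity (a flag in `build_state_mask`
switches to requiring confederate activity).  Speaking-phase ranges
with under 15 s of speech in a condition are excluded per participant x
condition.  Head translation is the median signed projection of head
position onto the axis toward the centre between the avatars, with the
participant's overall median position as origin.

All yaw arithmetic is wrap-aware ((-180, 180]) and
rotation-offset-equivariant, which is property-tested.

## Statistics

Behavioral measures go through a 2 (noise) x 4 (animation)
within-subject ANOVA (pingouin's two-way repeated-measures
implementation; the balanced complete design makes the sums of squares
unambiguous).  Mauchly's test runs per within factor with more than two
levels on the data collapsed over the other factor; when violated
(p <= .05) the Greenhouse-Geisser-corrected p and dfs are reported for
that factor and for the interaction, which contains it.  Partial
eta-squared is computed from the identity
`eta_p^2 = F*df1 / (F*df1 + df2)` with uncorrected dfs.  Significant
animation or interaction effects are followed by Bonferroni-corrected
pairwise comparisons of the animation marginal means; the significance
gate is exactly p <= 0.05.  A constant response yields F = 0, p = 1 by
convention (the untreated ratio is 0/0).

Ratings are ordinal; each item and each construct factor score is
tested with a Kruskal-Wallis rank-sum test (tie-corrected H) per
factor, followed — only when the omnibus p <= .05 — by Dunn's pairwise
z-tests on the pooled ranks with Bonferroni adjustment over all level
pairs.  Dunn's test is implemented in-package (tie-corrected pooled
variance) and verified against a hand-computed rank example.

One-factor models are fitted on standardized pooled responses with Q10
reverse-scored, by maximum likelihood (scikit-learn's EM) by default or
iterated principal-axis factoring as an alternative; scores use the
regression (posterior-mean) method.  A caveat established during
validation: with weakly correlated items the one-factor ML solution is
only weakly identified and can assign a near-unit loading to a single
item with a tiny specific variance (a near-Heywood configuration; R's
`factanal` behaves identically).  Individual null loadings are
therefore not guaranteed small; the stable null property — asserted in
the tests — is low mean communality.  Principal-axis fits are the more
conservative choice for noisy questionnaires.

## Synthetic data generator

The generator produces the statistical structure the analysis assumes,
with every target recoverable:

* **Floor chain** — a semi-Markov chain over three speakers (next
  speaker uniform among the other two).  Turn durations are log-normal
  with median 2.0 s (sigma 0.6): conversational turns in corpora run
  about 2 s; the shorter medians reported by level-based analyses
  describe merged activity fragments, not turns.  Transitions draw a
  gap (probability 0.7 in quiet) from an exponential with median
  0.50 s, or an overlap (exponential, median 1.11 s) clamped to 90% of
  both adjacent turns and to the incomer's availability — the clamp
  guarantees the incomer outlasts the floor holder and keeps the
  expected cycle length analytic.  In noise the gap median rises by
  0.074 s, the overlap median falls by 0.36 s, and the gap probability
  is re-solved (Brent's method on a two-dimensional Gauss-Hermite
  cycle-length expectation) so the expected gap rate rises by 0.72 per
  minute.  Backchannels arrive as a Poisson process (2/min), are placed
  inside another speaker's turn so they end before it does (never a
  floor transfer), and keep 1.55 s clearance from the producer's own
  segments so the merge rule cannot fuse them with real turns.
* **Levels** — per sample, linear-power sum of the condition's noise
  floor (48.2 / 71.1 dB SPL (C)) and, during utterances, speech at the
  speaker's base level (67.6 / 65.1 / 65.1 dB SPL for participant /
  experimenter / confederate in quiet) plus the Lombard gain of 4.6 dB
  per 10 dB of noise, a 3 dB sinusoidal level modulation at 4 Hz
  (syllabic rate, so detection thresholds face realistic dips), and
  per-utterance (1 dB), per-sample (0.5 dB) and per-participant (2 dB)
  Gaussian level jitter.
* **Head motion** — target yaw is `undershoot_gain x avatar yaw`
  (gain 0.7 +/- 0.05 across participants) of the single active
  confederate, centre otherwise; the head follows with a first-order
  lag (time constant 0.12 s, i.e. ~0.4 s to settle — a typical
  orienting response; a slower head would contaminate the per-sample
  angular-distance statistics with transition transients) plus 2 deg
  white yaw jitter.  In noise the head shifts 3 cm toward the screen.
* **Ratings** — presence and success latents are standard normal;
  success drops by 1.3 in noise.  Items are intercept + 0.8 x latent +
  N(0, 0.6), Q10 on a reversed scale, snapped to the 0.5 grid and
  clipped to [-3, 3].

What the generator does **not** emulate: prosody and spectral content
(levels only), gaze, facial expression, non-stationary noise, slow
drifts in engagement, item-specific rating intercepts, or animation
effects on behavior (only noise effects are built in).  Passing
recovery tests therefore show that the pipeline measures what the model
generates — they do not certify performance on real recordings, whose
segmentation is known to be sensitive to level-meter time constants and
thresholds.

## Known biases and limitations

* Measured speech levels include the noise floor's power; at the
  signal-to-noise ratios of the noise condition this inflates the
  recovered Lombard slope by roughly +0.1 to +0.2 dB per 10 dB.
* The 1.25 s merge rule absorbs floor transfers around short overlapped
  middle turns (roughly a sixth of transfers at the default chain
  settings) and preferentially removes small-offset events, biasing the
  detected gap median upward by a few tens of milliseconds.  This is a
  property of merged-segment turn detection itself, not of the
  implementation.
* Detected overlap magnitudes depend strongly on the overlap clamp and
  on segmentation edges; their absolute values are not comparable
  across analysis pipelines.
* The type-I-error calibrations run the reduced 2 x 2 ANOVA design
  (8 subjects) and 4 x 25 Kruskal-Wallis groups with 2000 null
  replicates; Monte-Carlo noise of about +/-0.005 on a 0.05 rate is
  inherent at that size.

## Problem sizes

The standard validation cohort is 16 participants x 8 conditions x
5 minutes, with levels at 172.4 Hz (5.8 ms blocks) and motion at
100 Hz; the full generate-and-analyse cycle runs in a few minutes on a
single CPU.  Unit tests use shorter conditions (30-120 s), and the
Monte-Carlo checks pool 10,000+ transitions.
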