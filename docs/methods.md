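# Methods

## Scope and data model

wormhab starts at trajectories, not video: the input is a per-frame
table of worm id, time (s), centroid position (mm), and body-axis
orientation (radians, toward the head), plus a tap-event log. This is
the natural hand-off point from multi-worm tracker toolchains, which
handle pixel-level outlining upstream; conversion from pixel units
(0.0233 mm/px for the reference camera) is the caller's responsibility
at the I/O boundary. Parsers for tracker-native binary formats are
deliberately out of scope (a future adapter concern), as are posture
(spine) kinematics, omega-turn classification, and egg-laying/feeding
behavior.

The recording protocol is a first-class object. The standard
tap-habituation session records ~13.5 Hz for 400 s with 30 taps at a
10-s interstimulus interval starting at 100 s; the 45-tap variant runs
550 s. Exploratory sessions are 300 s with no taps, so the protocol
type permits `n_stimuli = 0` (the stimulus-train bound is enforced
only when stimuli exist).

## Locomotion segmentation

Each inter-frame step is labeled by the velocity projected on the body
axis at the step's first sample: forward if the projection exceeds
`v_min`, backward below `−v_min`, otherwise unclassified. With only
centroid plus body-axis data this is the faithful reduction of
"movement bias relative to body orientation" segmentation. Stationary
periods and compound turns both map to unclassified, matching how such
frames are conventionally dropped from direction analysis.

Two jitter guards are exposed as config keys because published
protocols are silent on them: `v_min = 0.005 mm/s` and a bout-absorber
that relabels maximal runs shorter than `min_bout_s = 0.3 s` (~4 frames
at 13.5 Hz) into a neighboring run (the shortest offending run merges
first; a flanked run takes the longer neighbor's label). Tracks shorter
than `min_track_s = 10 s` within the analysis window are discarded as
probable imaging artifacts; the 10-s rule is applied to within-window
duration (the alternative — raw track duration — is not what the filter
is protecting against once a window is set). The analysis window
defaults to the final 60 s of the recording.

Direction speed per track is total path length in that label over total
time in it; the plate speed is the mean over animals weighted by each
animal's proportion of tracked time in that direction. Direction
fractions are pooled over all surviving tracked time, so the three
fractions partition unity exactly by construction.

## Reversal detection and habituation scoring

A reversal event is a maximal backward-labeled interval with net
displacement ≥ `min_disp_mm = 0.1 mm` (~10% of adult body length; the
threshold is a config key since tracker plugins do not publish theirs).
Duration, mean speed (path/duration), and peak step speed are measured
over the whole interval.

An animal is a responder at stimulus *k* if a reversal event *starts*
within `window_s = 2 s` of the tap. Two edge rules matter:

- **Onset resolution is one frame.** Taps in the standard protocol
  fall exactly on frame boundaries, so a response beginning within the
  first frame after a tap is timestamped at the tap itself; the scoring
  window is therefore closed on both ends, `[t_k, t_k + 2]`. A worm
  already reversing when the tap arrives is *not* a responder (it
  cannot be distinguished from a spontaneous bout); the
  `count_ongoing` flag reverses this choice.
- **Denominators.** Animals not tracked throughout the window are
  excluded from that stimulus's denominator. Whether the original
  tracker analyses did exactly this is not documented; our rule is
  explicit rather than claimed identical.

The response magnitude (duration, speed) of a responder is its event's,
even when the event outlasts the window. The "speed of the response" is
the mean reversal speed by default; peak speed is exposed as an option.
Accelerations — the non-reversal response mode of ~10% of naive
animals — are not modeled distinctly from non-response.

## Exponential fit and phenotypes

Per plate, defined response probabilities are fit by bounded nonlinear
least squares to `p(k) = a + b·exp(−(k−1)/λ)` with `a ∈ [0,1]`,
`b ∈ [−1,1]`, `λ ∈ (0, 10n]`, deterministic initialization
(`a₀ = min p`, `b₀ = p₁ − a₀`, `λ₀ = n/4`; no random restarts, so fits
are bit-reproducible), and tight tolerances (1e−14). If the optimizer
fails, a 400-point geometric grid over λ with a closed-form linear
solve for (a, b) stands in and the fit is flagged unconverged. At least
4 defined stimuli are required.

The **habituation level** is the curve at the final stimulus — the
operationalized asymptote, preferred over the raw `a` because a curve
still declining at stimulus *n* has not expressed its mathematical
asymptote. The **habituation rate** is the half-life `λ·ln 2`. Flat
profiles (`|b| < 0.01`) are a degeneracy: λ is unidentifiable, so the
level reports the profile mean and the half-life is NaN. Undefined
values throughout the package are NaN, never zero.

Group display curves can be fit to cross-plate mean profiles
(`mean_profile`), but inference always uses per-plate fits: one plate,
one datum.

## Group statistics

Student's pooled-variance unpaired two-tailed *t* (df = n₁+n₂−2) is the
primary test, matching the original analysis; Welch is deliberately not
the default. Zero pooled variance is given documented limit behavior
(p = 1 for equal means, p = 0 otherwise) instead of NaN. The
Mann–Whitney *U* check is exact for min(n) ≤ 8 without ties — the U
distribution is enumerated by dynamic programming and the two-sided p
doubles the smaller tail, capped at 1 — and otherwise uses the normal
approximation with tie and continuity corrections. No multiplicity
correction is applied to reported p-values; an advisory flag notes
whether the t-test survives Bonferroni correction at α = 0.05 for a
stated number of comparisons (default 5). Harsh-touch data reduce to
one datum per day (the 20-animal mean); percent reduction is
`100·(mean_ref − mean_test)/mean_ref`, signed.

## The simulator

The generator emulates the statistical structure the analysis assumes,
not worm biomechanics. Per worm: a forward crawling speed (truncated
normal), a heading random walk (0.4 rad/√s) with a uniform reorientation
turn after each reversal, tap-evoked reversals with Bernoulli
probability `p_asym + (p_init − p_asym)·exp(−(k−1)/τ)` — the same
family the analysis fits, chosen so parameter-recovery tests have exact
ground truth — uniform (0, 1 s] onset latency (inside the 2-s scoring
window by construction), truncated-normal duration and speed,
spontaneous reversals as a Poisson process, pauses as a Poisson renewal
process calibrated to a target time fraction, and tracker dropouts
(Poisson losses with ~3-s exponential gaps) that re-acquire the worm
under a fresh id, exercising the short-track filter and denominator
rules. Two structural constraints keep the generative truth and the
measurement consistent:

- Kinematic state is evaluated at inter-frame midpoints and integrated
  over frames, so recorded displacements match generative speeds
  exactly (before optional pixel quantization, off by default).
- A spontaneous reversal cannot begin while an evoked one is in
  progress: a worm is already reversing, and an abutting pair would be
  indistinguishable from one long bout. Without this refractory rule,
  bout merging inflates measured response durations by several
  hundredths of a second and depresses measured response probabilities.

Reversal durations are truncated below at 0.4 s — above the 0.3-s
bout-absorber — so segmentation cannot delete a genuine evoked
reversal; the truncation shifts the duration mean by <0.3%.

Preset parameters encode the published phenotypes where printed values
exist (wild-type p₁ = 0.91, mutant 0.954; durations 2.74/2.69 s; speeds
0.282/0.279 mm/s; mutant exploration 18% slower; 5% pause fraction;
40% harsh-touch reduction) and field-realistic choices where they do
not: τ = 4 stimuli (curves flatten well before stimulus 30), wild-type
habituated asymptote 0.39 (fitted level ≈ 0.4), mutant asymptote 0.75
(published only as "significantly higher"), exploration forward speed
0.15 mm/s, harsh-touch bends 5.0 ± 1.5 per animal (the published figure
is graphical only), spontaneous-reversal rates 0.005 Hz on tap plates
vs 0.03 Hz during food-free local search.

What simulated data do **not** contain: posture, body-length scaling,
speed modulation near reversals, sensitization or spontaneous recovery,
inter-worm interactions, spatially structured tracking failure (edge
effects), or acceleration responses. Passing recovery tests therefore
demonstrates that the analysis measures what the generative model
encodes at realistic sampling noise — not that it is robust to every
artifact of real video tracking.

## Reproducibility and problem sizes

Every stochastic routine takes an explicit seed and uses a single
generator per call; there is no global random state. The CLI derives
per-plate seeds as `SeedSequence(master, spawn_key=(plate_index,))`
reduced below 2³¹, logged per plate in the run manifest, so any plate
can be regenerated in isolation and identical config + seed yields
byte-identical tables. Trajectory floats are written with Python's
shortest round-trip representation (read∘write is the identity); event
times are written at millisecond resolution.

The recovery suite runs the study's own designs — 6 wild-type plates of
75 worms for the single-experiment estimates, 15 experiments for the
replicate aggregate (3 plates × 50 worms in the test suite, 4 × 75 in
the acceptance script; both inside the published 3–6 plates of 50–100
animals), 4 mutant plates, 5 harsh-touch days × 20 animals, and 6
exploratory plates of 30 worms. Distributional properties use scaled
designs chosen for statistical power per unit time: the decay-curve
goodness-of-fit pools 200 small plates; the type-I-error calibration
draws 500 null pairs of harsh-touch day means, where the plate/day
datum is exchangeable with the full trajectory pipeline at a fraction
of its cost.

## Known limitations

- The fitted level is mildly design-dependent: with τ = 4 the curve is
  flat at stimulus 30, but for slow decays (λ comparable to n) level
  estimates inherit the fit's end-of-curve extrapolation variance.
- The exact Mann–Whitney branch requires tie-free data; integer-valued
  day means with ties fall back to the corrected normal approximation
  even at small n.
- Step labels across tracking gaps classify the gap's mean velocity;
  long gaps dilute speed estimates slightly rather than being split.
- The harsh-touch percent-reduction estimator at the 5-day × 20-animal
  design has a sampling SD of ~3.8 percentage points under the default
  presets; single comparisons routinely land a few points from the
  generative 40%.
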