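# Methods

`crisiswarn` implements a deterministic model of emotion dynamics for
screening psychological-crisis risk from a person's post timeline. This
note records the model, its assumptions, the constants that matter, and
the design choices made where the underlying formulation was open.

## Model overview

The state is a signed 6-component intensity vector on Ekman's basic
emotions, ordered `(dis, ang, sur, fea, joy, sad)`. Surprise and joy are
positive-valence and live in [0, 1]; disgust, anger, fear and sadness are
negative-valence and live in [−1, 0] (more negative = more intense). The
state advances in daily steps:

```
I_t = clip( I_{t−1} · e^{−λ}  +  Θ_t  +  Φ(P) )
```

* **Decay** — every component attenuates by `e^{−λ}` per day. λ ≥ 0 is the
  attenuation factor (default 0.5/day, giving a half-life of ~1.4 days);
  larger λ means faster emotional recovery.
* **Stimulus Θ_t** — the combined influence of the stress events detected
  in that day's posts: the weighted per-event stimulus vectors of the
  unique events are summed and clipped to [−1, 1]. By default a stimulus
  is an impulse on its detection day only; persistence then arises from
  slow decay. A `sustained` mode re-applies the stimulus for a fixed
  number of days (default 3), for users who read stress events as
  episodes rather than shocks.
* **Personality bias Φ(P)** — a constant vector derived from the Big-Five
  profile (below), scaled by a gain (default 0.1) and signed by valence.
* **Clip** — each component is clipped into its valence range, so a
  positive emotion can never go below 0 and a negative one never above 0
  (no cross-valence leakage).

With constant Φ and no stimulus the recurrence is affine with the exact
solution `I_t = Φ (1 − e^{−λt}) / (1 − e^{−λ})`; the test suite checks the
iteration against this closed form to 1e−9.

## Personality chain

`Φ(P)` is produced by a three-stage linear chain:

1. **Big-Five → PAD.** `M = P K^T`, with `P = [o, c, e, a, n]` ∈ [0,1]⁵ and
   `K` (3×5) the linear regression from Big-Five traits onto the Pleasure/
   Arousal/Dominance mood axes used by the ALMA affect model. Example: the
   "open" reference profile [0.8, 0.2, 0.6, 0.4, 0] maps to
   M = (0.362, 0.240, 0.466).
2. **PAD → OCC.** `O = M F`, with `F` (3×24) whose column j is the PAD
   coordinate of the j-th OCC appraisal category; `O_j` is therefore the
   alignment of the current mood with that emotion's direction in mood
   space. Disgust and Surprise are not OCC categories; their columns use
   Mehrabian's emotion-term PAD coordinates.
3. **OCC → Ekman.** Disgust and Surprise pass through; anger is the mean
   of {Anger, Reproach, Hate}; fear the mean of {Fear, FearsConfirmed};
   sadness the mean of {Resentment, Pity, Distress, Shame, Remorse}; joy
   the mean of the 12 distinct positive categories. (A frequently
   reprinted version of the joy formula lists 14 terms with two
   duplicates over a divisor of 12; the 12-distinct-terms reading is the
   consistent one and is what we implement.)

The raw chain output is scaled by a **gain** and **valence-signed**
(negative emotions get −|·|, positive +|·|). Unscaled, the chain's
magnitudes (up to ~0.43 for fear) would push a quiescent person past
activation thresholds with no stimulus at all; the default gain of 0.1
keeps the personality bias a small standing tendency, matching the
intended pre-stimulus quiescence. Both K and F, and the gain, are
replaceable through the run configuration.

The exact numeric K and F behind the original formulation are not
published; ours are the standard ALMA coefficients. Conclusions that
depend on fine quantitative detail of Φ(P) should be read accordingly.

## Activation thresholds

Expression is thresholded, not continuous. With ξ = c + e − n (the
conscientiousness + extraversion vs. neuroticism balance), the negative
threshold is

```
ω_neg = (arctan ξ + π/2) / π ,   ω_pos = 1 − ω_neg
```

an S-shaped psychophysics-style transfer mapping ξ ∈ (−∞, ∞) into (0, 1).
A positive emotion is expressed when its intensity ≥ ω_pos; a negative one
when its magnitude ≥ ω_neg (negative intensities are stored signed,
thresholds are magnitudes — the only consistent reading given the ranges).
For the "open" reference profile ξ = 0.8 gives ω_neg ≈ 0.715 / ω_pos ≈
0.285; for the "neurotic" profile ξ = −0.2 gives ω_neg ≈ 0.437 / ω_pos ≈
0.563. One global threshold pair per person is used, not per-emotion
thresholds.

## Stress-event detection

Detection is dictionary-based: a post expresses an event when its
normalised (NFKC, case-folded) text contains one of the event's trigger
phrases as a substring. Substring rather than token matching is
deliberate — it works for unsegmented scripts (the intended source data is
Chinese social media) as well as spaced ones; a `token_boundaries` flag
adds word-boundary checks for space-delimited languages. Nested matches
are resolved longest-phrase-first per offset, and accepted matches do not
overlap. An event counts once per day regardless of repeat mentions.

The bundled lexicon (`data/default_lexicon.tsv`) covers the 14 student
stress events of the youth section of a Life-Events-Units-style checklist
(bereavement, parental divorce, dismissal, serious family illness,
break-up, awards, injury, new relationship, disciplinary action,
admission setback, joining an organisation, dropping out, academic/job
failure, learning difficulties) plus a placeholder 15th entry (the source
checklist counts 15 but enumerates 14). Its English phrases and stimulus
vectors are hand-set synthetic fixtures for testing, **not** a validated
instrument; real deployments must supply their own lexicon.

## Warning layer

Per-post activations are collapsed to one record per UTC calendar day:
`pos` = max expressed positive intensity, `neg` = max expressed negative
magnitude (the daily-maximum rule, identity for a single post). Days with
no posts score zero and break negative runs — no imputation. Two inputs
feed the warning score:

* `ΔI = neg − pos`. With the **flip-swing rule** (default on), a day whose
  dominant valence flips from positive to negative scores the full swing
  `today.neg + yesterday.pos`, so a 0.8 → −0.8 reversal scores 1.6 rather
  than 0.8. This operationalises "drastic emotional change"; it is an
  interpretation and can be disabled.
* `ΔT` = consecutive days of expressed negative affect ending today,
  divided by a reference duration (default 3 days). Raw day counts would
  saturate the logistic within ~5 days regardless of severity; scaling by
  the "persistent negative affect" reference keeps the two inputs
  commensurate.

The warning value is `g = 1 / (1 + e^{−(ΔI + ΔT_scaled)})` ∈ (0, 1),
banded into five levels with the printed interval semantics:
[0, 0.2] Security/Green, (0.2, 0.4) Safer/Blue, [0.4, 0.6]
Criticality/Yellow, (0.6, 0.8) More dangerous/Orange, [0.8, 1]
Dangerous/Red. A fully quiet day scores g = 0.5 — the model's neutral
point sits mid-scale (Criticality) by construction of the logistic, not
at Security. Whether ΔI and ΔT should be combined additively in one score
or raised as two separate alarms is ambiguous in the source formulation;
the joint sum is implemented.

## Reference scenarios and calibration

Four scenarios cross the "open" ([0.8, 0.2, 0.6, 0.4, 0]) and "neurotic"
([0, 0.6, 0.1, 0.1, 0.9]) profiles with a positive
([0.2, 0.1, 0.3, 0.1, 0.7, 0.3]) and a negative
([−0.5, −0.7, −0.1, −0.4, −0.5, −0.5]) stimulus applied at day 3 of a
10-day horizon, from an all-zero initial state. The decay factor and gain
behind the originally narrated trajectories are unstated, so
`calibrate()` grid-searches λ ∈ {0.1 … 1.0 step 0.1} × gain ∈
{0.05 … 1.0 step 0.05} against a qualitative template of narrated events
(first activation, deactivation, threshold crossings) and reports *all*
consistent parameter pairs rather than asserting one, plus the best
partial match when no pair satisfies everything. The gain grid extends to
1.0 because joy recovery above ω_pos within a few days of a −0.5 hit is
impossible below gain ≈ 0.5 — small-gain grids admit no re-crossing at
all.

A structural finding worth recording: for the open/negative scenario the
narrated sequence "negative crossing at day 5, joy re-crossing at day 6"
is **not reproducible** under this recurrence for any (λ, gain, stimulus
persistence, initialisation) we searched. The anger component of the
negative stimulus (−0.7) lands within 0.015 of the open profile's
ω_neg ≈ 0.715, so the maximum negative magnitude crosses the threshold at
the stimulus day itself for any non-trivial gain, one day later under a
sustained stimulus, or never — a crossing two days post-impulse would
require the state to keep growing after an impulse, which a decaying
linear system cannot do. The best reproducible pattern is crossing at
day 3 with joy re-crossing at day 6; the corresponding check in the
acceptance suite is left failing by design rather than weakened.

## Synthetic timelines

`generate_timeline(seed, schedule, lexicon, ...)` emulates a student's
daily posting: for each day it emits `posts_per_day` posts of filler
sentences (screened at generation time to be disjoint from every lexicon
phrase), embedding the scheduled events' trigger phrases in the day's
first post, with seeded jittered UTC timestamps. Output is byte-identical
for a fixed seed, and detection provably round-trips the schedule.

What the generator does *not* emulate: colloquial or oblique expressions
of distress (the hard NLP problem is out of scope — detection here is
exact phrase matching), multi-user interaction, posting-frequency
responses to mood, or any real linguistic distribution. Passing tests
therefore demonstrate the correctness of the pipeline's mechanics, not
detection recall on real social-media text.

## Numerical and interface choices

* Time is 1-based in days; timestamps are normalised to UTC and days are
  UTC calendar days.
* Threshold comparisons are inclusive (≥); band boundaries follow the
  printed closed/open brackets exactly; warning values are written with 6
  decimals so banding is reproducible from the CSV.
* Ties in daily dominant valence (pos == neg > 0) are called negative
  (conservative for a screening tool).
* All randomness flows through `numpy.random.default_rng(seed)`; scenario
  simulation and scoring are fully deterministic.
* Problem sizes used by the reproduction script: 10,000-step randomized
  simulation for the intensity bound; a 10 × 20 calibration grid over a
  10-day horizon for the scenario targets.

## Limitations

* The transfer matrices K and F are literature defaults, not fitted to
  any cohort; Φ(P) is a plausible constant bias, not an estimate.
* The fixture lexicon is synthetic; per-event stimulus vectors have no
  empirical calibration.
* The model is deterministic and single-user; no uncertainty, no
  population-level ranking, no intervention modelling.
* A quiet timeline scores g = 0.5 ("Criticality"), i.e. the scale's
  neutral point carries an alarming label — interpret bands relative to
  0.5, or re-band for deployment.
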