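# crisiswarn

Early-warning screening of psychological-crisis risk from a person's post
timeline, built on a deterministic model of emotion dynamics. The intended
users are researchers in affective computing and computational mental
health who want a tested, reproducible reference implementation of the
personality → mood → emotion → threshold → warning pipeline, with a
synthetic-data generator for end-to-end experiments.

## Model

The emotion state is a signed vector `I_t` on Ekman's six basic emotions
`(dis, ang, sur, fea, joy, sad)` — surprise and joy in [0, 1], the
negative emotions in [−1, 0] — advanced in daily steps:

```
I_t = clip( I_{t−1} e^{−λ} + Θ_t + Φ(P) )
```

* `Θ_t` — stimulus of the stress events detected in day *t*'s posts by
  case-folded substring matching against a lexicon of trigger phrases,
  each event carrying a weighted 6-component stimulus vector.
* `Φ(P)` — constant personality bias: the Big-Five profile `P` is mapped
  into PAD mood space (`M = P Kᵀ`), projected onto 24 OCC emotion
  categories (`O = M F`), collapsed to the six Ekman emotions by
  passthrough/mean formulas, then gain-scaled and valence-signed.
* Activation is thresholded by the personality balance `ξ = c + e − n`:
  `ω_neg = (arctan ξ + π/2)/π`, `ω_pos = 1 − ω_neg`; an emotion is
  expressed only when its magnitude reaches its valence threshold.

Expressed emotions are aggregated per UTC day (daily maxima `pos`, `neg`)
and scored with the logistic warning function

```
g(ΔI, ΔT) = 1 / (1 + e^{−(ΔI + ΔT)})
```

where `ΔI = neg − pos` (a positive→negative valence flip scores the full
swing) and `ΔT` is the run of consecutive negative days scaled by a 3-day
reference. `g` is banded into five levels: [0, 0.2] Security/Green,
(0.2, 0.4) Safer/Blue, [0.4, 0.6] Criticality/Yellow, (0.6, 0.8) More
dangerous/Orange, [0.8, 1] Dangerous/Red.

See `docs/methods.md` for assumptions, constants and limitations — in
particular, the bundled lexicon is a synthetic test fixture, not a
clinical instrument.

## Worked example

Generate a 6-day synthetic timeline in which the user mentions dropping
out on day 3 and a break-up on day 4, then score it for a high-neuroticism
profile (`ξ = −0.2`, so negative emotions activate at magnitude ≈ 0.437):

```
crisiswarn synth --seed 7 --days 6 \
    --schedule '{"3": ["drop_out_of_school"], "4": ["lovelorn"]}' --out tl.jsonl
crisiswarn score --timeline tl.jsonl --personality 0,0.6,0.1,0.1,0.9
```

```
date,pos,neg,delta_i,delta_t_days,warning_value,level,color
2024-03-01,0.000000,0.000000,0.000000,0,0.500000,Criticality,Yellow
2024-03-02,0.000000,0.000000,0.000000,0,0.500000,Criticality,Yellow
2024-03-03,0.000000,0.749813,0.749813,1,0.747089,More dangerous,Orange
2024-03-04,0.000000,1.000000,1.000000,2,0.841131,Dangerous,Red
2024-03-05,0.000000,0.619638,0.619638,3,0.834745,Dangerous,Red
2024-03-06,0.000000,0.000000,0.000000,0,0.500000,Criticality,Yellow
```

Quiet days sit at the neutral point g = 0.5. The day-3 event drives the
expressed negative magnitude to 0.750, and with one negative day on the
clock the score reaches 0.747 (More dangerous). The day-4 break-up stacks
on the decayed day-3 state, saturating negative intensity at 1.0 and a
2-day run pushes g to 0.841 (Dangerous). By day 5 intensities decay but
the 3-day negative run keeps g at 0.835; day 6 is quiet and the score
returns to baseline.

Scenario trajectories are available directly
(`crisiswarn simulate --personality open --stimulus negative`), as are
lexicon detection (`crisiswarn detect`) and grid calibration of the decay
factor and personality gain against narrated scenario events
(`crisiswarn calibrate`). The same functionality is importable from
`crisiswarn` as a library.

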