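# gobypass

Personality-informed risk assessment of whether nonmigratory benthic fish
ascend an in-stream barrier.

Classical fish-passage models assume every fish attempts to ascend a
barrier at all times, so the only limits are swimming performance against
flow.  For nonmigratory species — the motivating case is the invasive
round goby (*Neogobius melanostomus*) spreading upstream through fish
bypasses — that assumption is unrealistic: whether an individual even
*intends* to ascend depends on its personality.  `gobypass` implements a
risk-assessment pipeline that combines both:

1. **Swim decision** — critical swimming speed, modelled as linear in
   total length, `Ucrit(TL) = a·TL + b` (m/s), must exceed the barrier's
   maximum near-bottom flow velocity.
2. **Endurance decision** — endurance at flow `v` (cm/s) follows
   `log10 E = −0.027·v + 0.007·TL + 0.516` (E in minutes); the distance
   covered swimming at Ucrit for time E must exceed the largest gap
   between two resting pools.
3. **Personality decision** — three assay-scored indices (boldness =
   `log(3600) − log(latency to move)` after a simulated predator attack;
   activity = moves > 1 cm per 6-s frame; asociability = mean distance
   from a conspecific stimulus pair) are compared against a-priori
   thresholds set at the trait means of "invasion front" populations,
   with a compensatory 2-of-3 rule.

An individual ascends iff all three decisions pass.  A statistical layer
(binary logit fitted by IRLS with explicit handling of the
quasi-complete separation this design induces, all-subset AIC model
building, Hosmer–Lemeshow goodness of fit, Spearman rank correlations,
and skewness/kurtosis checks on the traits) relates ascent to the
measured predictors.  A synthetic-data module generates cohorts, assay
recordings and barrier flow profiles with the study's distributional
structure, so the whole pipeline is testable without field data.

## Worked example

The reference individual — 12.2 cm total length, boldness 1.71, activity
1.76, asociability 0.47 — against the shipped reference barrier (maximum
near-bottom flow 0.50 m/s, maximum pool spacing 4.54 m) and thresholds
(1.13, 1.17, 0.95):

```python
from gobypass import (FishRecord, SwimModel, ThresholdSet,
                      run_decision_matrix, worked_example_profile)

profile = worked_example_profile()
thr = ThresholdSet(boldness_mean=1.13, activity_mean=1.17,
                   asociability_mean=0.95, flow_limit_m_s=0.5,
                   distance_limit_m=4.54)
fish = FishRecord("example", tl_cm=12.2, boldness=1.71,
                  activity=1.76, asociability=0.47)
[trace] = run_decision_matrix([fish], profile, SwimModel(), thr)
```

which prints, field by field:

```
Ucrit          0.61 m/s   (limit 0.50 m/s)  -> decision 1 = 1
endurance      0.178 min
distance       6.53 m    (limit 4.54 m)    -> decision 2 = 1
traits above   2 of 3  (need 2)          -> decision 3 = 1
overall        1
```

The fish swims faster than any measured bottom flow (0.61 > 0.50 m/s),
can cover 6.53 m at Ucrit — more than the worst 4.54 m pool gap — and is
above-average bold and active (its low asociability is compensated by
the 2-of-3 rule), so it is predicted to ascend.

A full synthetic run (161 invasion-front + 98 invasion-center
individuals, thresholds derived from the front cohort):

```
$ gobypass run --seed 1 --out run1
$ cat run1/summary.txt
gobypass run summary
====================
individuals:        259 (0 excluded)
successful ascents: 42 (16.2% of scored)
flow limit:         0.500 m/s
distance limit:     4.54 m
thresholds (front means): boldness 1.159, activity 1.186, asociability 0.953
logit: deviance 104.377, AIC 114.377, LR chi2 125.221 (df 4, p 4.09e-26), 92% classified correctly
separation warning: True
Hosmer-Lemeshow: chi2 1.609 (df 8, p 0.991)
```

About one in six simulated fish ascends; length and boldness dominate
the fitted model, and the separation warning is expected — the outcome
is a deterministic function of the predictors, so the logit sits at its
capped solution.  CLI subcommands `simulate`, `score`, `decide`, `fit`
inside `run` can also be used stage by stage; all tabular I/O is CSV
with headers, configs are JSON or YAML.

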