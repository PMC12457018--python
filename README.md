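# paceline

Analysis pipeline for a pace-of-life question in a free-living small mammal:
does date of birth within the breeding season drive the apparent association
between personality and metabolic rate?  The package re-implements, as
tested reusable code, the full chain used to answer that question in female
bush Karoo rats (*Otomys unisulcatus*):

* **Respirometry** — pull-mode (excurrent-flow) O₂/CO₂ traces are converted
  to whole-animal oxygen consumption by the exact mass balance
  `VO2 = FR_dry [(FiO2 − FeO2) − FeO2 (FeCO2 − FiCO2)] / (1 − FeO2)`;
  resting metabolic rate (RMR) is the lowest 30-s mean in the last 10 min
  before the first acoustic alarm, Kleiber-scaled by body mass^0.75, and the
  acute-stress response is the peak and 1-min integral of VO₂ after each
  alarm, in % over resting, averaged over two alarms.
* **Life history** — age at first capture from the inverted Gompertz growth
  curve `age(M) = ln(ln(88/M)) / (−0.052) + 15` (valid to 65 g ≈ 38 days),
  hence date of birth, with 14- and 28-day coarsened variants for
  robustness.
* **Mixed models** — REML linear mixed models and Laplace binomial-logit
  mixed models with crossed random intercepts, written for the model shapes
  this study needs; repeatability as the intraclass correlation
  `R = σ²_ind / (σ²_ind + σ²_res)` (latent scale `σ²_ind / (σ²_ind + π²/3)`
  for the binary boldness trait) with parametric-bootstrap CIs and
  Monte-Carlo permutation p-values; the nine marginal behaviour→MR models.
* **Path analysis** — piecewise structural equation models over the study's
  directed acyclic graph (birth date → three correlated behaviours; birth
  date, year, age class, temperature, food, body mass, behaviours → one MR
  response), standardized coefficients, correlated errors among the
  behaviours, and global fit by the d-separation basis set with Fisher's
  `C = −2 Σ ln pᵢ ~ χ²(2k)`.
* **Synthetic data** — a generator that emulates the study's causal and
  noise structure (seasonal births, behavioural syndrome, ICC targets,
  chamber washout, alarm-locked peak–decay responses), so every stage is
  testable without any field data.

## Worked example

Simulate a 75-female study (up to four test sessions each) and run the whole
analysis:

```python
from paceline import GeneratorConfig, PipelineConfig, run_pipeline

cfg = PipelineConfig(
    generator=GeneratorConfig(n_individuals=75, sessions_per_individual=4,
                              survival_prob=0.85, rng_seed=42),
    n_permutations=200, n_bootstrap=200, rng_seed=42, output_dir="demo_out")
report = run_pipeline(cfg)
print(report.path_results["rmr"].summary())
```

The RMR path model prints (excerpt):

```
edge                                    beta      se       p
birth_date -> exploration              0.388   0.082  0.0000
birth_date -> distance                 0.281   0.084  0.0008
birth_date -> entry                    0.417   0.108  0.0001
birth_date -> rmr                      0.300   0.059  0.0000
temperature -> rmr                    -0.253   0.029  0.0000
year -> rmr                            0.696   0.055  0.0000
exploration -> rmr                     0.070   0.041  0.0877
distance -> rmr                       -0.019   0.038  0.6198
...
Fisher's C = 8.97, df = 6, p = 0.175
marginal R2[rmr] = 0.671
```

Later-born animals are more exploratory, travel further, enter the arena
more readily and have a higher RMR, while the *direct* behaviour→RMR paths
are null — the behaviour–metabolism correlation that the nine marginal
models do show (e.g. exploration→RMR β = 0.100 here) is carried by birth
date.  Fisher's C does not reject the generating graph.  `report` also
holds the repeatability tables (short-term sessions 1–2 and long-term
sessions 1–4), the nine-model association table, and a robustness block
(14-/28-day birth-date coarsening and the inverted-direction path models).

The same run is available from the shell:

```bash
paceline run --seed 42 --out demo_out       # full pipeline
paceline simulate --seed 42 --out bundle    # cohort + raw traces only
respiro --trace bundle/traces/R001_s1.csv --mass 90   # one trace -> RMR/stress
```

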