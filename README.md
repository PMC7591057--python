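# metastatic-bottleneck

A stochastic model of the **metastatic bottleneck** — the initiation
phase in which a freshly seeded colony of tumor cells must survive
hostile conditions at a secondary site — and of its consequences for
clinical outcome as a function of primary-tumor size at diagnosis.

The package is written for biostatisticians and modellers working with
registry-style cancer data (tumor diameter at diagnosis, metastasis
detection, cause-specific survival).  It provides:

* the colony-initiation birth–death process and its closed-form
  survival law,
* tumor-size-dependent probabilities of cancer death and metastasis
  detection, quantile times to death, and predicted survival curves,
* predicted impacts of treatment changes (surgery delay, chemotherapy
  boost, bottleneck strengthening),
* a synthetic cohort generator drawn exactly from the model's own
  assumptions, diameter-binned epidemiological summaries with three
  cancer-death estimators, and a per-cancer parameter fitter,
* a `metbneck` command-line interface over the whole pipeline.

## The model

A nascent colony of `i` cells experiences an Allee effect: each cell's
proliferation-to-death rate ratio is `λ_i/μ_i = i/b`, where `b` is the
bottleneck severity.  The colony grows by one cell with probability
`p_i = i/(i+b)`, shrinks otherwise, and is extinct at size 0.  Survival
from `i` cells is the Poisson CDF

    s_i(b) = F_Pois(i − 1; b),     s_1(b) = e^(−b),

so `⌈b⌉` is the critical size at which survival odds flip.  The primary
tumor — an exponentially growing sphere (doubling time `D`) shedding
cells from its surface, calibrated to 1.5 × 10⁵ cells/day at 1 g with
extravasation probability 0.8 — produces `N(t)` seeding attempts by
time `t`, each succeeding with probability `s_1(b)`, giving the
metastasis probability `M(t; b) = 1 − exp(−s_1(b)·N(t))`.  Conditioning
on being alive at diagnosis and on treatment removing young metastases
(irremovability age ~ Exponential(`a`)), and marginalizing `b` over a
per-patient log-normal frailty (location `μ`, scale `σ`), yields the
cancer-death and detection probability curves and the quantile times to
death used for fitting and validation.  Six parameters per cancer:
`δ₀, δ₁, a, h, μ, σ`.  See `docs/methods.md` for the full account.

## Worked example

```python
import metastatic_bottleneck as mb

law = mb.ColonyLaw(b=17.0)
print(f"s_1(17)        = {mb.survival_probability(1, law):.2e}")
print(f"critical size  = {mb.critical_size(law)} cells")
print(f"s_18(17)       = {mb.survival_probability(18, law):.3f}")

params = mb.demo_params()          # generic carcinoma, median b = 17
for d in (1.0, 2.0, 4.0):
    det = mb.detection_probability(d, params)
    death = mb.death_probability(d, params)
    med = mb.quantile_time_to_death(mb.QuantileQuery(d=d, q=0.5), params)
    print(f"d = {d:.0f} cm: P(detect) = {det:.3f}  P(cancer death) = {death:.3f}  "
          f"median time to death = {med:.2f} y")

boost = mb.Scenario(kind="bottleneck_boost", c2=1.2)
chemo = mb.Scenario(kind="chemo_boost", c1=1.2)
print(f"impact at 1 cm: bottleneck +20% -> {mb.impact_marginal(1.0, boost, params):+.3f}, "
      f"chemo +20% -> {mb.impact_marginal(1.0, chemo, params):+.3f}")
```

prints

```
s_1(17)        = 4.14e-08
critical size  = 17 cells
s_18(17)       = 0.564
d = 1 cm: P(detect) = 0.276  P(cancer death) = 0.495  median time to death = 1.28 y
d = 2 cm: P(detect) = 0.330  P(cancer death) = 0.534  median time to death = 1.12 y
d = 4 cm: P(detect) = 0.380  P(cancer death) = 0.570  median time to death = 1.05 y
impact at 1 cm: bottleneck +20% -> -0.090, chemo +20% -> -0.003
```

Reading the numbers: a single disseminated cell facing the modal
bottleneck (`b = 17`) almost never founds a metastasis (4 × 10⁻⁸), but
a colony that reaches 18 cells survives with probability 0.56 — the
transition at the critical size is sharp.  Detection and death
probabilities rise with tumor diameter while the median time to death
falls, and strengthening the bottleneck by 20% lowers the death
probability ~30× more than boosting chemotherapy efficacy by 20% under
these parameters.

The same pipeline is scriptable from the shell:

```sh
metbneck simulate-colony --b 2 --i0 1 --replicates 100000 --seed 1
metbneck run --config config.yaml        # synthesize -> ... -> predict
```

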