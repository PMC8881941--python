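# metabosense

Can people consciously feel how hard their metabolism is working? `metabosense`
implements a complete analysis pipeline for psychophysical studies of
**metabolic-rate perception** during assisted walking: experiments in which a
wearer's energetic cost is manipulated (for example by ankle-exoskeleton
assistance), measured breath by breath through indirect calorimetry, and
probed with sequential forced-choice questions ("is the current level of
exertion higher than the previous one?"). The pipeline turns raw breath data
and binary responses into per-participant **Just Noticeable Difference (JND)**
posteriors, compares competing perceptual models, and reports cohort-level
statistics. A synthetic-study generator with known ground truth makes every
stage testable end to end.

## Model

Responses in the sequential discrimination task are modeled with a logistic
psychometric function of the reference-normalized stimulus
x = 100·(B − A)/A (percent change of net metabolic rate from reference trial
A to comparison trial B):

```
Ψ(x; α, β, γ, λ) = γ + (1 − λ − γ) / (1 + exp(−β (x − α)))
```

with threshold α = 0, guess rate γ = 0.02, lapse rate λ = 0.02, and the slope
β as the single free parameter. The JND — the change detected with 75%
accuracy, equivalently the Weber fraction in percent — is

```
JND = k / β,   k = ½ ln[ ((0.75 − γ)(1 − λ − 0.25)) / ((1 − λ − 0.75)(0.25 − γ)) ]
```

Per-trial net rates come from a first-order cardiopulmonary transient fit
y(t) = y_ss + (y₀ − y_ss)·e^(−t/τ) to 2-minute breath-by-breath recordings,
minus a 4-minute standing baseline. JND posteriors use a uniform 0–70% prior
and MCMC; three model structures (pooled / independent / variable Weber
fraction) are compared by WAIC. See `docs/methods.md` for the full account.

## Worked example

Run a small synthetic study (4 participants × 6 blocks of 10 trials) through
the whole pipeline:

```python
from metabosense.io import RunConfig, run_pipeline
from metabosense.synthetic import StudyConfig
from metabosense.inference import McmcSettings

cfg = RunConfig(
    study=StudyConfig(n_participants=4, blocks_per_participant=6),
    mcmc=McmcSettings(chains=8, tune=1000, draws=4000, thin=2),
    pooled_mcmc=McmcSettings(chains=8, tune=1000, draws=4000, thin=2),
    seed=7,
)
results = run_pipeline(cfg, "out")
```

This prints (per participant: posterior-mode JND and 95% credible interval):

```
P01 JND 65.0% CI (34.6, 69.4)
P02 JND 37.7% CI (22.8, 67.6)
P03 JND 11.9% CI (6.4, 36.4)
P04 JND 26.5% CI (16.1, 61.2)

      model   score   se  p_eff  d_score  d_se
independent -122.46 7.20   3.53     0.00  0.00
variable_wf -123.06 7.40   5.26     0.60  1.08
     pooled -125.07 6.32   1.03     2.61  3.06
```

The generating (true) JNDs were 46.0 / 49.1 / 16.9 / 51.3% — each falls
inside its 95% interval, and intervals are wide because ~54 comparisons per
participant carry limited information (posteriors of insensitive participants
press against the 70% prior bound, as expected). The WAIC table (elpd scale,
higher is better) ranks the independent-JND model first: participants differ,
so a single pooled JND underfits, while the two-JND variable-WF model pays
more in effective parameters (`p_eff`) than it gains. The cohort report in
`results["cohort"]` gives the mean JND (35.3%, SE 11.2%) and the probability
that an average participant would perceive a given rate change, e.g. 57% for
a 9.6% change under this small cohort's curve.

The same pipeline runs from the shell:

```
metabosense run --config config.yaml --seed 7 --out out/
metabosense report --results out/ --deltas 9.6
```

and the individual stages (`simulate`, `metabolics`, `fit`, `compare`,
`report`) are available as separate subcommands. Real study data can be
ingested by exporting it to the documented CSV schema (see
`metabosense.io`) — `truth.json` is optional.

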