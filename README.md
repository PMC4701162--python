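# lanchester-abc

Simulation-based Bayesian inference for the attrition dynamics of two
interacting forces. The package fits four variants of the Lanchester
combat equations to battle casualty records with rejection-based
approximate Bayesian computation (ABC), selects between the variants
with Bayes factors computed from a model-index variable, and ships a
synthetic-data generator with known ground truth so the whole pipeline
can be validated by parameter- and model-recovery experiments.

It is aimed at quantitative historians, ecologists and modellers who
want likelihood-free inference over mechanistic attrition models on
small, noisy datasets of paired casualty counts.

## The models

Two forces with strengths `B_t` (blue) and `R_t` (red) lose soldiers
each step according to one of four difference schemes:

| model        | update |
|--------------|--------|
| linear       | `B' = B − r·B·R`,&nbsp; `R' = R − b·R·B` |
| squared      | `B' = B − r·R`,&nbsp;&nbsp;&nbsp; `R' = R − b·B` |
| logarithmic  | `B' = B − r·B`,&nbsp;&nbsp;&nbsp; `R' = R − b·R` |
| fatigue      | `B' = B − r·B/ln(e+t)`,&nbsp; `R' = R − b·R/ln(e+t)` |

The linear law describes hand-to-hand combat (losses couple to both
sizes), the squared law ranged fire (losses couple to the enemy's
size), the logarithmic law own-size-dependent losses, and the fatigue
law damps the logarithmic losses by `ln(e+t)` to model declining
combat efficiency as an engagement drags on.

`b` is blue's per-soldier fighting value, scaled so that a fighting
value of 1 inflicts at most 100 casualties per step at the initial
strengths (`b = 100/(B₀·R₀)` for the linear law, `b = 100/max(B₀,R₀)`
for the others). Red's value is `r = b·P`, with the odds ratio `P`
expressing red's per-soldier lethality as a multiple of blue's.

Because a single fixed `P` across hundreds of battles would ignore
engagement-to-engagement variation, `P` is drawn per battle from a
gamma distribution parameterised by mean `μ` and standard deviation
`σ` (shape `κ = (μ/σ)²`, scale `θ = σ²/μ`), with uniform `U(0, 5)`
priors on `μ` and `σ`.

## The inference

Each ABC run samples `(μ, σ)` (and, in hierarchical mode, a model
index `m`), replays every battle from its historical initial sizes
until either side's cumulative casualties reach that side's historical
total, and scores the run by the mean over battles of the relative
casualty error `|sim − hist| / hist` (averaged over the two sides,
matching the lower-casualty-ratio side of the simulation to the
lower-casualty-ratio side of the record). The tolerance `τ` is a
quantile: the best `⌊τ·n_runs⌋` runs form the approximate posterior,
and Bayes factors are ratios of accepted-run counts of `m`.

## Worked example

Generate 100 synthetic battles from the fatigue law with ground truth
`μ* = 2.0`, `σ* = 0.5`, then run hierarchical model selection with
20,000 runs at `τ = 0.01`:

```python
from lanchester_abc import *

cfg = SynthConfig(true_model=Model.FATIGUE, true_mu=2.0, true_sigma=0.5,
                  n_battles=100, seed=7)
ds, truth = generate_dataset(cfg)

rec = run_rejection(ds, ABCConfig(n_runs=20_000, tau=0.01, seed=1,
                                  mode="hierarchical"))
post = accept_at(rec, 0.01, model_set=ALL_MODELS)
bf, props = bayes_factors(post)
print(props.round(3))
```

prints the posterior model proportions

```
linear         0.000
squared        0.000
logarithmic    0.485
fatigue        0.515
```

the two classical laws are decisively rejected (no accepted runs),
while the fatigue law and its near-twin, the logarithmic law, share
the posterior almost evenly — they trace the same casualty path and
differ only in its timing, which casualty totals barely constrain.
Summarising the fatigue runs,

```python
for p, s in summarize_posterior(post, model=Model.FATIGUE).items():
    print(p, s.to_dict())
```

```
mu    {'mean': 2.027, 'mode': 1.928, 'q2.5': 1.54,  'median': 2.023, 'q97.5': 2.485, 'n': 103}
sigma {'mean': 0.258, 'mode': 0.062, 'q2.5': 0.007, 'median': 0.216, 'q97.5': 0.66,  'n': 103}
```

the posterior mean of `μ` (2.03) recovers the generating value 2.0;
the `σ` posterior is biased low, a structural property of rejection
ABC with this distance discussed in `docs/methods.md`.

The same pipeline is available from the shell:

```
lanchester-abc synth --model fatigue --mu 2.0 --sigma 0.5 --n 100 --seed 7 --out synth.csv
lanchester-abc select --data synth.csv --runs 20000 --tau 0.01 --seed 1 --out records.csv
lanchester-abc report --records records.csv --tau 0.01 --out summary.json
```

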