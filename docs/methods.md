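# Methods

## Model

Two forces, blue and red, start an engagement with strengths `B₀` and
`R₀` and lose soldiers in discrete steps. Four update rules are
implemented (linear, squared, logarithmic, fatigue; see the README for
the equations). All are simultaneous-update difference schemes: both
sides' losses in a step are computed from the state at the start of
the step. Per-step losses are clamped at the remaining strength, so
strengths are non-increasing and never negative, and strength plus
cumulative casualties equals the initial size exactly at every step
(this conservation identity is asserted throughout the test suite).

The fatigue rule divides the logarithmic per-step loss by `ln(e+t)`,
where `t` counts completed steps from 0. It therefore coincides with
the logarithmic rule at `t = 0` and damps attrition progressively —
the same total casualties are spread over a longer engagement. The
natural logarithm and the additive constant `e` make the damping
factor start exactly at 1.

Fighting values are normalised to the initial strengths:
`b = 100/(B₀·R₀)` for the linear law and `b = 100/max(B₀, R₀)` for
the other three, so that a fighting value of 1 inflicts at most 100
casualties per step regardless of the law's dimensionality; `r = b·P`.
The odds ratio `P` is the only free parameter of a single battle.

### Stochastic odds ratio

`P` is drawn once per battle from `Gamma(κ, θ)` with
`κ = (μ/σ)²`, `θ = σ²/μ`, so the hyperparameters are directly
interpretable as the mean and standard deviation of `P` across
battles. `μ` and `σ` carry independent `U(0, 5)` priors. Two
boundary conventions: draws of `μ` below 1e-6 are resampled (the
reparameterization is undefined at 0), and `σ` below 1e-6 routes to a
deterministic `P = μ`. Both affect a measure-zero sliver of the prior
and cannot move posteriors at the tolerances used. Gamma draws at
very small shape can underflow to exactly 0.0 in floating point; they
are floored at the smallest positive normal float, since a gamma
variate is almost surely positive.

## Simulation and stopping rule

Fitting replays each battle from its recorded initial sizes under the
candidate law and the drawn `P`, stopping at the first step where
either side's cumulative casualties reach that side's historical
total. Because per-step casualty quanta are of order 100 soldiers,
integer-step stopping would overshoot the trigger side's total by up
to one step's loss and inject noise of that size into the distance;
by default the final step is linearly interpolated so the trigger side
lands exactly on its total and the other side's final-step loss is
scaled by the same fraction. The non-interpolating mode is kept as an
option.

Degenerate cases never abort a run: a side whose strength falls below
1e-9 of its initial size is treated as annihilated (proportional-loss
laws decay geometrically and only reach zero asymptotically), and a
hard `max_steps` guard (default 100,000) bounds every call. Both
terminations are flagged on the outcome and leave casualties capped at
the sizes, so a distance is always computable.

The engine exists in two forms with identical semantics: a scalar
step-by-step reference, and a vectorised batch engine that advances
all pending battles of all runs in lock-step and drops finished ones
from the working set. The test suite asserts their equivalence on
randomised battles; the ABC loop uses the batch engine.

## Distance and acceptance

The per-battle distance is the mean over the two sides of
`|simulated − historical| / historical` casualties, after identifying
the red side — in the record *and* in the simulated outcome — as the
side with the lower casualty ratio, which makes the distance invariant
to side ordering. Records with zero casualties on either side are
rejected on input (the normalisation divides by them). A run's
distance is the arithmetic mean over battles (keeping values
comparable across datasets of different size); averaging rather than
summing the two sides is a constant factor that cannot change any
rank or acceptance decision.

The tolerance `τ` is an accepted *fraction*: the `⌊τ·n⌋` runs with
the smallest distances form the posterior, ties at the boundary broken
by run index for determinism. Distances are stored for every run, so
posteriors at other tolerances are pure rank cuts on the record store.
Two model-selection modes exist: hierarchical (the model index is
sampled uniformly per run, Bayes factors are accepted-count ratios)
and pooled (per-model record stores concatenated and cut globally).

Reproducibility: every consumer of randomness draws from a substream
keyed by `(root seed, stream tag, run index)`, so the record set is
independent of execution order and chunk size (asserted in tests).

## Synthetic data

The generator emulates the structure of historical battle
compilations: a few hundred engagements, lognormal force sizes
(default median 20,000 soldiers, 0.7 sd on the log scale, larger/
smaller ratio capped at 3), and casualty ratios well below 1 —
battles end in routs, not annihilation. Per battle it draws `P` from
the generating gamma, a rout fraction `f ~ U(0.05, 0.5)`, simulates
under the generating law until the first side's casualty fraction
reaches `f`, and records the interpolated casualty pair as the
battle's "historical" outcome; years are uniform over 1620–1905.

The advantaged (red) side is the larger force. This is deliberate:
the fit estimates the odds ratio of the canonically oriented battle
(red = lower casualty ratio), and under all four laws the advantaged
side ends with the lower ratio whenever it is at least as large as
its opponent and `P ≥ 1`. Assigning the advantage to a random side
folds the true `P` to `1/P` for a substantial fraction of battles
(up to ~40% under the squared law), so recovery experiments would
score against a mislabelled truth.

What the generator does *not* emulate: draws and indecisive actions,
missing or rounded casualty counts, correlated engagements within
campaigns, and any secular trend in army size or lethality. Passing
recovery tests therefore demonstrate that the inference machinery is
self-consistent under the stated generative assumptions, not that
those assumptions describe any historical record.

## Recovery experiments and their problem sizes

The validation experiments use 100 battles, ground truth `μ* = 2.0`,
`σ* = 0.5`, 20,000 runs and `τ = 0.01` (200 accepted runs) — large
enough for stable posterior proportions, small enough that the whole
suite runs in a couple of minutes on one CPU. Production-scale
experiments (10⁶ runs, `τ` down to 5·10⁻⁴) use the same code path;
the record store is re-thresholdable without re-simulation.

Two structural limitations surface in these experiments and are left
visible rather than papered over:

* **The `σ` posterior is biased toward 0.** The expected run distance
  is monotonically increasing in the run's `σ`: a point mass at the
  central `P` minimises the mean absolute casualty error against any
  fixed set of battles, so rejection preferentially keeps low-`σ`
  runs and the posterior mean of `σ` sits well below the generating
  value. `μ` recovery is unaffected. Any user reading `σ` posteriors
  from this method (on synthetic *or* real data) should treat them as
  lower bounds on heterogeneity.
* **The logarithmic and fatigue laws are near-unidentifiable from
  casualty totals.** The fatigue law is a time-reparameterisation of
  the logarithmic law: both trace the same path in casualty space, and
  a distance built only on final casualty pairs separates them only
  through step-discretisation effects, which are orders of magnitude
  smaller than the distance's noise floor. Selection between the two
  (in either direction) rests on this thin margin, and the finer
  stepping of the fatigue law gives it a slight systematic edge
  regardless of which of the two generated the data. The linear and
  squared laws, by contrast, are sharply identified.

## Numerical and design choices

* Ambiguous source readings: the fatigue factor is implemented as
  *division* of the per-step loss by `ln(e+t)` (multiplication would
  accelerate rather than damp attrition, contradicting the intended
  dynamics), and the fighting-value scalings as `100/(B₀·R₀)` and
  `100/max(B₀, R₀)` (the readings under which a fighting value of 1
  inflicts at most 100 casualties per step).
* Canonical orientation tie-break: with exactly equal casualty
  ratios, the larger force is blue. Deterministic and documented;
  the orientation rule itself is silent on ties.
* Casualties are stored as reals: interpolated simulated casualties
  are fractional; historical inputs are integral.
* Posterior mode estimator: midpoint of the maximal bin of a
  Freedman–Diaconis histogram by default, with a Gaussian-KDE argmax
  alternative. Reported "peaks" depend on this choice; both are
  exposed and the choice is recorded in the summary.
* The CSV reader takes a configurable column map (defaults
  `id, year, size_a, size_b, casualties_a, casualties_b`) and a
  strict/lenient switch: invalid rows either abort with a row-indexed
  diagnostic or are skipped and logged, never silently dropped.

## Known limitations

* No continuous-time (ODE) integration; the difference schemes are
  the model, not an approximation of one.
* No within-step event ordering, reinforcements, retreats, or
  multi-day engagement structure.
* Rejection ABC only — no sequential, MCMC or regression-adjusted
  variants, and no summary-statistic compression (the distance
  compares casualty sets directly).
* Bayes factors inherit the tolerance dependence of the accepted set;
  proportions should always be inspected across several `τ` values
  (the record store makes this free).
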