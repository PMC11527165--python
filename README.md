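# insightnet

Simulation and analysis toolkit for studying **insight-like strategy
switches** — sudden, selective, delayed performance jumps — in minimal
neural networks trained by noisy online gradient descent.

## The scientific problem

In a two-alternative perceptual decision task, an agent judges a noisy
*motion* feature whose difficulty varies over five coherence levels, while
an easy *colour* feature is visible but uninformative.  Partway through
training, colour silently becomes fully predictive of the correct choice.
Some human learners discover this hidden regularity in a sudden,
aha-moment-like strategy switch; others never do.  The question this
package addresses: can those behavioural signatures — suddenness,
selectivity across individuals and variable delay — emerge from a plain
gradient-descent learner with no dedicated insight mechanism?

The core model is a gated linear network with four scalars.  On each trial
with inputs `x_m ~ N(y·M_m, σ_m)` and `x_c ~ N(c·M_c, σ_c)` (label
`y = ±1`; `c = y` once colour predicts, otherwise a coin flip), the
decision is

```
ŷ = sign(g_m w_m x_m + g_c w_c x_c + η),   η ~ N(0, σ_η)
```

Weights `w` and multiplicative gates `g` are trained online on the squared
error of the continuous output, with an L1 penalty `λ(|g_m| + |g_c|)` on
the **gates only** and Gaussian noise on every gradient update.  The L1
penalty keeps the gate of the (initially useless) colour channel at zero
while gradient noise lets the colour *weight* drift — accumulating "silent
knowledge" whose behavioural expression is suppressed until the
gate escapes, at which point the multiplicative coupling produces an abrupt
switch.

Behaviour is classified exactly as one would classify human learners:
accuracy on the hardest trials is binned (50-trial half blocks), a sigmoid
`y = (y_max − y_min)/(1 + e^{−m(t − t_s)}) + y_min` is fitted and compared
against linear and step models by BIC, and the slope at the inflection
point, `m(y_max − y_min)/4`, corrected by the fit's RMSE, is thresholded at
the maximum observed in a **control cohort** for which colour never becomes
predictive.

## Worked example

```python
import insightnet as inet

# one simulated subject: curriculum, matched inputs, training
profile = inet.synth_target_profiles(1, rng=0)[0]          # per-coherence targets
fit = inet.fit_motion_means(profile, seed=0)               # COBYLA matching
trials = inet.build_curriculum(rng=1)
trials = inet.sample_inputs(trials, inet.InputModel(M_m=fit.means), rng=1)
net = inet.GatedLinearNetwork().fit(trials, rng=2)

trials["correct"] = net.correct_
series = inet.bin_accuracy(trials)                         # 14 bins of 50 trials
fits = inet.fit_switch_models(series)
print({k: round(float(v.bic), 1) for k, v in fits.items()})
print("corrected steepness:", round(fits["sigmoid"].corrected_steepness, 2),
      "switch bin:", round(fits["sigmoid"].switch_point, 1))
```

Output from this exact snippet:

```
{'linear': -54.2, 'step': -75.8, 'sigmoid': -86.1}
corrected steepness: 1.92 switch bin: 4.0
```

The sigmoid wins the model comparison (lowest BIC), and this subject's
accuracy jumps at bin 4.0 — right at colour onset — with a corrected slope
of 1.92 at the inflection.  Whether that counts as
an insight-like switch is decided against a control cohort:

```python
cohort = inet.run_cohort(n=99, seed=0)      # 99 networks + 99 controls, ~3 min
print(f"{cohort.n_insight}/99 insight networks, "
      f"mean delay {cohort.delay_stats['mean_delay_bins']:.1f} half-blocks")
```

A command-line interface mirrors the library:
`insightnet simulate`, `insightnet classify` (for behavioural CSVs),
`insightnet sweep-noise`, `insightnet sweep-lambda`, `insightnet intervene`,
`insightnet dynamics`.

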