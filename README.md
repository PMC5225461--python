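# trainsig

Secondary-signal (indirect-response) models of the dose–response relationship
between physical training and performance.

## The problem

Coaches, sport scientists and rehabilitation planners want to predict how an
individual's performance will respond to a schedule of daily training doses —
and in particular how much daily training is *too much*. The classical
fitness–fatigue models describe performance as a balance of two antagonistic
first-order impulse responses, but they are ill-conditioned to fit and
conflate acute fatigue with maladaptation to intensified training.

`trainsig` implements an alternative family borrowed from pharmacodynamic
turnover (indirect-response) modelling. Each day's training dose `W_i`
(in training units, tu; one maximal 5-min cycling trial ≡ 100 tu) produces a
latent *secondary signal* that dissipates with first-order kinetics and is
transformed into production of performance, balanced by first-order removal:

```
Signal_i  = Signal_{i-1} · e^{-k_s1} + W_i
Inhib_i   = k_i · W_i                              (TI, TIF)
Prod_i    = k_off · Perf_0 + k_s2 · (1 − Inhib_i) · Signal_i
Perf_i    = Perf_{i-1} + Prod_{i-1} − k_off · Perf_{i-1}
Fatigue_i = Fatigue_{i-1} · e^{-k_f2} + k_f1 · W_i  (TF, TIF)
NetPerf_i = Perf_i − Fatigue_i                      (TF, TIF)
```

Four nested variants differ in how training acts negatively: **T** (none,
3 parameters), **TI** (same-day inhibition of the transformation of signal
into adaptation — maladaptation, 4), **TF** (subtractive fatigue, 5), **TIF**
(both, 6). Baseline production is pinned at `k_off · Perf_0` so that
performance is stationary without training. Under TI, steady-state
performance for a constant daily dose `w` is

```
Perf*(w) = Perf_0 + k_s2 · (1 − k_i·w) · w / [(1 − e^{-k_s1}) · k_off]
```

an inverted-U with an interior optimum at `w = 1/(2·k_i)`.

The package provides:

* exact daily-recursion simulation with full state decomposition
  (signal, inhibition, production, performance, fatigue);
* maximum-likelihood fitting (profiled Gaussian likelihood, log-scale
  positivity constraints, seeded Latin-hypercube multi-start);
* the model-selection battery: R², adjusted R², SE, overall ANOVA, AICc,
  Akaike weights, nested F-ratio tests;
* steady-state dose–response curves, optimal daily dose, and
  session-interaction simulations;
* a synthetic-subject generator emulating a 15-week cycle-ergometer
  protocol (8 weeks at 3 sessions/week, a rest week, 4 intensified weeks at
  5 sessions/week, 2 rest weeks; 40–46 performance trials; intensity
  prescribed at 85% of the last measured 5-min performance), for demos and
  parameter-recovery studies;
* a CLI: `trainsig fit | compare | simulate | dose-response | synth`.

## Worked example

Fit all four variants to a synthetic subject generated under Model TI with
the published median parameters and 3 W of measurement noise:

```python
import trainsig as ts
from trainsig.datasets import MEDIAN_TI_PARAMS

cfg = ts.ProtocolConfig(noise_sd=3.0, seed=42, baseline_perf=250.0)
series = ts.generate_subject("TI", MEDIAN_TI_PARAMS, cfg)

table = ts.compare_models(series, n_starts=10, seed=7)
print(table.render_text())
print(table.fits[ts.ModelKind.TI].summary())

best = table.fits[ts.ModelKind.TI].params
opt = ts.optimal_dose(best, method="numeric")
ss = ts.steady_state_performance("TI", best, opt, 250.0)
print(f"optimal daily dose {opt:.1f} tu -> steady state {ss:.1f} W")
```

prints

```
               Model T    Model TI    Model TF   Model TIF
    Adj.R2       0.915       0.991       0.939       0.991
      AICc      316.33      214.79      303.97      218.28
   w(AICc)       0.000       0.851       0.000       0.149
Secondary-signal model TI (p=4, n=45, removal=euler)
----------------------------------------------------------
  k_off  = 0.030629
  k_s1   = 0.26666
  k_s2   = 0.0067805
  k_i    = 0.0021192
  RSS    = 255.1389 W^2
  ln(L)  = -102.8930
  AICc   = 214.79
  converged = True (11 starts)
optimal daily dose 235.9 tu -> steady state 361.6 W
```

The weight of evidence lands on the true generating model (TI, w = 0.851),
the four true rates (0.0305, 0.292, 0.0074, 0.0021) are recovered within a
few percent, and the fitted inhibition constant implies an optimal daily
dose of ~236 tu — near the published ~253 tu/day average across subjects.

Equivalent CLI: `trainsig synth --model TI --params ti.json --noise-sd 3
--seed 42 --out subj.csv`, then `trainsig compare --input subj.csv`.

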