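# Methods

## Model family

The package models daily training effect as an indirect (turnover) response.
Training dose on day `i`, `W_i` (tu), is an impulse input. It produces a
latent secondary signal in equal amount; the signal dissipates with
first-order rate `k_s1` (1/day) and is transformed into production of
performance with gain `k_s2` (W·day⁻¹ per tu). Performance `Perf` (W) is
produced at rate `Prod` and removed with first-order rate `k_off` (1/day).
Baseline production is tied to the initial performance, `k0_on = q·Perf_0`
(with `q` the one-day removal fraction, below), so that performance is
exactly stationary in the absence of training — `Perf_0` is fixed at the
first measured performance and is not a fitted parameter.

Negative effects of training enter in two alternative ways:

* **Inhibition (TI, TIF)** — memoryless and dose-proportional:
  `Inhib_i = k_i·W_i`, zero on rest days, multiplying the transformation
  term as `(1 − Inhib_i)`. It is deliberately *not* clamped at 1: a daily
  dose above `1/k_i` makes the day's marginal transformation negative
  (signal wasting), which is exactly what produces the inverted-U
  steady-state dose-response.
* **Fatigue (TF, TIF)** — a parallel first-order state
  `Fatigue_i = Fatigue_{i−1}·e^{−k_f2} + k_f1·W_i` subtracted from
  performance; the observable for TF/TIF is net performance. `k_f1` is
  unconstrained in sign (fits on real data are known to go negative,
  which is itself diagnostic evidence against the fatigue mechanism).

## Discretization

The fitted object is the daily recursion, not a continuous ODE. Within-day
ordering: signal (and fatigue) first decays from the previous day's level,
then receives the whole day's dose as an impulse; this keeps the constant-
dose fixed point clean at `S* = w/(1 − e^{−k_s1})`. Production on day `i`
uses the same day's signal and inhibition, while performance on day `i` uses
production from day `i − 1`; consequently a measurement on day `i` is
unaffected by that day's own training (the trial's 100 tu influence later
days only), which resolves the ordering of trial and measurement within a
day. Multiple bouts on one day (trial + session) sum into a single daily
impulse.

Signal and fatigue decay use the exact one-day factor `e^{−k}`; performance
removal uses the Euler fraction `q = k_off` by default. Because the exact
and Euler factors differ only at O(k_off²) (~0.05%/day at the fitted rates)
and the published recursion structure is ambiguous on this point, both are
supported via `removal="euler" | "exact"`; with the exact factor the
baseline production becomes `q = 1 − e^{−k_off}` times `Perf_0`, preserving
exact stationarity under both conventions.

## Estimation

Measurement errors are modelled i.i.d. Gaussian. The error variance is
profiled out, giving `ln L = −(n/2)[ln(2π·RSS/n) + 1]`; minimizing the
negative log-likelihood is therefore equivalent to least squares, but the
likelihood scale is what AICc consumes. The profiled σ is *not* counted in
the parameter count: `p = 3/4/5/6` for T/TI/TF/TIF.

Rates constrained positive (`k_off, k_s1, k_s2, k_i, k_f2`) are optimized on
a log scale; `k_f1` on its natural scale. Default bounds —
`k_off ∈ [0.001, 0.2]`, `k_s1 ∈ [0.01, 2]`, `k_s2 ∈ [10⁻⁵, 0.1]`,
`k_i ∈ [10⁻⁵, 0.01]`, `k_f1 ∈ [−1, 1]`, `k_f2 ∈ [0.01, 2]` — bracket the
published per-subject estimates with at least a threefold margin. The
optimizer is L-BFGS-B (`ftol` 10⁻¹⁰, `gtol` 10⁻⁶ on the transformed scale)
launched from a seeded Latin-hypercube design (default 20 starts);
`fit()` accepts `extra_starts`, and `compare_models` uses them to seed each
model with the optimum of its nested reduction (T → TI/TF → TIF), which
enforces the RSS nesting inequality by construction. Given a seed the whole
multi-start procedure is bitwise reproducible. A numerically zero RSS makes
the profiled likelihood unbounded; the public likelihood raises a
degenerate-fit error, while the fitting objective floors RSS so that
perfect-fit self-consistency checks terminate cleanly.

## Model selection

`R² = 1 − RSS/TSS` (TSS about the mean of the measurements),
`Adj.R² = 1 − (1 − R²)(n − 1)/(n − p − 1)` (the standard denominator;
adopted as the design choice where the published formula is ambiguous),
`SE = RSS/(n − p)`, overall significance from
`F = [(TSS − RSS)/p]/[RSS/(n − p − 1)]` on `(p, n − p − 1)` df. Nested
improvements use `F = [(RSS_red − RSS_full)/Δp]/[RSS_full/(n − p_full)]` on
`(Δp, n − p_full)` df, with a negative numerator clamped to `F = 0, p = 1`.
`AICc = −2 ln L + 2p + 2p(p+1)/(n − p − 1)`; Akaike weights
`w_i = e^{−Δ_i/2}/Σ e^{−Δ_j/2}` with Δ relative to the minimum. p-values are
kept at machine precision; threshold formatting (0.05, 0.001) is left to
report rendering.

## Forward analyses

Steady state under a constant daily dose is evaluated in closed form,
`Perf* = baseline + k_s2(1 − k_i·w)·S*/q` (minus `k_f1·w/(1 − e^{−k_f2})`
for the fatigue models), sampled at the post-impulse daily instant — stated
explicitly because within-day phase changes the signal level by `e^{−k_s1}`.
The closed form is cross-checked against brute-force iteration of the
recursion to 10⁻⁶ W. The TI optimum is `1/(2k_i)` analytically and by
bounded golden-section search numerically; the mean optimal dose across
subjects is computed per subject, then averaged (sample SD, n − 1).
Session-interaction simulations start from rest (no prior training history)
and report the daily gain `ΔPerf(t) = observable(t) − baseline` for a single
session and for the same session repeated one or two days later.

## Synthetic protocol generator

`ProtocolConfig` defaults emulate a 15-week (plus baseline week 0) cycling
study: weeks 1–8 with three trial+session days (Mon/Wed/Fri), rest week 9,
weeks 10–13 with five consecutive training days (trials on days 1/3/5,
5-repetition sessions without trial on days 2/4), rest weeks 14–15. Trial
days in rest weeks are two evenly spaced days per week; with three trials in
week 0 this yields 45 trials, inside the studied 40–46 range. Exact weekday
conventions are a free choice since the models are day-indexed.

Dose quantification anchors one maximal 5-min trial at 100 tu and sets
`W_session = trial_load · rep · (P_mean/P_lim5′)`; with intensity prescribed
as 85% of the last measured performance this reduces algebraically to
`100 · rep · 0.85` (340 tu for 4-repetition sessions, 425 tu for
5-repetition sessions; 440 tu on trial+session days), and the generator
computes it through the closed loop so the cancellation is a tested
consequence, not an assumption. Measurement noise is additive i.i.d.
Gaussian — consistent with the fitting likelihood — with default
`noise_sd = 3 W`, chosen so that synthetic subjects fit with adjusted R² in
the ~0.9–0.99 range typical of this kind of data. What the generator does
*not* emulate: missed sessions, drift in intensity prescription,
non-Gaussian or heteroscedastic measurement error, and between-day
correlation of errors; passing recovery tests therefore demonstrate
identifiability under the design, not robustness to those real-data
features.

Parameter-recovery studies (`recovery_study`) regenerate and refit
replicates with per-replicate seeds. At the default design and 3 W noise,
the removal and inhibition rates are recovered with median absolute
relative errors of a few percent (the suite asserts ≤ 25% over 100
replicates); noise-free recovery is exact to better than 10⁻³. Problem
sizes used by the test suite (replicate counts, multi-start counts of 6–10
for batteries) are chosen to keep the full suite in the minutes range while
leaving the assertions comfortably determined.

## Known limitations

* The daily recursion assumes doses act as end-of-day impulses; sub-daily
  timing and within-day recovery are out of scope.
* `Perf_0` is pinned to the first measurement, so error in that first trial
  propagates as a small bias rather than being averaged out.
* The inhibition mechanism is memoryless by construction; multi-day
  carry-over of maladaptation is only representable through the signal
  pathway.
* The original study's per-day data are not redistributed; the fit-table
  reproduction runs only when users transcribe the published spreadsheet to
  the documented CSV layout.
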