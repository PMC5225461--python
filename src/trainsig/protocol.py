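"""Synthetic subjects following the 15-week cycle-ergometer training protocol.

The emulated study design: a baseline week of performance trials only
(week 0), eight weeks with three training days per week (weeks 1-8), a rest
week (week 9), four intensified weeks with five consecutive training days
(weeks 10-13), and two final rest weeks (weeks 14-15).  A performance trial
is a maximal 5-minute effort worth a fixed 100 tu; on training days in weeks
1-8 (and on days 1/3/5 of the intensified weeks) the trial is followed by a
session of 4 repetitions of 5 minutes at 85% of the last measured
performance; days 2/4 of the intensified weeks carry a 5-repetition session
with no trial.  Daily dose follows W = trial_load * rep * (P_mean / P_lim5'),
anchored so that one maximal 5-minute trial is exactly 100 tu; with
intensity prescribed as a fraction of the last measured performance the
per-session dose reduces to trial_load * rep * intensity_fraction.

Measurements are the model's observable performance plus i.i.d. Gaussian
noise; generation is closed-loop (session intensity tracks the current noisy
last-measured performance) and fully seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import removal_fraction
from .kinds import ModelKind
from .params import ModelParameters
from .series import TrainingTimeSeries

#: Within-week day offsets (day 0 of a week is the "weekend" anchor).
_TRIAL_OFFSETS_TRAINING = (1, 3, 5)  # Mon/Wed/Fri
_TRIAL_OFFSETS_REST = (1, 4)  # two evenly spaced trials in rest weeks
_PHASE2_SESSION_OFFSETS = (1, 2, 3, 4, 5)  # five consecutive days


@dataclass(frozen=True)
class ProtocolConfig:
    """Configuration of the synthetic 15-week training protocol.

    Defaults reproduce the emulated study: 40-46 performance trials, daily
    doses of 440 tu on trial+session days, 425 tu on the intensified weeks'
    session-only days, 100 tu on trial-only days.
    """

    weeks_phase1: int = 8
    sessions_per_week_phase1: int = 3
    rest_week: int = 9
    weeks_phase2: int = 4
    sessions_per_week_phase2: int = 5
    taper_weeks: int = 2
    reps_phase1: int = 4
    reps_phase2_extra_days: int = 5
    intensity_fraction: float = 0.85
    trial_load: float = 100.0
    noise_sd: float = 3.0
    seed: int = 0
    baseline_perf: float = 250.0

    def __post_init__(self) -> None:
        counts = (
            self.weeks_phase1,
            self.sessions_per_week_phase1,
            self.weeks_phase2,
            self.sessions_per_week_phase2,
            self.taper_weeks,
            self.reps_phase1,
            self.reps_phase2_extra_days,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all protocol counts must be positive")
        if not (0.0 < self.intensity_fraction <= 1.0):
            raise ValueError("intensity_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.trial_load <= 0:
            raise ValueError("trial_load must be > 0")
        if self.rest_week != self.weeks_phase1 + 1:
            raise ValueError(
                "rest week must immediately follow phase 1 (overlapping phases)"
            )

    @property
    def n_weeks(self) -> int:
        # week 0 + phase 1 + rest week + phase 2 + taper
        return 1 + self.weeks_phase1 + 1 + self.weeks_phase2 + self.taper_weeks

    @property
    def n_days(self) -> int:
        return 7 * self.n_weeks


def build_protocol(config: ProtocolConfig | None = None) -> pd.DataFrame:
    """Lay out the day-by-day schedule of trials and training sessions.

    Returns a frame with one row per day: ``day``, ``week``, ``session_reps``
    (0 on non-session days) and ``trial`` (bool).
    """
    cfg = config or ProtocolConfig()
    n_days = cfg.n_days
    reps = np.zeros(n_days, dtype=int)
    trial = np.zeros(n_days, dtype=bool)

    phase1_weeks = range(1, 1 + cfg.weeks_phase1)
    phase2_start = cfg.rest_week + 1
    phase2_weeks = range(phase2_start, phase2_start + cfg.weeks_phase2)
    rest_weeks = {0, cfg.rest_week} | set(
        range(phase2_start + cfg.weeks_phase2, cfg.n_weeks)
    )

    for week in range(cfg.n_weeks):
        base = 7 * week
        if week in rest_weeks:
            offsets = _TRIAL_OFFSETS_TRAINING if week == 0 else _TRIAL_OFFSETS_REST
            for off in offsets:
                trial[base + off] = True
        elif week in phase1_weeks:
            for off in _TRIAL_OFFSETS_TRAINING[: cfg.sessions_per_week_phase1]:
                trial[base + off] = True
                reps[base + off] = cfg.reps_phase1
        elif week in phase2_weeks:
            for j, off in enumerate(
                _PHASE2_SESSION_OFFSETS[: cfg.sessions_per_week_phase2]
            ):
                if j % 2 == 0:  # days 1/3/5: trial + standard session
                    trial[base + off] = True
                    reps[base + off] = cfg.reps_phase1
                else:  # days 2/4: extra repetitions, no trial
                    reps[base + off] = cfg.reps_phase2_extra_days
    return pd.DataFrame(
        {
            "day": np.arange(n_days),
            "week": np.arange(n_days) // 7,
            "session_reps": reps,
            "trial": trial,
        }
    )


def generate_subject(
    kind: ModelKind | str,
    params: ModelParameters,
    config: ProtocolConfig | None = None,
    removal: str = "euler",
) -> TrainingTimeSeries:
    """Simulate one synthetic subject through the protocol (closed loop).

    Daily state is advanced with the model recursion; on trial days the
    measurement is the observable performance plus Gaussian noise, and the
    day's session dose is computed from the prescribed intensity relative to
    the last measured performance, W = trial_load * rep * (P_mean/P_lim5'),
    which reduces to trial_load * rep * intensity_fraction when intensity is
    prescribed as that fraction of the last measurement.
    """
    kind = ModelKind.coerce(kind)
    params.validate_for(kind)
    cfg = config or ProtocolConfig()
    schedule = build_protocol(cfg)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_days

    q = removal_fraction(params.k_off, removal)
    decay_s = math.exp(-params.k_s1)
    k_i = params.k_i if kind.has_inhibition else 0.0
    if kind.has_fatigue:
        k_f1, decay_f = params.k_f1, math.exp(-params.k_f2)
    else:
        k_f1, decay_f = 0.0, 0.0
    perf0 = cfg.baseline_perf
    k0_on = q * perf0

    loads = np.zeros(n)
    mdays: list[int] = []
    meas: list[float] = []
    signal = 0.0
    perf = perf0
    fatigue = 0.0
    prod_prev = k0_on
    last_measured = perf0  # P_lim5' governing prescribed intensity

    reps = schedule["session_reps"].to_numpy()
    trials = schedule["trial"].to_numpy()
    for day in range(1, n):
        w = 0.0
        if trials[day]:
            w += cfg.trial_load
        if reps[day] > 0:
            # prescribed mean power is intensity_fraction of the last
            # measured 5-min performance; dose scales with P_mean/P_lim5'
            p_mean = cfg.intensity_fraction * last_measured
            w += cfg.trial_load * reps[day] * (p_mean / last_measured)
        loads[day] = w

        new_signal = signal * decay_s + w
        new_perf = perf + prod_prev - q * perf
        prod_prev = k0_on + params.k_s2 * (1.0 - k_i * w) * new_signal
        fatigue = fatigue * decay_f + k_f1 * w
        signal, perf = new_signal, new_perf

        if not (math.isfinite(perf) and math.isfinite(signal)):
            raise RuntimeError(
                f"model diverged on day {day} (perf={perf!r}, signal={signal!r}); "
                f"check parameters {params.to_dict(kind)}"
            )
        if trials[day]:
            observable = perf - fatigue if kind.has_fatigue else perf
            value = observable + rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd else observable
            mdays.append(day)
            meas.append(value)
            last_measured = value

    return TrainingTimeSeries(
        loads=loads,
        measurement_days=np.array(mdays),
        measurements=np.array(meas),
        subject=f"synthetic-{kind.name}-seed{cfg.seed}",
    )


def recovery_study(
    kind: ModelKind | str,
    true_params: ModelParameters,
    config: ProtocolConfig | None = None,
    n_replicates: int = 10,
    n_starts: int = 8,
    seed: int = 0,
    include_truth_start: bool = False,
) -> dict:
    """Parameter-recovery simulation: generate, refit, summarize errors.

    Generates ``n_replicates`` subjects from ``true_params`` (replicate r uses
    generator seed ``seed + r``), fits the same model kind to each, and
    summarizes per-parameter bias and median absolute relative error.  Fit
    failures are recorded, not fatal.
    """
    from .estimation import SecondarySignalModel

    kind = ModelKind.coerce(kind)
    if n_replicates < 10:
        raise ValueError("need at least 10 replicates")
    cfg = config or ProtocolConfig()
    names = kind.param_names
    truth = np.array(true_params.to_array(kind))
    estimates = []
    failures = []
    extra = [true_params.for_kind(kind)] if include_truth_start else []
    for r in range(n_replicates):
        sub_cfg = replace(cfg, seed=int(seed) + r)
        series = generate_subject(kind, true_params, sub_cfg)
        try:
            fit = SecondarySignalModel(series, kind).fit(
                n_starts=n_starts, seed=int(seed) + r, extra_starts=extra
            )
            estimates.append(fit.params.to_array(kind))
        except Exception as err:
            failures.append({"replicate": r, "error": str(err)})
    est = np.array(estimates)
    rel_err = (est - truth) / truth
    return {
        "kind": kind.name,
        "n_replicates": n_replicates,
        "n_failed": len(failures),
        "failures": failures,
        "param_names": names,
        "estimates": est,
        "bias": dict(zip(names, np.mean(est - truth, axis=0))),
        "median_abs_rel_error": dict(
            zip(names, np.median(np.abs(rel_err), axis=0))
        ),
    }
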