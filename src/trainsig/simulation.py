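"""Forward analyses: session interactions, steady-state dose-response, optima.

Under a constant daily dose w the signal recursion converges to
S* = w / (1 - exp(-k_s1)), so steady-state performance has the closed form

    Perf* = baseline + k_s2 * (1 - k_i * w) * S* / q

with q the one-day removal fraction of performance (k_off under the Euler
discretization).  For the inhibition models the gain is proportional to
w * (1 - k_i * w): an inverted-U in dose, maximal at w = 1/(2 k_i) and back
at baseline when w = 1/k_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .core import removal_fraction, simulate_trajectory
from .kinds import ModelKind
from .params import ModelParameters

#: Scenario labels for session-interaction simulations: a single session, the
#: same session repeated the next day, and repeated after a two-day gap.
SCHEDULES: dict[str, tuple[int, ...]] = {
    "single": (1,),
    "+1 day": (1, 2),
    "+2 days": (1, 3),
}


def steady_state_performance(
    kind: ModelKind | str,
    params: ModelParameters,
    dose: float,
    baseline: float,
    removal: str = "euler",
) -> float:
    """Closed-form steady-state performance under a constant daily dose (W).

    Sampled at the daily instant after the day's update (post-impulse), the
    convention under which S* = dose / (1 - exp(-k_s1)).
    """
    kind = ModelKind.coerce(kind)
    params.validate_for(kind)
    if dose < 0:
        raise ValueError("dose must be >= 0")
    q = removal_fraction(params.k_off, removal)
    if q == 0:
        raise ValueError("k_off = 0 admits no steady state")
    k_i = params.k_i if kind.has_inhibition else 0.0
    s_star = dose / (1.0 - math.exp(-params.k_s1))
    perf = baseline + params.k_s2 * (1.0 - k_i * dose) * s_star / q
    if kind.has_fatigue:
        # fatigue steady state F* = k_f1 * dose / (1 - exp(-k_f2))
        perf -= params.k_f1 * dose / (1.0 - math.exp(-params.k_f2))
    return perf


def iterated_steady_state(
    kind: ModelKind | str,
    params: ModelParameters,
    dose: float,
    baseline: float,
    n_days: int = 4000,
    removal: str = "euler",
) -> float:
    """Steady state by brute-force iteration of the daily recursion (W)."""
    loads = np.full(n_days, float(dose))
    loads[0] = 0.0
    traj = simulate_trajectory(kind, params, loads, baseline, removal)
    return float(traj.observable[-1])


def optimal_dose(
    params: ModelParameters,
    method: str = "analytic",
    baseline: float = 250.0,
    removal: str = "euler",
) -> float:
    """Daily dose (tu/day) maximizing steady-state performance under TI.

    Analytic value 1/(2 k_i); ``method="numeric"`` instead maximizes the
    closed-form curve by bounded golden-section search (resolution << 0.5 tu).
    """
    if params.k_i is None or params.k_i <= 0:
        raise ValueError("optimal dose requires k_i > 0 (no interior optimum)")
    analytic = 1.0 / (2.0 * params.k_i)
    if method == "analytic":
        return analytic
    if method == "numeric":
        res = optimize.minimize_scalar(
            lambda w: -steady_state_performance(
                ModelKind.TI, params, w, baseline, removal
            ),
            bounds=(0.0, 2.0 * analytic),
            method="bounded",
            options={"xatol": 1e-6},
        )
        return float(res.x)
    raise ValueError(f"method must be 'analytic' or 'numeric', got {method!r}")


@dataclass(frozen=True)
class DoseResponseCurve:
    """Steady-state performance over a grid of constant daily doses."""

    kind: ModelKind
    doses: np.ndarray
    performance: np.ndarray
    baseline: float
    optimum_dose: float
    optimum_performance: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"dose_tu_per_day": self.doses, "steady_state_perf_w": self.performance}
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.doses, self.performance)
        ax.axvline(self.optimum_dose, ls="--", alpha=0.5)
        ax.set_xlabel("daily training dose (tu)")
        ax.set_ylabel("steady-state performance (W)")
        return ax


def dose_response_curve(
    kind: ModelKind | str,
    params: ModelParameters,
    dose_grid: Sequence[float] | np.ndarray,
    baseline: float,
    removal: str = "euler",
) -> DoseResponseCurve:
    """Evaluate the steady-state dose-response on a grid and record the optimum."""
    kind = ModelKind.coerce(kind)
    grid = np.asarray(dose_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("dose grid is empty")
    if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("dose grid must be nonnegative and strictly increasing")
    perf = np.array(
        [steady_state_performance(kind, params, w, baseline, removal) for w in grid]
    )
    j = int(np.argmax(perf))
    return DoseResponseCurve(
        kind=kind,
        doses=grid,
        performance=perf,
        baseline=baseline,
        optimum_dose=float(grid[j]),
        optimum_performance=float(perf[j]),
    )


def session_interaction(
    kind: ModelKind | str,
    params: ModelParameters,
    dose: float,
    schedules: Sequence[str] = ("single", "+1 day", "+2 days"),
    horizon: int = 300,
    baseline: float = 250.0,
    removal: str = "euler",
) -> dict[str, dict]:
    """Performance gain over baseline after one or two identical sessions.

    Each scenario starts from rest (no prior training history) with sessions
    of ``dose`` tu on the scheduled days.  Returns, per scenario, the daily
    gain series delta(t) = observable(t) - baseline, its peak, and the peak
    gain per session.
    """
    kind = ModelKind.coerce(kind)
    if dose <= 0:
        raise ValueError("dose must be > 0")
    if horizon < 30:
        raise ValueError("horizon must be >= 30 days")
    out: dict[str, dict] = {}
    for label in schedules:
        if label not in SCHEDULES:
            raise ValueError(
                f"unknown scenario label {label!r}; expected one of {sorted(SCHEDULES)}"
            )
        days = SCHEDULES[label]
        loads = np.zeros(horizon + 1)
        for d in days:
            loads[d] += dose
        traj = simulate_trajectory(kind, params, loads, baseline, removal)
        delta = traj.observable - baseline
        out[label] = {
            "delta_perf": delta,
            "peak_gain": float(delta.max()),
            "peak_day": int(delta.argmax()),
            "n_sessions": len(days),
            "gain_per_session": float(delta.max()) / len(days),
        }
    return out


def mean_optimal_dose(
    parameter_sets: Sequence[ModelParameters] | Mapping[str, ModelParameters],
    method: str = "numeric",
    baseline: float = 250.0,
) -> dict:
    """Per-subject optimal daily doses and their mean +/- sample SD (tu/day)."""
    if isinstance(parameter_sets, Mapping):
        parameter_sets = list(parameter_sets.values())
    optima = np.array([optimal_dose(p, method=method, baseline=baseline) for p in parameter_sets])
    return {
        "per_subject": optima,
        "mean": float(optima.mean()),
        "sd": float(optima.std(ddof=1)) if optima.size > 1 else float("nan"),
    }
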