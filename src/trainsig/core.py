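"""Daily state recursion of the secondary-signal models.

The models are first-order turnover (indirect-response) systems driven by a
daily impulse train of training doses W_i (tu).  Each day's dose produces a
secondary signal that dissipates with first-order kinetics; the accumulated
signal is transformed into production of performance, which is balanced by
first-order removal of performance.  The daily recursion, with day 0 at rest
(Signal_0 = Inhib_0 = Fatigue_0 = 0, Perf_0 = perf0, W_0 = 0), is

    Signal_i  = Signal_{i-1} * exp(-k_s1) + W_i
    Inhib_i   = k_i * W_i                          (0 for T/TF)
    Prod_i    = k0_on + k_s2 * (1 - Inhib_i) * Signal_i
    Perf_i    = Perf_{i-1} + Prod_{i-1} - q * Perf_{i-1}
    Fatigue_i = Fatigue_{i-1} * exp(-k_f2) + k_f1 * W_i   (TF/TIF)
    NetPerf_i = Perf_i - Fatigue_i                 (TF/TIF; else Perf_i)

where q is the one-day removal fraction of performance and k0_on = q * perf0
is the baseline zero-order production pinned by the stationarity constraint
(performance constant in the absence of training).  Two discretizations of
the removal factor are supported: the Euler fraction q = k_off (default) and
the exact one-day factor q = 1 - exp(-k_off); they differ at O(k_off^2).

Inhibition is deliberately not clamped at 1: daily doses above 1/k_i drive
(1 - Inhib_i) negative, i.e. net signal wasting, which is what produces the
inverted-U steady-state dose-response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kinds import ModelKind
from .params import ModelParameters
from .series import TrainingTimeSeries

REMOVAL_MODES = ("euler", "exact")


def removal_fraction(k_off: float, removal: str = "euler") -> float:
    """One-day removal fraction q of performance for a discretization mode."""
    if removal == "euler":
        return k_off
    if removal == "exact":
        return 1.0 - math.exp(-k_off)
    raise ValueError(f"removal must be one of {REMOVAL_MODES}, got {removal!r}")


@dataclass(frozen=True)
class Trajectory:
    """Per-day state decomposition of a simulated response to training.

    Attributes
    ----------
    signal : tu; inhib : dimensionless; prod : W/day; perf : W;
    fatigue : W (zeros for T/TI); net_perf : W (== perf for T/TI).
    """

    kind: ModelKind
    days: np.ndarray
    loads: np.ndarray
    signal: np.ndarray
    inhib: np.ndarray
    prod: np.ndarray
    perf: np.ndarray
    fatigue: np.ndarray
    net_perf: np.ndarray

    @property
    def observable(self) -> np.ndarray:
        """The model output fitted to data: net_perf (TF/TIF) or perf (T/TI)."""
        return self.net_perf if self.kind.has_fatigue else self.perf

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "day": self.days,
                "load_tu": self.loads,
                "signal_tu": self.signal,
                "inhib": self.inhib,
                "prod_w_per_day": self.prod,
                "perf_w": self.perf,
                "fatigue_w": self.fatigue,
                "netperf_w": self.net_perf,
            }
        )

    def plot(self, ax=None):
        """Line chart of the state decomposition (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.days, self.perf, label="performance (W)")
        if self.kind.has_fatigue:
            ax.plot(self.days, self.net_perf, label="net performance (W)")
        ax.plot(self.days, self.signal, label="signal (tu)", alpha=0.6)
        ax.set_xlabel("day")
        ax.legend()
        return ax


def simulate_trajectory(
    kind: ModelKind | str,
    params: ModelParameters,
    loads: Sequence[float] | np.ndarray,
    perf0: float,
    removal: str = "euler",
) -> Trajectory:
    """Run the daily recursion and return the full per-day decomposition.

    Parameters
    ----------
    kind : ModelKind
        Model variant; parameters outside the kind are ignored.
    params : ModelParameters
        Valid rate constants for ``kind``.
    loads : sequence of float
        Daily training doses W_i (tu), day 0 first; W_0 must be 0.
    perf0 : float
        Initial (baseline) performance in watts, > 0.
    removal : {"euler", "exact"}
        One-day removal discretization for performance (see module docstring).
    """
    kind = ModelKind.coerce(kind)
    params.validate_for(kind)
    w = np.asarray(loads, dtype=float)
    if w.ndim != 1 or w.size < 1:
        raise ValueError("loads must be a 1-d sequence of daily doses")
    if not np.all(np.isfinite(w)):
        raise ValueError("all loads must be finite")
    if np.any(w < 0):
        raise ValueError("loads must be >= 0")
    if w[0] != 0:
        raise ValueError("load on day 0 must be 0")
    if not (math.isfinite(perf0) and perf0 > 0):
        raise ValueError(f"perf0 must be finite and > 0, got {perf0!r}")

    n = w.size
    q = removal_fraction(params.k_off, removal)
    decay_s = math.exp(-params.k_s1)
    k_s2 = params.k_s2
    k_i = params.k_i if kind.has_inhibition else 0.0
    if kind.has_fatigue:
        k_f1 = params.k_f1
        decay_f = math.exp(-params.k_f2)
    else:
        k_f1, decay_f = 0.0, 0.0
    k0_on = q * perf0

    signal = np.zeros(n)
    inhib = np.zeros(n)
    prod = np.zeros(n)
    perf = np.zeros(n)
    fatigue = np.zeros(n)

    perf[0] = perf0
    prod[0] = k0_on  # signal is 0 on day 0
    for i in range(1, n):
        signal[i] = signal[i - 1] * decay_s + w[i]
        inhib[i] = k_i * w[i]
        perf[i] = perf[i - 1] + prod[i - 1] - q * perf[i - 1]
        prod[i] = k0_on + k_s2 * (1.0 - inhib[i]) * signal[i]
        fatigue[i] = fatigue[i - 1] * decay_f + k_f1 * w[i]

    net = perf - fatigue if kind.has_fatigue else perf
    return Trajectory(
        kind=kind,
        days=np.arange(n),
        loads=w,
        signal=signal,
        inhib=inhib,
        prod=prod,
        perf=perf,
        fatigue=fatigue if kind.has_fatigue else np.zeros(n),
        net_perf=net,
    )


def predict_at_measurements(
    kind: ModelKind | str,
    params: ModelParameters,
    series: TrainingTimeSeries,
    removal: str = "euler",
) -> np.ndarray:
    """Model-predicted performance on the measurement days of ``series``.

    The initial performance is pinned to the first measured value; the
    prediction is net performance for TF/TIF and performance for T/TI.
    Returns an array aligned with ``series.measurement_days``.
    """
    kind = ModelKind.coerce(kind)
    if series.n_measurements == 0:
        raise ValueError("series has no measurements")
    traj = simulate_trajectory(kind, params, series.loads, series.perf0, removal)
    return traj.observable[series.measurement_days]
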