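"""Maximum-likelihood fitting of secondary-signal models.

The error model is i.i.d. Gaussian on measured performance.  The error
variance is profiled out, giving the concentrated log-likelihood

    ln(L) = -(n/2) * [ln(2*pi*RSS/n) + 1]

with RSS the residual sum of squares over the n measurement days.  Rates
constrained positive are optimized on a log scale; the fatigue gain k_f1 is
unconstrained in sign.  Local minima are guarded against with multi-start
optimization from a seeded Latin-hypercube design over bounds bracketing the
physiologically plausible range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .core import predict_at_measurements
from .kinds import ModelKind
from .params import ModelParameters
from .series import TrainingTimeSeries

#: Default optimization bounds (natural scale), bracketing the published
#: per-subject estimates with at least a threefold margin on each side.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k_off": (1e-3, 0.2),
    "k_s1": (0.01, 2.0),
    "k_s2": (1e-5, 0.1),
    "k_i": (1e-5, 0.01),
    "k_f1": (-1.0, 1.0),
    "k_f2": (0.01, 2.0),
}

#: Parameters optimized on a log scale (positive by construction).
_LOG_SCALE = {"k_off", "k_s1", "k_s2", "k_i", "k_f2"}

_RSS_FLOOR = 1e-300  # guards the log in the objective for perfect fits


class DegenerateFitError(ValueError):
    """Raised when RSS is numerically zero and the likelihood is unbounded."""


def gaussian_loglik(rss: float, n: int) -> float:
    """Profiled-variance Gaussian log-likelihood ln(L) from RSS and n."""
    if rss <= 0:
        raise DegenerateFitError(
            "residual sum of squares is numerically zero; the profiled "
            "Gaussian likelihood is unbounded"
        )
    return -(n / 2.0) * (math.log(2.0 * math.pi * rss / n) + 1.0)


def negative_log_likelihood(
    kind: ModelKind | str,
    params: ModelParameters,
    series: TrainingTimeSeries,
    removal: str = "euler",
) -> float:
    """Gaussian negative log-likelihood of ``params`` for ``series``.

    Equals (n/2) * [ln(2*pi*RSS/n) + 1] with the error variance profiled
    out as RSS/n.
    """
    pred = predict_at_measurements(kind, params, series, removal)
    if not np.all(np.isfinite(pred)):
        raise ValueError("model prediction is non-finite for these parameters")
    rss = float(np.sum((series.measurements - pred) ** 2))
    return -gaussian_loglik(rss, series.n_measurements)


@dataclass(frozen=True)
class SecondarySignalResults:
    """Fit results for one model variant on one subject's series.

    Carries the ML parameter estimates and the quantities the model-selection
    battery consumes (RSS, ln L, n, p).  ``summary()`` renders a short
    human-readable report.
    """

    kind: ModelKind
    params: ModelParameters
    perf0: float
    residuals: np.ndarray
    rss: float
    n: int
    p: int
    loglik: float
    converged: bool
    n_starts: int
    seed: int | None
    removal: str = "euler"
    start_diagnostics: tuple = field(default=(), repr=False, compare=False)

    @property
    def nobs(self) -> int:
        return self.n

    @property
    def sigma2(self) -> float:
        """Profiled error variance RSS/n (W^2)."""
        return self.rss / self.n

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.p

    @property
    def aicc(self) -> float:
        """Bias-corrected Akaike information criterion."""
        from .selection import aicc

        return aicc(self)

    def predict(self, series: TrainingTimeSeries) -> np.ndarray:
        return predict_at_measurements(self.kind, self.params, series, self.removal)

    def summary(self) -> str:
        lines = [
            f"Secondary-signal model {self.kind.name} "
            f"(p={self.p}, n={self.n}, removal={self.removal})",
            "-" * 58,
        ]
        for name in self.kind.param_names:
            lines.append(f"  {name:6s} = {getattr(self.params, name):.5g}")
        lines += [
            f"  RSS    = {self.rss:.4f} W^2",
            f"  ln(L)  = {self.loglik:.4f}",
            f"  AICc   = {self.aicc:.2f}",
            f"  converged = {self.converged} ({self.n_starts} starts)",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.name,
            "params": self.params.to_dict(self.kind),
            "perf0": self.perf0,
            "rss": self.rss,
            "n": self.n,
            "p": self.p,
            "loglik": self.loglik,
            "aicc": self.aicc,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "removal": self.removal,
        }


def _transform(values: np.ndarray, names: Sequence[str]) -> np.ndarray:
    out = np.array(values, dtype=float)
    for j, name in enumerate(names):
        if name in _LOG_SCALE:
            out[j] = math.log(out[j])
    return out


def _back_transform(theta: np.ndarray, names: Sequence[str]) -> np.ndarray:
    out = np.array(theta, dtype=float)
    for j, name in enumerate(names):
        if name in _LOG_SCALE:
            out[j] = math.exp(out[j])
    return out


class SecondarySignalModel:
    """A secondary-signal model variant bound to one subject's data.

    Statsmodels-style: construct from data, call :meth:`fit` to obtain a
    :class:`SecondarySignalResults`.

    Parameters
    ----------
    series : TrainingTimeSeries
        Daily loads and sparse performance measurements.
    kind : ModelKind or str
        Which variant (T, TI, TF, TIF).
    removal : {"euler", "exact"}
        Discretization of the one-day performance-removal factor.
    """

    def __init__(
        self,
        series: TrainingTimeSeries,
        kind: ModelKind | str = ModelKind.TI,
        removal: str = "euler",
    ):
        self.series = series
        self.kind = ModelKind.coerce(kind)
        self.removal = removal
        if series.n_measurements <= self.kind.n_params + 1:
            raise ValueError(
                f"need n > p + 1 measurements to fit {self.kind.name} "
                f"(n={series.n_measurements}, p={self.kind.n_params})"
            )

    @classmethod
    def from_dataframe(cls, frame, kind: ModelKind | str = ModelKind.TI, **kw):
        """Construct from a ``day,load_tu,performance_w`` DataFrame."""
        return cls(TrainingTimeSeries.from_frame(frame), kind, **kw)

    # -- likelihood ---------------------------------------------------------
    def loglike(self, params: ModelParameters) -> float:
        return -negative_log_likelihood(self.kind, params, self.series, self.removal)

    def nloglike(self, params: ModelParameters) -> float:
        return negative_log_likelihood(self.kind, params, self.series, self.removal)

    def _objective(self, theta: np.ndarray, names: Sequence[str]) -> float:
        values = _back_transform(theta, names)
        try:
            params = ModelParameters.from_array(self.kind, values)
            pred = predict_at_measurements(self.kind, params, self.series, self.removal)
        except (ValueError, OverflowError):
            return 1e12
        if not np.all(np.isfinite(pred)):
            return 1e12
        rss = float(np.sum((self.series.measurements - pred) ** 2))
        n = self.series.n_measurements
        return (n / 2.0) * (math.log(2.0 * math.pi * max(rss, _RSS_FLOOR) / n) + 1.0)

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        n_starts: int = 20,
        seed: int = 0,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        tol: float = 1e-10,
        extra_starts: Sequence[ModelParameters] = (),
        maxiter: int = 1000,
    ) -> SecondarySignalResults:
        """Multi-start bounded ML fit; returns the best local optimum.

        ``n_starts`` Latin-hypercube launches (seeded, reproducible) plus any
        ``extra_starts`` (e.g. the optimum of a nested reduced model, which
        guarantees RSS(full) <= RSS(reduced)).
        """
        names = self.kind.param_names
        bnds = dict(DEFAULT_BOUNDS)
        if bounds:
            bnds.update(bounds)
        lo = _transform(np.array([bnds[n][0] for n in names]), names)
        hi = _transform(np.array([bnds[n][1] for n in names]), names)

        starts = []
        if n_starts > 0:
            sampler = qmc.LatinHypercube(d=len(names), seed=int(seed))
            unit = sampler.random(n_starts)
            starts.extend(lo + unit * (hi - lo))
        for extra in extra_starts:
            theta = _transform(np.array(extra.to_array(self.kind)), names)
            starts.append(np.clip(theta, lo, hi))
        if not starts:
            raise ValueError("fit requires at least one start")

        best = None
        diagnostics = []
        for theta0 in starts:
            res = optimize.minimize(
                self._objective,
                theta0,
                args=(names,),
                method="L-BFGS-B",
                bounds=list(zip(lo, hi)),
                options={"ftol": tol, "gtol": 1e-6, "maxiter": maxiter},
            )
            diagnostics.append((float(res.fun), bool(res.success), res.message))
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None or best.fun >= 1e12:
            raise RuntimeError(
                "all optimizer starts diverged; per-start diagnostics: "
                f"{diagnostics}"
            )

        values = _back_transform(best.x, names)
        params = ModelParameters.from_array(self.kind, values)
        pred = predict_at_measurements(self.kind, params, self.series, self.removal)
        resid = self.series.measurements - pred
        rss = float(np.sum(resid**2))
        n = self.series.n_measurements
        loglik = gaussian_loglik(max(rss, _RSS_FLOOR), n)
        # an essentially perfect fit can abort the line search without the
        # success flag; it is converged for every practical purpose
        converged = bool(best.success) or rss <= 1e-10 * n
        return SecondarySignalResults(
            kind=self.kind,
            params=params,
            perf0=self.series.perf0,
            residuals=resid,
            rss=rss,
            n=n,
            p=self.kind.n_params,
            loglik=loglik,
            converged=converged,
            n_starts=len(starts),
            seed=seed,
            removal=self.removal,
            start_diagnostics=tuple(diagnostics),
        )


def fit_model(
    kind: ModelKind | str,
    series: TrainingTimeSeries,
    n_starts: int = 20,
    seed: int = 0,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    tol: float = 1e-10,
    extra_starts: Sequence[ModelParameters] = (),
    removal: str = "euler",
) -> SecondarySignalResults:
    """Fit one model variant to a series (functional wrapper over the class)."""
    model = SecondarySignalModel(series, kind, removal)
    return model.fit(
        n_starts=n_starts, seed=seed, bounds=bounds, tol=tol, extra_starts=extra_starts
    )
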