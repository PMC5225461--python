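"""Goodness-of-fit and model-comparison battery.

For each fitted variant: R^2, adjusted R^2, residual mean square
SE = RSS/(n-p), the overall-significance ANOVA, AICc and Akaike weights;
between nested variants, the F-ratio test on the drop in RSS.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .estimation import SecondarySignalModel, SecondarySignalResults
from .kinds import ModelKind
from .series import TrainingTimeSeries

KIND_ORDER = (ModelKind.T, ModelKind.TI, ModelKind.TF, ModelKind.TIF)


def goodness_of_fit(fit: SecondarySignalResults, series: TrainingTimeSeries) -> dict:
    """R^2, adjusted R^2, SE = RSS/(n-p) and the overall ANOVA p-value.

    r2 = 1 - RSS/TSS about the mean of the measurements;
    adj_r2 = 1 - (1 - r2) (n - 1)/(n - p - 1);
    overall F = [(TSS - RSS)/p] / [RSS/(n - p - 1)] on (p, n - p - 1) df.
    """
    n, p = fit.n, fit.p
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    y = series.measurements
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = fit.rss
    r2 = 1.0 - rss / tss
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    se = rss / (n - p)
    f_stat = ((tss - rss) / p) / (rss / (n - p - 1))
    overall_p = float(stats.f.sf(f_stat, p, n - p - 1))
    return {
        "r2": r2,
        "adj_r2": adj_r2,
        "se": se,
        "overall_f": f_stat,
        "overall_p": overall_p,
    }


def aicc(fit: SecondarySignalResults) -> float:
    """Bias-corrected Akaike information criterion.

    AICc = -2 ln(L) + 2p + 2p(p+1)/(n-p-1); the profiled error variance is
    not counted in p (p = 3/4/5/6 for T/TI/TF/TIF).
    """
    n, p = fit.n, fit.p
    if n <= p + 1:
        raise ValueError(f"AICc undefined for n <= p + 1 (n={n}, p={p})")
    return -2.0 * fit.loglik + 2.0 * p + 2.0 * p * (p + 1) / (n - p - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Akaike weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2).

    Delta_i is each AICc minus the smallest; the weights sum to 1 and are
    invariant to adding a constant to every AICc.
    """
    a = np.asarray(aicc_values, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 AICc values")
    if not np.all(np.isfinite(a)):
        raise ValueError("all AICc values must be finite")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def nested_f_test(
    reduced: SecondarySignalResults, full: SecondarySignalResults
) -> dict:
    """F-ratio test for the drop in RSS from a nested reduced model.

    F = [(RSS_red - RSS_full)/(p_full - p_red)] / [RSS_full/(n - p_full)]
    on (p_full - p_red, n - p_full) degrees of freedom.  A negative numerator
    (possible only with imperfect optimization) clamps F to 0, p to 1.
    """
    if not reduced.kind.is_nested_in(full.kind):
        raise ValueError(
            f"model {reduced.kind.name} is not nested in {full.kind.name}"
        )
    if reduced.n != full.n:
        raise ValueError("fits compare different numbers of measurements")
    df1 = full.p - reduced.p
    df2 = full.n - full.p
    num = (reduced.rss - full.rss) / df1
    den = full.rss / df2
    if num <= 0:
        return {"f_stat": 0.0, "df1": df1, "df2": df2, "p_value": 1.0}
    f_stat = num / den
    return {
        "f_stat": float(f_stat),
        "df1": df1,
        "df2": df2,
        "p_value": float(stats.f.sf(f_stat, df1, df2)),
    }


@dataclass(frozen=True)
class SelectionTable:
    """The per-subject model-comparison battery over the four variants."""

    fits: Mapping[ModelKind, SecondarySignalResults]
    gof: Mapping[ModelKind, dict]
    aicc: Mapping[ModelKind, float]
    delta_aicc: Mapping[ModelKind, float]
    akaike_weight: Mapping[ModelKind, float]
    nested_tests: Mapping[tuple[ModelKind, ModelKind], dict]
    failures: Mapping[ModelKind, str] = field(default_factory=dict)

    @property
    def kinds(self) -> tuple[ModelKind, ...]:
        return tuple(k for k in KIND_ORDER if k in self.fits)

    def best_kind(self) -> ModelKind:
        return max(self.kinds, key=lambda k: self.akaike_weight[k])

    def to_dict(self) -> dict:
        out: dict = {"models": {}, "nested_f_tests": [], "failures": dict(
            (k.name, v) for k, v in self.failures.items()
        )}
        for k in self.kinds:
            out["models"][k.name] = {
                **{m: self.gof[k][m] for m in ("r2", "adj_r2", "se", "overall_p")},
                "rss": self.fits[k].rss,
                "loglik": self.fits[k].loglik,
                "n": self.fits[k].n,
                "p": self.fits[k].p,
                "aicc": self.aicc[k],
                "delta_aicc": self.delta_aicc[k],
                "akaike_weight": self.akaike_weight[k],
                "params": self.fits[k].params.to_dict(k),
            }
        for (red, full), test in self.nested_tests.items():
            out["nested_f_tests"].append(
                {"reduced": red.name, "full": full.name, **test}
            )
        return out

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def render_text(self) -> str:
        """Aligned-text report: rows Adj.R^2 / AICc / w(AICc), model columns."""
        kinds = self.kinds
        header = f"{'':>10}" + "".join(f"{('Model ' + k.name):>12}" for k in kinds)
        rows = [
            ("Adj.R2", [f"{self.gof[k]['adj_r2']:.3f}" for k in kinds]),
            ("AICc", [f"{self.aicc[k]:.2f}" for k in kinds]),
            ("w(AICc)", [f"{self.akaike_weight[k]:.3f}" for k in kinds]),
        ]
        lines = [header]
        for label, cells in rows:
            lines.append(f"{label:>10}" + "".join(f"{c:>12}" for c in cells))
        return "\n".join(lines)


def compare_models(
    series: TrainingTimeSeries,
    n_starts: int = 20,
    seed: int = 0,
    removal: str = "euler",
    kinds: Sequence[ModelKind] = KIND_ORDER,
    **fit_kw,
) -> SelectionTable:
    """Fit all variants to one series and assemble the comparison table.

    Fits are warm-started along the nesting lattice: the T optimum seeds TI
    and TF, and the TI/TF optima seed TIF, so RSS can only improve as
    parameters are added.
    """
    fits: dict[ModelKind, SecondarySignalResults] = {}
    failures: dict[ModelKind, str] = {}
    optima: dict[ModelKind, SecondarySignalResults] = {}
    for kind in kinds:
        extra = []
        for parent in kind.nested_parents:
            if parent in optima:
                base = optima[parent].params.to_dict(parent)
                # absent mechanisms enter at their inert value
                if "k_i" in kind.param_names and "k_i" not in base:
                    base["k_i"] = 1e-5
                if "k_f1" in kind.param_names and "k_f1" not in base:
                    base["k_f1"] = 0.0
                    base["k_f2"] = 0.1
                from .params import ModelParameters

                extra.append(ModelParameters.from_dict(base))
        try:
            fit = SecondarySignalModel(series, kind, removal).fit(
                n_starts=n_starts, seed=seed, extra_starts=extra, **fit_kw
            )
            fits[kind] = fit
            optima[kind] = fit
        except Exception as err:  # partial table with failure flags
            failures[kind] = f"{type(err).__name__}: {err}"

    gof = {k: goodness_of_fit(f, series) for k, f in fits.items()}
    aicc_vals = {k: aicc(f) for k, f in fits.items()}
    ordered = [k for k in KIND_ORDER if k in fits]
    weights = akaike_weights([aicc_vals[k] for k in ordered]) if len(ordered) >= 2 else np.ones(len(ordered))
    weight_map = dict(zip(ordered, map(float, weights)))
    amin = min(aicc_vals.values()) if aicc_vals else math.nan
    delta = {k: v - amin for k, v in aicc_vals.items()}
    nested = {}
    for full in ordered:
        for red in full.nested_parents:
            if red in fits:
                nested[(red, full)] = nested_f_test(fits[red], fits[full])
    return SelectionTable(
        fits=fits,
        gof=gof,
        aicc=aicc_vals,
        delta_aicc=delta,
        akaike_weight=weight_map,
        nested_tests=nested,
        failures=failures,
    )
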