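"""Rate-constant containers for the secondary-signal models."""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Mapping

from .kinds import ModelKind


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants of a secondary-signal model.

    Parameters
    ----------
    k_off : float
        First-order removal rate of performance (1/day), > 0.  The baseline
        zero-order production k0_on = k_off * Perf_0 is derived from it
        (stationarity constraint) and never stored.
    k_s1 : float
        First-order dissipation rate of the secondary signal (1/day), > 0.
    k_s2 : float
        Gain transforming signal into production of performance
        (W/day per tu of signal), >= 0.
    k_i : float, optional
        Inhibition proportionality constant (1/tu), >= 0.  Used by TI/TIF.
    k_f1 : float, optional
        Fatigue production gain (W per tu); sign unconstrained.  TF/TIF.
    k_f2 : float, optional
        First-order dissipation rate of fatigue (1/day), > 0.  TF/TIF.
    """

    k_off: float
    k_s1: float
    k_s2: float
    k_i: float | None = None
    k_f1: float | None = None
    k_f2: float | None = None

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None and not math.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v!r}")
        if self.k_off is None or self.k_off <= 0:
            raise ValueError(f"k_off must be > 0, got {self.k_off!r}")
        if self.k_s1 is None or self.k_s1 <= 0:
            raise ValueError(f"k_s1 must be > 0, got {self.k_s1!r}")
        if self.k_s2 is None or self.k_s2 < 0:
            raise ValueError(f"k_s2 must be >= 0, got {self.k_s2!r}")
        if self.k_i is not None and self.k_i < 0:
            raise ValueError(f"k_i must be >= 0, got {self.k_i!r}")
        if self.k_f2 is not None and self.k_f2 <= 0:
            raise ValueError(f"k_f2 must be > 0, got {self.k_f2!r}")

    def validate_for(self, kind: ModelKind) -> None:
        """Check that every parameter required by ``kind`` is present.

        Fields not belonging to the kind are permitted but ignored by the
        recursion (nested-model reduction uses this).
        """
        missing = [n for n in kind.param_names if getattr(self, n) is None]
        if missing:
            raise ValueError(f"model {kind.name} requires parameters {missing}")

    def for_kind(self, kind: ModelKind) -> "ModelParameters":
        """Copy with fields outside ``kind`` dropped."""
        self.validate_for(kind)
        return ModelParameters(**{n: getattr(self, n) for n in kind.param_names})

    def to_array(self, kind: ModelKind) -> list[float]:
        self.validate_for(kind)
        return [float(getattr(self, n)) for n in kind.param_names]

    @classmethod
    def from_array(cls, kind: ModelKind, values: Iterable[float]) -> "ModelParameters":
        values = list(values)
        if len(values) != kind.n_params:
            raise ValueError(
                f"model {kind.name} takes {kind.n_params} parameters, got {len(values)}"
            )
        return cls(**dict(zip(kind.param_names, map(float, values))))

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown parameter names {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_dict(self, kind: ModelKind | None = None) -> dict[str, float]:
        if kind is not None:
            return {n: float(getattr(self, n)) for n in kind.param_names}
        return {
            f.name: float(getattr(self, f.name))
            for f in fields(self)
            if getattr(self, f.name) is not None
        }
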