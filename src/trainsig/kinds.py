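"""Model variants of the secondary-signal family.

Four nested variants describe how daily training doses translate into
performance: a base model in which a first-order secondary signal drives
production of performance (T), and extensions adding same-day inhibition of
that production (TI), a subtractive fatigue component (TF), or both (TIF).
"""

from __future__ import annotations

import enum


class ModelKind(enum.Enum):
    """Enumeration of the four secondary-signal model variants.

    T
        Training effect only: signal production/dissipation plus first-order
        removal of performance (3 parameters: k_off, k_s1, k_s2).
    TI
        Adds dose-proportional, same-day inhibition of the transformation of
        signal into performance (4 parameters: + k_i).
    TF
        Adds a first-order fatigue component subtracted from performance; the
        observable is net performance (5 parameters: + k_f1, k_f2).
    TIF
        Both inhibition and fatigue (6 parameters).
    """

    T = "T"
    TI = "TI"
    TF = "TF"
    TIF = "TIF"

    @property
    def has_inhibition(self) -> bool:
        return self in (ModelKind.TI, ModelKind.TIF)

    @property
    def has_fatigue(self) -> bool:
        return self in (ModelKind.TF, ModelKind.TIF)

    @property
    def n_params(self) -> int:
        """Number of free parameters: 3 (T), 4 (TI), 5 (TF), 6 (TIF)."""
        return 3 + (1 if self.has_inhibition else 0) + (2 if self.has_fatigue else 0)

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["k_off", "k_s1", "k_s2"]
        if self.has_inhibition:
            names.append("k_i")
        if self.has_fatigue:
            names += ["k_f1", "k_f2"]
        return tuple(names)

    @classmethod
    def coerce(cls, value: "ModelKind | str") -> "ModelKind":
        if isinstance(value, cls):
            return value
        try:
            return cls[str(value).upper()]
        except KeyError:
            raise ValueError(
                f"unknown model kind {value!r}; expected one of "
                f"{[k.name for k in cls]}"
            ) from None

    # nesting structure used by the F-ratio test and by warm-started fits
    @property
    def nested_parents(self) -> tuple["ModelKind", ...]:
        """Reduced models directly nested inside this one."""
        return {
            ModelKind.T: (),
            ModelKind.TI: (ModelKind.T,),
            ModelKind.TF: (ModelKind.T,),
            ModelKind.TIF: (ModelKind.TI, ModelKind.TF),
        }[self]

    def is_nested_in(self, full: "ModelKind") -> bool:
        """True if every mechanism of this model is present in ``full``."""
        if self is full:
            return False
        return set(self.param_names) < set(full.param_names)
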