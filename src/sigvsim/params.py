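"""Parameterisation of the sigma-V / RsiV circuit.

The circuit couples an alternative sigma factor (sigma-V) to its
anti-sigma factor (RsiV) through a *mixed* feedback loop: free sigma-V
drives a single operon that produces both sigma-V (positive arm) and
RsiV (negative arm), while RsiV sequesters sigma-V in an inactive
complex.  Lysozyme stress cleaves the complex, releasing sigma-V and
destroying RsiV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = ["CircuitParameters", "VariantSpec", "VARIANT_KINDS"]


_PARAM_FIELDS = ("v0", "v", "K", "n", "k_deg", "k_B", "k_D", "k_C")


@dataclass(frozen=True)
class CircuitParameters:
    """Rate constants of the sigma-V circuit.

    Attributes
    ----------
    v0 : float
        Operon leak production rate (molecules/min).
    v : float
        Maximal operon activity on top of the leak (molecules/min).
    K : float
        Apparent dissociation constant of the Hill activation (molecules).
    n : float
        Hill coefficient of operon activation by free sigma-V.
    k_deg : float
        Dilution rate of all three species (1/min); set to roughly the
        experimental division rate, since the proteins are stable.
    k_B : float
        sigma-V + RsiV binding rate (1/(molecule*min)).
    k_D : float
        Complex dissociation rate (1/min).
    k_C : float
        Base cleavage rate of the complex (1/min); the effective
        cleavage rate is ``L * k_C`` where L is the lysozyme level.
    """

    v0: float = 0.1
    v: float = 2.5
    K: float = 60.0
    n: float = 2.0
    k_deg: float = 0.01
    k_B: float = 10.0
    k_D: float = 5.0
    k_C: float = 0.05

    def __post_init__(self) -> None:
        for name in _PARAM_FIELDS:
            value = getattr(self, name)
            if not (value >= 0):
                raise ValueError(f"parameter {name} must be >= 0, got {value!r}")
        if self.n < 1:
            raise ValueError(f"Hill coefficient n must be >= 1, got {self.n!r}")

    def replace(self, **kwargs) -> "CircuitParameters":
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in _PARAM_FIELDS}

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParameters":
        unknown = set(d) - set(_PARAM_FIELDS)
        if unknown:
            raise ValueError(f"unknown parameter key(s): {sorted(unknown)}")
        return cls(**d)


VARIANT_KINDS = (
    "wild_type",
    "second_copy_sigv",
    "second_copy_rsiv",
    "second_copy_operon",
    "feedback_broken",
    "leak_sigv",
    "leak_rsiv",
    "hill_override",
)

_NEEDS_POSITIVE_MAGNITUDE = ("feedback_broken", "leak_sigv", "leak_rsiv")


@dataclass(frozen=True)
class VariantSpec:
    """A genetic or structural perturbation of the wild-type circuit.

    ``magnitude`` is the constitutive production rate for
    ``feedback_broken``, the added baseline rate for the leak variants,
    and the replacement Hill coefficient for ``hill_override``; it is
    ignored for the copy-number variants and the wild type.
    """

    kind: str = "wild_type"
    magnitude: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in VARIANT_KINDS:
            raise ValueError(
                f"unknown variant kind {self.kind!r}; expected one of {VARIANT_KINDS}"
            )
        if self.kind in _NEEDS_POSITIVE_MAGNITUDE:
            if self.magnitude is None or not self.magnitude > 0:
                raise ValueError(
                    f"variant {self.kind!r} requires magnitude > 0, got {self.magnitude!r}"
                )
        if self.kind == "hill_override":
            if self.magnitude is None or self.magnitude < 1:
                raise ValueError(
                    f"hill_override requires magnitude >= 1, got {self.magnitude!r}"
                )

    def as_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.magnitude is not None:
            d["magnitude"] = self.magnitude
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VariantSpec":
        unknown = set(d) - {"kind", "magnitude"}
        if unknown:
            raise ValueError(f"unknown variant key(s): {sorted(unknown)}")
        return cls(**d)


WILD_TYPE = VariantSpec("wild_type")
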