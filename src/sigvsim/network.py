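"""Reaction-network construction for the sigma-V circuit.

The state vector is ``(sigv, rsiv, complex)``: free sigma-V, free RsiV
and the sigma-V--RsiV complex.  The wild-type network has seven
channels:

======================  ======================  =======================
channel                 stoichiometry           propensity
======================  ======================  =======================
operon production       (+1, +1, 0)             v0 + v*s^n/(s^n + K^n)
sigma-V dilution        (-1, 0, 0)              k_deg * s
RsiV dilution           (0, -1, 0)              k_deg * r
complex dilution        (0, 0, -1)              k_deg * c
binding                 (-1, -1, +1)            k_B * s * r
dissociation            (+1, +1, -1)            k_D * c
cleavage                (+1, 0, -1)             L * k_C * c
======================  ======================  =======================

Cleavage releases sigma-V and destroys RsiV, so it conserves total
sigma-V and removes exactly one RsiV.  Variants add or replace channels
(see :func:`build_network`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .params import CircuitParameters, VariantSpec

__all__ = [
    "ReactionNetwork",
    "CircuitState",
    "hill_production_rate",
    "build_network",
    "propensities",
    "apply_reaction",
]

N_SPECIES = 3
SIGV, RSIV, COMPLEX = 0, 1, 2

# propensity kind codes (shared with the jitted simulation cores)
CONST = 0      # a = rate
LINEAR = 1     # a = rate * x[s0]
BILINEAR = 2   # a = rate * x[s0] * x[s1]
HILL = 3       # a = rate + hv * x[s0]^hn / (x[s0]^hn + hK^hn)
LINEAR_L = 4   # a = L * rate * x[s0]


def _as_state(state) -> np.ndarray:
    x = np.asarray(state, dtype=float)
    if x.shape != (N_SPECIES,):
        raise ValueError(f"state must have 3 entries (sigv, rsiv, complex), got {x!r}")
    if np.any(x < 0):
        raise ValueError(f"state must be non-negative, got {x!r}")
    return x


class CircuitState:
    """Convenience constructors for (sigv, rsiv, complex) state vectors."""

    @staticmethod
    def zeros(dtype=np.int64) -> np.ndarray:
        return np.zeros(N_SPECIES, dtype=dtype)

    @staticmethod
    def of(sigv, rsiv, complex, dtype=np.int64) -> np.ndarray:
        x = np.array([sigv, rsiv, complex], dtype=dtype)
        if np.any(x < 0):
            raise ValueError("copy numbers must be non-negative")
        return x


def hill_production_rate(sigv_free: float, params: CircuitParameters) -> float:
    """Operon production rate v0 + v*s^n/(s^n + K^n) at free sigma-V ``s``.

    Strictly increasing in ``sigv_free`` when ``v > 0`` and bounded in
    ``[v0, v0 + v)``; equals ``v0 + v/2`` exactly at ``s = K``.
    """
    if sigv_free < 0:
        raise ValueError(f"sigv_free must be >= 0, got {sigv_free!r}")
    if sigv_free == 0:
        return params.v0
    # branch on the ratio so neither extreme of s can overflow
    if sigv_free < params.K:
        t = (sigv_free / params.K) ** params.n
        return params.v0 + params.v * t / (1.0 + t)
    ratio = (params.K / sigv_free) ** params.n
    return params.v0 + params.v / (1.0 + ratio)


@dataclass(frozen=True)
class ReactionNetwork:
    """Array-encoded reaction network, ready for the simulation cores.

    Channels are encoded column-wise: ``stoich[j]`` is the stoichiometry
    vector of channel ``j`` over (sigv, rsiv, complex), ``kind[j]`` the
    propensity-form code, ``rate[j]`` its rate constant (the leak v0 for
    Hill channels), ``hv/hK/hn[j]`` the Hill parameters (unused
    otherwise) and ``s0/s1[j]`` the reactant species indices.
    """

    stoich: np.ndarray
    kind: np.ndarray
    rate: np.ndarray
    hv: np.ndarray
    hK: np.ndarray
    hn: np.ndarray
    s0: np.ndarray
    s1: np.ndarray
    labels: tuple
    params: CircuitParameters
    variant: VariantSpec

    @property
    def n_channels(self) -> int:
        return len(self.kind)

    def arrays(self):
        """The tuple of arrays consumed by the jitted simulation cores."""
        return (self.stoich, self.kind, self.rate, self.hv, self.hK,
                self.hn, self.s0, self.s1)


def _channel(label, stoich, kind, rate, hv=0.0, hK=1.0, hn=1.0, s0=0, s1=0):
    return (label, stoich, kind, rate, hv, hK, hn, s0, s1)


def build_network(params: CircuitParameters,
                  variant: VariantSpec = VariantSpec()) -> ReactionNetwork:
    """Assemble the reaction network for a parameter set and variant.

    Variants:

    - ``second_copy_sigv`` / ``second_copy_rsiv``: an extra channel
      producing only sigma-V (resp. RsiV) at the same Hill rate,
      mimicking a second gene copy driven by the sigV promoter.
    - ``second_copy_operon``: a duplicate of the full production channel
      (equivalent to doubling v0 and v).
    - ``feedback_broken``: the Hill production channel is replaced by a
      constant-rate channel (constitutive operon expression at
      ``magnitude`` molecules/min, still producing the pair).
    - ``leak_sigv`` / ``leak_rsiv``: an independent constant-rate
      channel adding baseline production of one species.
    - ``hill_override``: the Hill coefficient is replaced by
      ``magnitude``.
    """
    n = params.n
    if variant.kind == "hill_override":
        n = float(variant.magnitude)

    hill = dict(kind=HILL, rate=params.v0, hv=params.v, hK=params.K, hn=n, s0=SIGV)

    chans = []
    if variant.kind == "feedback_broken":
        chans.append(_channel("production", (1, 1, 0), CONST, float(variant.magnitude)))
    else:
        chans.append(_channel("production", (1, 1, 0), **hill))
    chans += [
        _channel("dilution_sigv", (-1, 0, 0), LINEAR, params.k_deg, s0=SIGV),
        _channel("dilution_rsiv", (0, -1, 0), LINEAR, params.k_deg, s0=RSIV),
        _channel("dilution_complex", (0, 0, -1), LINEAR, params.k_deg, s0=COMPLEX),
        _channel("binding", (-1, -1, 1), BILINEAR, params.k_B, s0=SIGV, s1=RSIV),
        _channel("dissociation", (1, 1, -1), LINEAR, params.k_D, s0=COMPLEX),
        _channel("cleavage", (1, 0, -1), LINEAR_L, params.k_C, s0=COMPLEX),
    ]

    if variant.kind == "second_copy_sigv":
        chans.append(_channel("production_2x_sigv", (1, 0, 0), **hill))
    elif variant.kind == "second_copy_rsiv":
        chans.append(_channel("production_2x_rsiv", (0, 1, 0), **hill))
    elif variant.kind == "second_copy_operon":
        chans.append(_channel("production_2x_operon", (1, 1, 0), **hill))
    elif variant.kind == "leak_sigv":
        chans.append(_channel("leak_sigv", (1, 0, 0), CONST, float(variant.magnitude)))
    elif variant.kind == "leak_rsiv":
        chans.append(_channel("leak_rsiv", (0, 1, 0), CONST, float(variant.magnitude)))
    elif variant.kind not in ("wild_type", "feedback_broken", "hill_override"):
        # unreachable for validated VariantSpec, kept as a guard
        raise ValueError(f"unknown variant kind {variant.kind!r}")

    labels, st, kd, rt, hv, hK, hn, s0, s1 = zip(*chans)
    return ReactionNetwork(
        stoich=np.array(st, dtype=np.int64),
        kind=np.array(kd, dtype=np.int64),
        rate=np.array(rt, dtype=np.float64),
        hv=np.array(hv, dtype=np.float64),
        hK=np.array(hK, dtype=np.float64),
        hn=np.array(hn, dtype=np.float64),
        s0=np.array(s0, dtype=np.int64),
        s1=np.array(s1, dtype=np.int64),
        labels=tuple(labels),
        params=params,
        variant=variant,
    )


def single_species_death_network(rate: float, species: int = SIGV,
                                 params: CircuitParameters | None = None) -> ReactionNetwork:
    """Calibration network: one first-order death channel on one species.

    The linear death process has the closed-form mean ``x0 * exp(-rate*t)``,
    which makes this network a convenient exactness oracle for the
    stochastic simulators.  Pass ``rate=0`` for an all-rates-zero network.
    """
    if rate < 0:
        raise ValueError(f"death rate must be >= 0, got {rate!r}")
    st = [0, 0, 0]
    st[species] = -1
    label, stoich, kind, r, hv, hK, hn, s0, s1 = _channel(
        "death", tuple(st), LINEAR, rate, s0=species)
    return ReactionNetwork(
        stoich=np.array([stoich], dtype=np.int64),
        kind=np.array([kind], dtype=np.int64),
        rate=np.array([r], dtype=np.float64),
        hv=np.array([hv]), hK=np.array([hK]), hn=np.array([hn]),
        s0=np.array([s0], dtype=np.int64), s1=np.array([s1], dtype=np.int64),
        labels=(label,),
        params=params or CircuitParameters(),
        variant=VariantSpec(),
    )


def propensities(network: ReactionNetwork, state, L: float) -> np.ndarray:
    """Per-channel reaction rates (1/min) at a state and lysozyme level."""
    if L < 0:
        raise ValueError(f"lysozyme level L must be >= 0, got {L!r}")
    x = _as_state(state)
    a = np.empty(network.n_channels, dtype=float)
    for j in range(network.n_channels):
        kind = network.kind[j]
        if kind == CONST:
            a[j] = network.rate[j]
        elif kind == LINEAR:
            a[j] = network.rate[j] * x[network.s0[j]]
        elif kind == BILINEAR:
            a[j] = network.rate[j] * x[network.s0[j]] * x[network.s1[j]]
        elif kind == HILL:
            s = x[network.s0[j]]
            if s == 0:
                a[j] = network.rate[j]
            else:
                a[j] = network.rate[j] + network.hv[j] / (
                    1.0 + (network.hK[j] / s) ** network.hn[j]
                )
        else:  # LINEAR_L
            a[j] = L * network.rate[j] * x[network.s0[j]]
    return a


def apply_reaction(state, network: ReactionNetwork, channel: int) -> np.ndarray:
    """State after firing one reaction event of the given channel."""
    x = np.asarray(state)
    new = x + network.stoich[channel]
    if np.any(new < 0):
        raise RuntimeError(
            f"channel {network.labels[channel]} would drive state {x} negative"
        )
    return new
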