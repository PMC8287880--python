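"""Deterministic mean-field companion of the stochastic circuit.

The mean-field ODE is assembled channel-by-channel from the same
:class:`~sigvsim.network.ReactionNetwork` used by the stochastic
simulators, so every term of the right-hand side corresponds one-to-one
to a reaction channel.  It serves as a verification oracle: in the
large-system (small-noise) limit the stochastic ensemble mean follows
this ODE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import ReactionNetwork, propensities

__all__ = ["mean_field_rhs", "integrate_ode", "steady_state", "SteadyStateResult"]


def mean_field_rhs(state, network: ReactionNetwork, L: float) -> np.ndarray:
    """Time derivatives d(sigv, rsiv, complex)/dt at a continuous state."""
    a = propensities(network, state, L)
    return network.stoich.T @ a


def integrate_ode(network: ReactionNetwork, L: float, t_span, x0,
                  t_eval=None, rtol: float = 1e-8, atol: float = 1e-10):
    """Integrate the mean-field ODE at constant lysozyme level L."""

    def rhs(t, x):
        # clamp tiny negative excursions from the integrator
        return mean_field_rhs(np.maximum(x, 0.0), network, L)

    sol = solve_ivp(rhs, t_span, np.asarray(x0, dtype=float), t_eval=t_eval,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol


def integrate_ode_protocol(network: ReactionNetwork, protocol, times: np.ndarray,
                           x0) -> np.ndarray:
    """Mean-field solution sampled on ``times`` under a piecewise-constant
    lysozyme protocol (segments integrated back-to-back)."""
    times = np.asarray(times, dtype=float)
    out = np.empty((len(times), 3))
    x = np.asarray(x0, dtype=float)
    bounds = protocol.segment_bounds(times[-1])
    t_prev = times[0]
    for (t0, t1, L) in bounds:
        t0 = max(t0, t_prev)
        if t1 <= t0:
            continue
        mask = (times >= t0) & (times <= t1)
        t_eval = np.unique(np.concatenate([[t0], times[mask], [t1]]))
        sol = integrate_ode(network, L, (t0, t1), x, t_eval=t_eval)
        interp = {t: y for t, y in zip(sol.t, sol.y.T)}
        for i, t in enumerate(times):
            if mask[i]:
                out[i] = interp[t]
        x = sol.y[:, -1]
        t_prev = t1
    return out


@dataclass(frozen=True)
class SteadyStateResult:
    """A steady state of the mean-field ODE.

    ``state`` is the fixed point reached from the zero-state initial
    condition (the canonical low branch when the system is bistable);
    ``multistable`` flags whether a distinct fixed point is reached from
    a high-sigma-V initial condition, which is then given in
    ``high_state``.
    """

    state: np.ndarray
    multistable: bool
    high_state: np.ndarray | None = None

    @property
    def sigv(self) -> float:
        return float(self.state[0])


def _settle(network: ReactionNetwork, L: float, x0, t_final: float) -> np.ndarray:
    sol = integrate_ode(network, L, (0.0, t_final), x0)
    x = np.maximum(sol.y[:, -1], 0.0)
    res = root(lambda y: mean_field_rhs(np.maximum(y, 0.0), network, L), x,
               method="hybr", tol=1e-12)
    if res.success and np.all(res.x > -1e-9):
        x = np.maximum(res.x, 0.0)
    # verify: the residual must be tiny either way
    if np.max(np.abs(mean_field_rhs(x, network, L))) > 1e-6:
        raise RuntimeError(
            f"steady-state search did not converge at L={L}: state={x}, "
            f"residual={mean_field_rhs(x, network, L)}"
        )
    return x


def steady_state(network: ReactionNetwork, L: float,
                 t_final: float = 1e5, rel_tol: float = 1e-3) -> SteadyStateResult:
    """Mean-field fixed point, probed from low and high initial conditions.

    Returns the state reached from ``(0, 0, 0)``; if integrating from a
    high-sigma-V initial condition lands on a distinct fixed point
    (relative difference above ``rel_tol``), the result is flagged
    multistable and the high branch is reported too.
    """
    if L < 0:
        raise ValueError(f"L must be >= 0, got {L!r}")
    low = _settle(network, L, np.zeros(3), t_final)
    p = network.params
    scale = (p.v0 + p.v) / p.k_deg if p.k_deg > 0 else 10.0 * p.K
    high = _settle(network, L, np.array([2.0 * scale, 0.0, 0.0]), t_final)
    denom = max(np.max(np.abs(low)), np.max(np.abs(high)), 1.0)
    multistable = bool(np.max(np.abs(high - low)) / denom > rel_tol)
    return SteadyStateResult(state=low, multistable=multistable,
                             high_state=high if multistable else None)
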