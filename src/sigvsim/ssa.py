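"""Stochastic simulation of the circuit: Gillespie direct SSA and a
chemical-Langevin (Euler--Maruyama) scheme under piecewise-constant
lysozyme protocols.

Both simulators handle the time-varying input exactly for
piecewise-constant rates: at every protocol segment boundary the
exponential clock is simply re-drawn with the updated propensities,
which is exact because all rates are constant within a segment.

The inner loops are compiled with numba when available (they fall back
to pure Python transparently); trajectories are recorded on a uniform
sampling grid by last-event-carried-forward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .network import ReactionNetwork
from .params import VariantSpec
from .protocols import StressProtocol

__all__ = [
    "Trajectory",
    "Ensemble",
    "simulate_ssa",
    "simulate_cle",
    "simulate_ensemble",
    "child_seeds",
]

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _propensity_sum(x, L, kind, rate, hv, hK, hn, s0, s1, a):
    total = 0.0
    for j in range(kind.size):
        k = kind[j]
        if k == 0:
            aj = rate[j]
        elif k == 1:
            aj = rate[j] * x[s0[j]]
        elif k == 2:
            aj = rate[j] * x[s0[j]] * x[s1[j]]
        elif k == 3:
            s = x[s0[j]]
            if s <= 0.0:
                aj = rate[j]
            else:
                r = hK[j] / s
                if hn[j] == 2.0:
                    ratio = r * r
                elif hn[j] == 1.0:
                    ratio = r
                else:
                    ratio = r ** hn[j]
                aj = rate[j] + hv[j] / (1.0 + ratio)
        else:
            aj = L * rate[j] * x[s0[j]]
        a[j] = aj
        total += aj
    return total


@njit(cache=True)
def _ssa_core(x0, seg_starts, seg_levels, t_end, sample_times,
              stoich, kind, rate, hv, hK, hn, s0, s1, seed):
    np.random.seed(seed)
    m = kind.size
    a = np.empty(m)
    x = x0.astype(np.float64)
    ns = sample_times.size
    out = np.empty((ns, 3))
    si = 0
    nseg = seg_starts.size
    for seg in range(nseg):
        t = seg_starts[seg]
        if t >= t_end:
            break
        t1 = seg_starts[seg + 1] if seg + 1 < nseg else t_end
        if t1 > t_end:
            t1 = t_end
        L = seg_levels[seg]
        while True:
            total = _propensity_sum(x, L, kind, rate, hv, hK, hn, s0, s1, a)
            if total <= 0.0:
                break  # fast-forward to the segment boundary
            tn = t - math.log(np.random.random()) / total
            if tn >= t1:
                break  # clock re-drawn at the boundary (exact for constant rates)
            while si < ns and sample_times[si] < tn:
                out[si, 0] = x[0]
                out[si, 1] = x[1]
                out[si, 2] = x[2]
                si += 1
            u = np.random.random() * total
            c = 0.0
            jsel = m - 1
            for j in range(m):
                c += a[j]
                if u < c:
                    jsel = j
                    break
            x[0] += stoich[jsel, 0]
            x[1] += stoich[jsel, 1]
            x[2] += stoich[jsel, 2]
            t = tn
    while si < ns:
        out[si, 0] = x[0]
        out[si, 1] = x[1]
        out[si, 2] = x[2]
        si += 1
    return out


@njit(cache=True)
def _ssa_events_core(x0, seg_starts, seg_levels, t_end,
                     stoich, kind, rate, hv, hK, hn, s0, s1, seed, max_events):
    np.random.seed(seed)
    m = kind.size
    a = np.empty(m)
    x = x0.astype(np.float64)
    ev_t = np.empty(max_events)
    ev_c = np.empty(max_events, np.int64)
    ev_x = np.empty((max_events, 3))
    ne = 0
    nseg = seg_starts.size
    for seg in range(nseg):
        t = seg_starts[seg]
        if t >= t_end:
            break
        t1 = seg_starts[seg + 1] if seg + 1 < nseg else t_end
        if t1 > t_end:
            t1 = t_end
        L = seg_levels[seg]
        while True:
            total = _propensity_sum(x, L, kind, rate, hv, hK, hn, s0, s1, a)
            if total <= 0.0:
                break
            tn = t - math.log(np.random.random()) / total
            if tn >= t1:
                break
            u = np.random.random() * total
            c = 0.0
            jsel = m - 1
            for j in range(m):
                c += a[j]
                if u < c:
                    jsel = j
                    break
            x[0] += stoich[jsel, 0]
            x[1] += stoich[jsel, 1]
            x[2] += stoich[jsel, 2]
            if ne >= max_events:
                return -1, ev_t, ev_c, ev_x
            ev_t[ne] = tn
            ev_c[ne] = jsel
            ev_x[ne, 0] = x[0]
            ev_x[ne, 1] = x[1]
            ev_x[ne, 2] = x[2]
            ne += 1
            t = tn
    return ne, ev_t, ev_c, ev_x


@njit(cache=True)
def _cle_core(x0, seg_starts, seg_levels, t_end, sample_times, dt_cap, adaptive, leap_target,
              stoich, kind, rate, hv, hK, hn, s0, s1, seed):
    np.random.seed(seed)
    m = kind.size
    a = np.empty(m)
    x = x0.astype(np.float64)
    xc = np.empty(3)
    ns = sample_times.size
    out = np.empty((ns, 3))
    si = 0
    nseg = seg_starts.size
    for seg in range(nseg):
        t = seg_starts[seg]
        if t >= t_end:
            break
        t1 = seg_starts[seg + 1] if seg + 1 < nseg else t_end
        if t1 > t_end:
            t1 = t_end
        L = seg_levels[seg]
        while t < t1:
            # full truncation: propensities see the state clamped at zero,
            # the state itself keeps its (small) negative excursions
            for i in range(3):
                xc[i] = x[i] if x[i] > 0.0 else 0.0
            _propensity_sum(xc, L, kind, rate, hv, hK, hn, s0, s1, a)
            dt = dt_cap
            if adaptive:
                amax = 0.0
                for j in range(m):
                    if a[j] > amax:
                        amax = a[j]
                if amax > 0.0 and leap_target / amax < dt:
                    dt = leap_target / amax
            if t + dt > t1:
                dt = t1 - t
            tn = t + dt
            while si < ns and sample_times[si] < tn:
                out[si, 0] = x[0]
                out[si, 1] = x[1]
                out[si, 2] = x[2]
                si += 1
            # drift sum_j nu_j a_j dt plus Gaussian noise with the exact
            # per-step covariance dt * sum_j a_j nu_j nu_j^T (equivalent in
            # law to independent per-channel noises, but needs 3 normal
            # draws instead of one per channel)
            s00 = s01 = s02 = s11 = s12 = s22 = 0.0
            for j in range(m):
                aj = a[j]
                if aj <= 0.0:
                    continue
                n0 = stoich[j, 0]
                n1 = stoich[j, 1]
                n2 = stoich[j, 2]
                x[0] += n0 * aj * dt
                x[1] += n1 * aj * dt
                x[2] += n2 * aj * dt
                s00 += aj * n0 * n0
                s01 += aj * n0 * n1
                s02 += aj * n0 * n2
                s11 += aj * n1 * n1
                s12 += aj * n1 * n2
                s22 += aj * n2 * n2
            # Cholesky of the 3x3 covariance rate matrix (semi-definite safe)
            l00 = math.sqrt(s00) if s00 > 0.0 else 0.0
            l10 = s01 / l00 if l00 > 0.0 else 0.0
            l20 = s02 / l00 if l00 > 0.0 else 0.0
            d1 = s11 - l10 * l10
            l11 = math.sqrt(d1) if d1 > 0.0 else 0.0
            l21 = (s12 - l20 * l10) / l11 if l11 > 0.0 else 0.0
            d2 = s22 - l20 * l20 - l21 * l21
            l22 = math.sqrt(d2) if d2 > 0.0 else 0.0
            sq = math.sqrt(dt)
            z0 = np.random.normal(0.0, 1.0)
            z1 = np.random.normal(0.0, 1.0)
            z2 = np.random.normal(0.0, 1.0)
            x[0] += sq * l00 * z0
            x[1] += sq * (l10 * z0 + l11 * z1)
            x[2] += sq * (l20 * z0 + l21 * z1 + l22 * z2)
            t = tn
    while si < ns:
        out[si, 0] = x[0]
        out[si, 1] = x[1]
        out[si, 2] = x[2]
        si += 1
    return out


@dataclass(frozen=True)
class Trajectory:
    """A single simulated path sampled on a uniform time grid."""

    times: np.ndarray
    states: np.ndarray  # (T, 3): sigv, rsiv, complex
    seed: int
    variant: VariantSpec
    protocol: StressProtocol
    method: str = "ssa"

    @property
    def sigv(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def rsiv(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def complex(self) -> np.ndarray:
        return self.states[:, 2]

    def lysozyme(self) -> np.ndarray:
        return np.array([self.protocol.level_at(t) for t in self.times])

    def to_dataframe(self, cell_id: int = 0) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": cell_id,
            "time_min": self.times,
            "sigv": self.states[:, 0],
            "rsiv": self.states[:, 1],
            "complex": self.states[:, 2],
            "L": self.lysozyme(),
        })


@dataclass(frozen=True)
class Ensemble:
    """N independent trajectories sharing grid, protocol and variant."""

    trajectories: List[Trajectory]

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise ValueError("ensemble must contain at least one trajectory")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def __getitem__(self, i):
        return self.trajectories[i]

    @property
    def times(self) -> np.ndarray:
        return self.trajectories[0].times

    @property
    def states(self) -> np.ndarray:
        """Stacked (N, T, 3) state array."""
        return np.stack([tr.states for tr in self.trajectories])

    @property
    def sigv(self) -> np.ndarray:
        """(N, T) free sigma-V copy numbers."""
        return self.states[:, :, 0]

    def mean_path(self) -> np.ndarray:
        return self.states.mean(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.concat(
            [tr.to_dataframe(cell_id=i) for i, tr in enumerate(self.trajectories)],
            ignore_index=True,
        )

    def to_hdf5(self, path) -> None:
        """Write the ensemble to an HDF5 container (large-run option)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("states", data=self.states)
            f.create_dataset("seeds", data=np.array([t.seed for t in self]))
            f.attrs["variant"] = str(self.trajectories[0].variant.as_dict())
            f.attrs["protocol"] = str(self.trajectories[0].protocol.as_dict())
            f.attrs["method"] = self.trajectories[0].method


def _grid(duration: float, sample_interval: float) -> np.ndarray:
    if sample_interval <= 0:
        raise ValueError(f"sample_interval must be > 0, got {sample_interval!r}")
    n = int(np.floor(duration / sample_interval + 1e-9))
    return np.arange(n + 1) * float(sample_interval)


def _prepare(network: ReactionNetwork, protocol: StressProtocol,
             duration: Optional[float], initial_state):
    if duration is None:
        duration = protocol.duration
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration!r}")
    if initial_state is None:
        x0 = np.zeros(3, dtype=np.int64)
    else:
        x0 = np.asarray(initial_state)
        if x0.shape != (3,) or np.any(x0 < 0):
            raise ValueError(f"initial_state must be 3 non-negative counts, got {initial_state!r}")
        x0 = x0.astype(np.int64)
    for arr in (network.rate, network.hv, network.hK, network.hn):
        if not np.all(np.isfinite(arr)):
            raise ValueError("network contains non-finite rate constants")
    starts, levels = protocol.arrays()
    return float(duration), x0, starts, levels


def simulate_ssa(network: ReactionNetwork, protocol: StressProtocol,
                 duration: Optional[float] = None, sample_interval: float = 10.0,
                 initial_state=None, seed: int = 0) -> Trajectory:
    """Exact Gillespie direct-method simulation of one cell.

    States are recorded on the uniform grid by last-event-carried-forward;
    identical (network, protocol, seed) yield bit-identical trajectories.
    """
    duration, x0, starts, levels = _prepare(network, protocol, duration, initial_state)
    times = _grid(duration, sample_interval)
    out = _ssa_core(x0, starts, levels, duration, times, *network.arrays(),
                    int(seed) & 0x7FFFFFFF)
    states = np.rint(out).astype(np.int64)
    if np.any(states < 0):
        raise RuntimeError("SSA produced a negative count (internal error)")
    return Trajectory(times=times, states=states, seed=int(seed),
                      variant=network.variant, protocol=protocol, method="ssa")


def simulate_ssa_events(network: ReactionNetwork, protocol: StressProtocol,
                        duration: Optional[float] = None, initial_state=None,
                        seed: int = 0, max_events: int = 2_000_000):
    """SSA run returning the full event record.

    Returns ``(event_times, channel_indices, states_after)`` for every
    reaction event; used to verify per-event conservation laws.
    """
    duration, x0, starts, levels = _prepare(network, protocol, duration, initial_state)
    ne, ev_t, ev_c, ev_x = _ssa_events_core(
        x0, starts, levels, duration, *network.arrays(),
        int(seed) & 0x7FFFFFFF, int(max_events))
    if ne < 0:
        raise RuntimeError(f"event record overflow (> {max_events} events)")
    return ev_t[:ne].copy(), ev_c[:ne].copy(), np.rint(ev_x[:ne]).astype(np.int64)


def simulate_cle(network: ReactionNetwork, protocol: StressProtocol,
                 duration: Optional[float] = None, dt: Optional[float] = None,
                 sample_interval: float = 10.0, initial_state=None,
                 seed: int = 0) -> Trajectory:
    """Chemical-Langevin (Euler--Maruyama over channels) simulation.

    Each step adds ``sum_j nu_j * (a_j dt + sqrt(a_j dt) xi_j)`` with
    independent standard-normal ``xi_j``.  By default the step size is
    chosen adaptively so that ``max_j a_j * dt <= 0.1`` (capped at 0.5
    min); pass ``dt`` to use a fixed step instead.  Negative excursions
    are handled by full truncation: propensities are evaluated on a copy
    of the state clamped at zero, the state itself keeps its small
    negative excursions (recorded samples are clamped at zero).
    """
    if dt is not None and dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt!r}")
    duration, x0, starts, levels = _prepare(network, protocol, duration, initial_state)
    times = _grid(duration, sample_interval)
    adaptive = dt is None
    dt_cap = 0.5 if adaptive else float(dt)
    out = _cle_core(x0, starts, levels, duration, times, dt_cap, adaptive, 0.1,
                    *network.arrays(), int(seed) & 0x7FFFFFFF)
    states = np.maximum(out, 0.0)
    return Trajectory(times=times, states=states, seed=int(seed),
                      variant=network.variant, protocol=protocol, method="cle")


def child_seeds(base_seed: int, n: int) -> np.ndarray:
    """Deterministically expand one base seed into n distinct child seeds."""
    seeds = np.random.SeedSequence(int(base_seed)).generate_state(n, dtype=np.uint64)
    seeds = (seeds % np.uint64(2**31)).astype(np.int64)
    # collisions are astronomically unlikely; resolve them anyway
    seen = set()
    for i in range(n):
        while int(seeds[i]) in seen:
            seeds[i] = (seeds[i] + 1) % 2**31
        seen.add(int(seeds[i]))
    return seeds


def simulate_ensemble(network: ReactionNetwork, protocol: StressProtocol,
                      duration: Optional[float] = None, sample_interval: float = 10.0,
                      N: int = 100, base_seed: int = 0, initial_state=None,
                      method: str = "ssa", dt: Optional[float] = None) -> Ensemble:
    """N independent trajectories with seeds derived from ``base_seed``."""
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N!r}")
    if method not in ("ssa", "cle"):
        raise ValueError(f"method must be 'ssa' or 'cle', got {method!r}")
    seeds = child_seeds(base_seed, N)
    trajectories = []
    for s in seeds:
        if method == "ssa":
            tr = simulate_ssa(network, protocol, duration, sample_interval,
                              initial_state, seed=int(s))
        else:
            tr = simulate_cle(network, protocol, duration, dt, sample_interval,
                              initial_state, seed=int(s))
        trajectories.append(tr)
    return Ensemble(trajectories)
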