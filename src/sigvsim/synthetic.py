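"""Synthetic mother-machine data with known ground truth.

Generates single-cell fluorescence traces and channel lineage forests
that look like mother-machine time-lapse data: a YFP-like reporter with
~15 min maturation delay driven by the operon promoter, frames every
~10 min, divisions every ~51 +/- 13 min, multiplicative lognormal
measurement noise, a width channel with a configurable fraction of
"sick" (overshooting, wider) cells, and death events under lethal
stress.  Every dataset is reproducible from (config, seed) and is
emitted together with its ground truth, which is the test surface for
the trace statistics.

The reporter is deliberately distinct from the model readout: model
analyses read free sigma-V directly, while the synthetic reporter
integrates the operon production rate through a maturation filter and
dilution, like a transcriptional reporter protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .network import build_network, hill_production_rate
from .params import CircuitParameters, VariantSpec
from .protocols import StressProtocol
from .ssa import Trajectory, child_seeds, simulate_ensemble, simulate_ssa
from .traces import CellTrace, LineageCell, LineageForest

__all__ = [
    "GeneratorConfig",
    "generate_reporter_trace",
    "generate_mother_machine_ensemble",
    "generate_parametric_traces",
    "generate_priming_lineages",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic mother-machine generator.

    Times are minutes, lengths/widths micrometres.  Defaults emulate the
    imaging cadence (10 min frames), the ~15 min YFP maturation time and
    the 51 +/- 13 min cell-cycle time of the experimental system.
    ``measurement_noise`` is the sigma of multiplicative lognormal noise
    on fluorescence.  ``sick_fraction`` of cells become wider (by
    ``sick_width_factor``) after stress.  ``prestress_correlation`` is
    the programmed anti-correlation between pre-stress reporter level
    and switch delay in the parametric trace generator.
    ``survival_rule`` maps reporter level at lethal-stress onset to a
    survival probability (default: constant 0.5); it is a free modelling
    knob, there being no quantitative survival-vs-expression dose curve
    to emulate.
    """

    frame_interval: float = 10.0
    maturation_time: float = 15.0
    division_time_mean: float = 51.0
    division_time_sd: float = 13.0
    measurement_noise: float = 0.05
    length_at_birth: float = 2.0
    width_mean: float = 1.0
    width_sd: float = 0.03
    width_frame_noise: float = 0.01
    sick_fraction: float = 0.1
    sick_width_factor: float = 1.5
    prestress_correlation: float = 0.6
    survival_rule: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        for name in ("frame_interval", "division_time_mean", "division_time_sd",
                     "length_at_birth", "width_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("maturation_time", "measurement_noise", "width_sd",
                     "width_frame_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.sick_fraction <= 1:
            raise ValueError("sick_fraction must be in [0, 1]")

    def survival_probability(self, reporter_level: float) -> float:
        rule = self.survival_rule or (lambda level: 0.5)
        p = float(rule(reporter_level))
        return min(max(p, 0.0), 1.0)


def _stress_time(protocol: StressProtocol) -> float:
    for start, L in protocol.segments:
        if L > 0:
            return start
    return protocol.duration


def _reporter_filter(production: np.ndarray, dt: float, maturation_time: float,
                     k_deg: float) -> np.ndarray:
    """Mature-reporter level driven by a piecewise-constant production
    rate: immature -> mature conversion at rate 1/maturation_time, both
    pools diluted at k_deg.  Exact exponential updates per frame;
    initialised at the steady state of the first input value."""
    u = np.asarray(production, dtype=float)
    if maturation_time == 0:
        a = k_deg
        M = np.empty_like(u)
        M[0] = u[0] / a if a > 0 else 0.0
        decay = np.exp(-a * dt)
        for i in range(1, len(u)):
            gain = (u[i - 1] / a) * (1 - decay) if a > 0 else u[i - 1] * dt
            M[i] = M[i - 1] * decay + gain
        return M
    km = 1.0 / maturation_time
    a_i = km + k_deg  # immature loss rate
    a_m = k_deg       # mature loss rate
    I = np.empty_like(u)
    M = np.empty_like(u)
    I[0] = u[0] / a_i
    M[0] = km * I[0] / a_m if a_m > 0 else 0.0
    di = np.exp(-a_i * dt)
    dm = np.exp(-a_m * dt)
    for i in range(1, len(u)):
        u0 = u[i - 1]
        i_ss = u0 / a_i
        dev = I[i - 1] - i_ss
        I[i] = i_ss + dev * di
        # exact solution of M' = km*I - a_m*M over one frame with I(t)
        # relaxing exponentially from I[i-1] to i_ss
        transient = km * dev * (dm - di) / (a_i - a_m)
        if a_m > 0:
            m_ss = km * i_ss / a_m
            M[i] = m_ss + (M[i - 1] - m_ss) * dm + transient
        else:
            M[i] = M[i - 1] + km * i_ss * dt + km * dev * (1 - di) / a_i
    return M


def generate_reporter_trace(sigv_trajectory: Trajectory, config: GeneratorConfig,
                            seed: int = 0, params: CircuitParameters = None,
                            noiseless: bool = False) -> CellTrace:
    """Reporter trace for one sigma-V trajectory.

    The reporter production rate is the operon Hill production term
    evaluated on the trajectory's free sigma-V, passed through a
    first-order maturation filter (time constant ``maturation_time``)
    and diluted at k_deg, then sampled on frames with multiplicative
    lognormal measurement noise.  Deterministic for fixed seed.
    """
    params = params or CircuitParameters()
    tr = sigv_trajectory
    dt_traj = float(tr.times[1] - tr.times[0])
    if dt_traj > config.frame_interval + 1e-9:
        raise ValueError("trajectory must be sampled at <= frame_interval")
    production = np.array([hill_production_rate(s, params) for s in tr.sigv])
    mature = _reporter_filter(production, dt_traj, config.maturation_time, params.k_deg)
    stride = max(int(round(config.frame_interval / dt_traj)), 1)
    times = tr.times[::stride]
    signal = mature[::stride]
    if not noiseless and config.measurement_noise > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x4E0]))
        signal = signal * rng.lognormal(0.0, config.measurement_noise, size=len(signal))
    return CellTrace(cell_id=int(tr.seed), times=times, fluorescence=signal,
                     stress_time=_stress_time(tr.protocol))


def _half_max_crossing(times: np.ndarray, values: np.ndarray, stress_time: float,
                       final_window: float, sustained: int = 2) -> Optional[float]:
    """First sustained post-stress crossing of half the trailing-window
    mean; None when never crossed."""
    tail = times >= times[-1] - final_window + 1e-9
    half = values[tail].mean() / 2.0
    post = np.nonzero((times >= stress_time) & (values >= half))[0]
    for i in post:
        if all(values[min(i + k, len(values) - 1)] >= half for k in range(sustained)):
            return float(times[i] - stress_time)
    return None


def _grow_lengths(times: np.ndarray, rate: float, division_interval: float,
                  l0: float, t0: float = 0.0):
    """Exponential growth at ``rate`` reset by halving every
    ``division_interval``; returns (lengths, division frame indices)."""
    lengths = np.empty_like(times)
    div_frames = []
    birth = t0
    for i, t in enumerate(times):
        while t - birth >= division_interval:
            birth += division_interval
            if i > 0:
                div_frames.append(i)
        lengths[i] = l0 * np.exp(rate * (t - birth))
    return lengths, np.array(sorted(set(div_frames)), dtype=int)


def generate_mother_machine_ensemble(config: GeneratorConfig, N: int,
                                     protocol: StressProtocol,
                                     params: CircuitParameters = None,
                                     variant: VariantSpec = VariantSpec(),
                                     seed: int = 0,
                                     final_window: float = 300.0
                                     ) -> Tuple[List[CellTrace], pd.DataFrame]:
    """N synthetic mother-machine cells under a stress protocol.

    Each cell is an independent SSA run of the circuit wrapped in a
    reporter trace, with an exponentially growing length channel (reset
    at division, rate set by a per-cell cell-cycle time drawn from
    N(division_time_mean, division_time_sd)), a width channel whose
    "sick" fraction widens after stress, and multiplicative measurement
    noise.  Returns the traces and a ground-truth table with columns
    ``cell_id, switch_time_sigv, switch_time_reporter, growth_rate,
    division_time, sick, prestress_reporter_mean``.

    ``switch_time_sigv`` is the first sustained crossing of free sigma-V
    above half its own final level; ``switch_time_reporter`` is the same
    crossing for the noise-free reporter, which lags it by the
    maturation and dilution response and is the level an estimator can
    recover from the measured fluorescence.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    params = params or CircuitParameters()
    net = build_network(params, variant)
    ens = simulate_ensemble(net, protocol, sample_interval=config.frame_interval,
                            N=N, base_seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x3A7A]))
    stress_time = _stress_time(protocol)
    traces, truth = [], []
    for i, tr in enumerate(ens):
        production = np.array([hill_production_rate(s, params) for s in tr.sigv])
        mature = _reporter_filter(production, config.frame_interval,
                                  config.maturation_time, params.k_deg)
        noise = rng.lognormal(0.0, config.measurement_noise, size=len(mature)) \
            if config.measurement_noise > 0 else np.ones_like(mature)
        division_time = max(rng.normal(config.division_time_mean,
                                       config.division_time_sd), 20.0)
        growth_rate = np.log(2.0) / division_time
        lengths, div_frames = _grow_lengths(tr.times, growth_rate, division_time,
                                            config.length_at_birth,
                                            t0=-float(rng.uniform(0, division_time)))
        sick = bool(rng.random() < config.sick_fraction)
        base_width = rng.normal(config.width_mean, config.width_sd)
        widths = base_width + rng.normal(0.0, config.width_frame_noise,
                                         size=len(tr.times))
        if sick:
            widths = np.where(tr.times >= stress_time,
                              widths * config.sick_width_factor, widths)
        trace = CellTrace(cell_id=i, times=tr.times.copy(),
                          fluorescence=mature * noise, stress_time=stress_time,
                          length=lengths, width=widths,
                          division_frames=div_frames)
        traces.append(trace)
        pre = tr.times < stress_time
        truth.append({
            "cell_id": i,
            "switch_time_sigv": _half_max_crossing(
                tr.times, tr.sigv.astype(float), stress_time, final_window),
            "switch_time_reporter": _half_max_crossing(
                tr.times, mature, stress_time, final_window),
            "growth_rate": growth_rate,
            "division_time": division_time,
            "sick": sick,
            "prestress_reporter_mean": float(mature[pre].mean()) if pre.any() else np.nan,
        })
    return traces, pd.DataFrame(truth)


def generate_parametric_traces(config: GeneratorConfig, N: int,
                               stress_time: float = 200.0,
                               duration: float = 1000.0, seed: int = 0,
                               base_level: float = 10.0, base_sd: float = 2.0,
                               plateau: float = 100.0, switch_mean: float = 300.0,
                               switch_sd: float = 120.0, rise_time: float = 30.0
                               ) -> Tuple[List[CellTrace], pd.DataFrame]:
    """Parametric sigmoid-step traces with a programmed correlation
    between pre-stress level and switch delay.

    Pre-stress levels and switch delays are drawn from a bivariate
    normal with correlation ``-prestress_correlation`` (higher pre-level
    means earlier switching, as in the experimental association).  Used
    to test the pre-stress/response-time statistics against programmed
    ground truth without running the circuit model.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9A7]))
    rho = -float(config.prestress_correlation)
    cov = [[1.0, rho], [rho, 1.0]]
    z = rng.multivariate_normal([0.0, 0.0], cov, size=N)
    pre_levels = base_level + base_sd * z[:, 0]
    delays = np.clip(switch_mean + switch_sd * z[:, 1], 2 * config.frame_interval,
                     duration - stress_time - 100.0)
    times = np.arange(0.0, duration + 1e-9, config.frame_interval)
    traces, truth = [], []
    for i in range(N):
        clean = pre_levels[i] + (plateau - pre_levels[i]) / (
            1.0 + np.exp(-(times - stress_time - delays[i]) / rise_time))
        noise = rng.lognormal(0.0, config.measurement_noise, size=len(times)) \
            if config.measurement_noise > 0 else 1.0
        traces.append(CellTrace(cell_id=i, times=times.copy(),
                                fluorescence=clean * noise,
                                stress_time=stress_time))
        truth.append({
            "cell_id": i,
            "switch_time_reporter": _half_max_crossing(times, clean, stress_time,
                                                       final_window=100.0),
            "prestress_level": pre_levels[i],
            "programmed_delay": delays[i],
        })
    return traces, pd.DataFrame(truth)


def generate_priming_lineages(config: GeneratorConfig, n_channels: int,
                              protocol: StressProtocol, lethal_time: float,
                              params: CircuitParameters = None,
                              seed: int = 0, n_slots: int = 6,
                              assay_duration: float = 280.0,
                              death_delay: float = 30.0
                              ) -> Tuple[LineageForest, pd.DataFrame]:
    """Channel lineage forests for the priming-survival experiment.

    Each channel holds ``n_slots`` stacked cells (slot 1 at the closed
    end); divisions insert the daughter below the mother and push the
    bottom cell out of the channel (annotated ``left_channel`` with an
    exit position near the open end).  At ``lethal_time`` every live
    cell draws survival from ``config.survival_rule`` evaluated on its
    founder lineage's noise-free reporter level at that moment
    (descendants share the founder's circuit trajectory - a clonal
    simplification); non-survivors die ``death_delay`` min later,
    survivors persist to the movie end at ``lethal_time +
    assay_duration``.  Ground truth records each scored cell's survival
    label and reporter level.
    """
    if lethal_time >= protocol.duration:
        raise ValueError("protocol must extend beyond the lethal phase onset "
                         "(no lethal phase marker inside the protocol)")
    params = params or CircuitParameters()
    net = build_network(params)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x51AB]))
    founder_seeds = child_seeds(seed, n_channels * n_slots)
    cell_len = 3.0
    channel_end = n_slots * cell_len
    movie_end = lethal_time + assay_duration

    cells: List[LineageCell] = []
    truth = []
    next_id = 0
    frame_times = np.arange(0.0, protocol.duration + 1e-9, config.frame_interval)

    for ch in range(n_channels):
        # founder circuit trajectories + noise-free reporter, one per slot
        reporters = []
        for s in range(n_slots):
            tr = simulate_ssa(net, protocol, sample_interval=config.frame_interval,
                              seed=int(founder_seeds[ch * n_slots + s]))
            production = np.array([hill_production_rate(x, params) for x in tr.sigv])
            reporters.append(_reporter_filter(production, config.frame_interval,
                                              config.maturation_time, params.k_deg))
        lethal_idx = int(np.searchsorted(frame_times, lethal_time - 1e-9))

        # event-driven division bookkeeping: active[slot] = [cell_id, birth, t_div, founder]
        active = {}
        for s in range(n_slots):
            t_div = rng.normal(config.division_time_mean, config.division_time_sd)
            active[s] = [next_id, 0.0, max(t_div, 20.0) * rng.uniform(0.2, 1.0), s]
            next_id += 1
        records = {active[s][0]: dict(parent=None, birth=0.0, slot=s, founder=s)
                   for s in active}

        def new_cell(slot, parent, t, founder):
            nonlocal next_id
            interval = max(rng.normal(config.division_time_mean,
                                      config.division_time_sd), 20.0)
            active[slot] = [next_id, t, t + interval, founder]
            records[next_id] = dict(parent=parent, birth=t, slot=slot,
                                    founder=founder)
            next_id += 1
            return next_id - 1

        while True:
            slot, (cid, birth, t_div, founder) = min(
                ((s, c) for s, c in active.items()), key=lambda kv: kv[1][2])
            if t_div >= lethal_time:
                break
            records[cid].update(end=t_div, cause="division",
                                pos=(slot + 0.5) * cell_len)
            if slot == n_slots - 1:
                # bottom cell divides: one daughter keeps the slot, the
                # other is pushed straight out of the channel
                new_cell(slot, cid, t_div, founder)
                records[next_id] = dict(parent=cid, birth=t_div, slot=slot,
                                        founder=founder, end=t_div + 1e-6,
                                        cause="left_channel",
                                        pos=channel_end + rng.normal(0.0, 0.5))
                next_id += 1
            else:
                # everything below the mother shifts down; the bottom
                # occupant leaves the channel
                ex_cid = active[n_slots - 1][0]
                records[ex_cid].update(end=t_div, cause="left_channel",
                                       pos=channel_end + rng.normal(0.0, 0.5))
                for s in range(n_slots - 1, slot + 1, -1):
                    active[s] = active[s - 1]
                    records[active[s][0]]["slot"] = s
                new_cell(slot, cid, t_div, founder)
                new_cell(slot + 1, cid, t_div, founder)

        # lethal stress: survival draw for every live cell
        for s, (cid, birth, t_div, founder) in active.items():
            level = float(reporters[founder][min(lethal_idx,
                                                 len(reporters[founder]) - 1)])
            p = config.survival_probability(level)
            survived = bool(rng.random() < p)
            rec = records[cid]
            rec.update(pos=(s + 0.5) * cell_len, rank=s)
            if survived:
                rec.update(end=movie_end, cause="movie_end")
            else:
                rec.update(end=min(lethal_time + death_delay, movie_end),
                           cause="death")
            truth.append({"cell_id": cid, "channel_id": ch, "slot": s,
                          "survived": survived, "reporter_at_lethal": level,
                          "survival_probability": p})

        for cid, rec in records.items():
            cells.append(LineageCell(
                cell_id=cid, channel_id=ch, parent_id=rec.get("parent"),
                birth_time=rec["birth"],
                end_time=rec.get("end", movie_end),
                end_cause=rec.get("cause", "movie_end"),
                position=rec.get("pos", (rec["slot"] + 0.5) * cell_len),
                rank_at=rec.get("rank", np.nan),
            ))

    forest = LineageForest(cells=cells, stress_time=lethal_time,
                           channel_length=channel_end)
    return forest, pd.DataFrame(truth)
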