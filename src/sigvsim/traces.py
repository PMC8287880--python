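"""Single-cell trace statistics for mother-machine-style data.

Implements the activation-time (half-maximum) rule and cumulative
activation curves, snapshot activation fractions (mean + k*sd rule),
fold change, coefficient of variation, instantaneous growth rates,
width-based filtering of overshooting (sick) cells, the pre-stress
level vs response-time association test, and survival counting in
priming experiments on lineage forests.

Conventions used throughout: sample standard deviations (N-1
denominator) for every mean + k*sd threshold; censored cells (those
that never cross their activation threshold within the observation
window) are retained and count in denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import ks_2samp

__all__ = [
    "CellTrace",
    "ActivationSummary",
    "LineageCell",
    "LineageForest",
    "activation_time",
    "summarize_activation",
    "cumulative_activation_curve",
    "fraction_activated_snapshot",
    "fold_change",
    "coefficient_of_variation",
    "instantaneous_growth_rate",
    "filter_overshooting",
    "compare_activation_by_prestress",
    "survival_fraction",
]


@dataclass
class CellTrace:
    """One cell's uniformly sampled time series.

    ``fluorescence`` is the reporter readout in arbitrary units (for
    model traces it may hold free sigma-V copy numbers directly);
    ``stress_time`` is the time stress was applied, in the same clock as
    ``times``.  ``division_frames`` lists the indices of frames that
    start a new cell cycle.
    """

    cell_id: int
    times: np.ndarray
    fluorescence: np.ndarray
    stress_time: float
    length: Optional[np.ndarray] = None
    width: Optional[np.ndarray] = None
    division_frames: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("trace needs at least two frames")
        dt = np.diff(self.times)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("frame times must be strictly increasing and uniform")
        for name in ("fluorescence", "length", "width"):
            arr = getattr(self, name)
            if arr is not None and len(np.asarray(arr)) != len(self.times):
                raise ValueError(f"{name} length does not match times")

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    def prestress_mask(self) -> np.ndarray:
        return self.times < self.stress_time


@dataclass(frozen=True)
class ActivationSummary:
    """Per-cell activation-time entry (half-maximum rule)."""

    cell_id: int
    activation_time: Optional[float]  # min since stress; None if censored
    final_level: float
    half_max: float
    censored: bool


def activation_time(trace: CellTrace, final_window: float = 100.0) -> ActivationSummary:
    """Half-maximum activation time of one trace.

    The final level is the mean fluorescence over the trailing
    ``final_window`` minutes; the activation time is the first
    post-stress frame at or above half of that level, measured from
    stress addition.  The cell is censored when it never crosses, or
    when the final level does not exceed the pre-stress mean
    (non-responder).  Traces with no pre-stress frames skip the
    non-responder check (used when re-analysing from a restress onset).
    """
    t, f = trace.times, trace.fluorescence
    if t[-1] < trace.stress_time:
        raise ValueError("trace ends before stress addition")
    tail = t >= t[-1] - final_window + 1e-9
    if not tail.any():
        tail = np.zeros_like(t, dtype=bool)
        tail[-1] = True
    final_level = float(f[tail].mean())
    half = final_level / 2.0
    pre = trace.prestress_mask()
    non_responder = pre.any() and final_level <= float(f[pre].mean())
    post = t >= trace.stress_time
    crossed = post & (f >= half) & (f > 0)
    if non_responder or not crossed.any():
        return ActivationSummary(trace.cell_id, None, final_level, half, True)
    t_act = float(t[crossed][0] - trace.stress_time)
    return ActivationSummary(trace.cell_id, t_act, final_level, half, False)


def summarize_activation(traces: Iterable[CellTrace],
                         final_window: float = 100.0) -> List[ActivationSummary]:
    return [activation_time(tr, final_window) for tr in traces]


def cumulative_activation_curve(summaries: Sequence[ActivationSummary],
                                grid: np.ndarray) -> np.ndarray:
    """Fraction of all cells activated by each grid time (censored cells
    stay in the denominator), measured from stress addition."""
    if len(summaries) == 0:
        raise ValueError("no activation summaries given")
    grid = np.asarray(grid, dtype=float)
    times = np.array([s.activation_time for s in summaries if not s.censored])
    n = len(summaries)
    return np.array([(times <= g).sum() / n for g in grid])


def fraction_activated_snapshot(pre_values, post_values, k_sd: float = 6.0) -> float:
    """Snapshot activation fraction: share of post-stress values strictly
    above mean(pre) + k_sd * sd(pre)."""
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.size < 2:
        raise ValueError("need at least 2 pre-stress values to form a threshold")
    threshold = pre.mean() + k_sd * pre.std(ddof=1)
    return float((post > threshold).sum() / post.size)


def fold_change(trace: CellTrace, pre_window: float, post_window: float) -> Optional[float]:
    """Induction fold change: mean over the trailing ``post_window``
    divided by the mean over the ``pre_window`` before stress.

    Returns None (undefined, no pseudo-counts) when the pre-stress mean
    is exactly zero.
    """
    t, f = trace.times, trace.fluorescence
    pre = (t < trace.stress_time) & (t >= trace.stress_time - pre_window)
    post = t >= t[-1] - post_window + 1e-9
    if not pre.any() or not post.any():
        raise ValueError("pre/post windows fall outside the trace")
    pre_mean = f[pre].mean()
    if pre_mean == 0:
        return None
    return float(f[post].mean() / pre_mean)


def coefficient_of_variation(values) -> float:
    """Sample CV: sd (N-1 denominator) divided by the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    m = x.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(x.std(ddof=1) / m)


def instantaneous_growth_rate(trace: CellTrace) -> pd.DataFrame:
    """Per-frame-pair elongation rates (log len_{i+1} - log len_i) / dt.

    Rates are only computed within one cell cycle: frame pairs spanning
    a marked division are skipped.  Returns a frame-indexed table with
    columns ``frame`` (index i of the pair) and ``growth_rate``.
    """
    if trace.length is None:
        raise ValueError("trace has no length channel")
    lengths = np.asarray(trace.length, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("cell lengths must be positive")
    div = set(np.asarray(trace.division_frames, dtype=int).tolist()
              if trace.division_frames is not None else [])
    dt = trace.frame_interval
    rows = []
    for i in range(len(lengths) - 1):
        if (i + 1) in div:  # frame i+1 starts a new cycle: pair spans a division
            continue
        rows.append((i, (np.log(lengths[i + 1]) - np.log(lengths[i])) / dt))
    return pd.DataFrame(rows, columns=["frame", "growth_rate"])


def filter_overshooting(traces: Sequence[CellTrace], k_sd: float = 6.0,
                        smooth_sigma: float = 2.0) -> Tuple[List[CellTrace], List[CellTrace]]:
    """Remove cells whose (smoothed) maximum width exceeds the pooled
    pre-stress mean width + k_sd * sd.

    Width traces are smoothed with a Gaussian kernel (``smooth_sigma``
    in frames) before taking the maximum.  Returns (kept, removed).
    """
    if any(tr.width is None for tr in traces):
        raise ValueError("all traces need a width channel")
    pooled = np.concatenate([
        np.asarray(tr.width, dtype=float)[tr.prestress_mask()] for tr in traces
    ])
    if pooled.size < 2:
        raise ValueError("no pre-stress frames to form the width threshold")
    threshold = pooled.mean() + k_sd * pooled.std(ddof=1)
    kept, removed = [], []
    for tr in traces:
        smooth = gaussian_filter1d(np.asarray(tr.width, dtype=float), smooth_sigma)
        (removed if smooth.max() > threshold else kept).append(tr)
    return kept, removed


@dataclass(frozen=True)
class PrestressComparison:
    n_high: int
    n_low: int
    ks_statistic: float
    p_value: float
    reject_null: bool       # p < alpha: activation times differ between groups
    mean_time_high: float
    mean_time_low: float
    computable: bool = True


def compare_activation_by_prestress(traces: Sequence[CellTrace],
                                    summaries: Sequence[ActivationSummary],
                                    k_sd: float = 1.0,
                                    alpha: float = 0.05) -> PrestressComparison:
    """Split cells by pre-stress level (mean + k_sd*sd of per-cell
    pre-stress means) and compare activation-time distributions with a
    two-sided two-sample Kolmogorov--Smirnov test.

    Censored cells are excluded from the KS comparison.
    """
    pre_means = np.array([
        np.asarray(tr.fluorescence)[tr.prestress_mask()].mean() for tr in traces
    ])
    threshold = pre_means.mean() + k_sd * pre_means.std(ddof=1)
    high_ids = {tr.cell_id for tr, m in zip(traces, pre_means) if m > threshold}
    t_high = [s.activation_time for s in summaries
              if not s.censored and s.cell_id in high_ids]
    t_low = [s.activation_time for s in summaries
             if not s.censored and s.cell_id not in high_ids]
    if not t_high or not t_low:
        return PrestressComparison(len(t_high), len(t_low), np.nan, np.nan,
                                   False, np.nan, np.nan, computable=False)
    res = ks_2samp(t_high, t_low, alternative="two-sided", method="auto")
    return PrestressComparison(
        n_high=len(t_high), n_low=len(t_low),
        ks_statistic=float(res.statistic), p_value=float(res.pvalue),
        reject_null=bool(res.pvalue < alpha),
        mean_time_high=float(np.mean(t_high)), mean_time_low=float(np.mean(t_low)),
    )


@dataclass
class LineageCell:
    """One cell in a mother-machine channel lineage tree."""

    cell_id: int
    channel_id: int
    parent_id: Optional[int]
    birth_time: float
    end_time: float
    end_cause: str  # division | death | left_channel | movie_end
    position: float = np.nan      # position at its last recorded frame (um from closed end)
    rank_at: float = np.nan       # position rank at the reference (assay start) frame

    def alive_at(self, t: float) -> bool:
        return self.birth_time <= t < self.end_time or (
            self.end_time >= t and self.birth_time <= t and self.end_cause == "movie_end"
        )


_END_CAUSES = {"division", "death", "left_channel", "movie_end"}


@dataclass
class LineageForest:
    """Channel-wise lineage trees with division/death/washout annotations."""

    cells: List[LineageCell]
    stress_time: float            # lethal-stress addition time
    channel_length: Optional[float] = None

    def __post_init__(self) -> None:
        ids = {c.cell_id for c in self.cells}
        for c in self.cells:
            if c.end_cause not in _END_CAUSES:
                raise ValueError(f"unknown end cause {c.end_cause!r}")
            if c.parent_id is not None and c.parent_id not in ids:
                raise ValueError(f"cell {c.cell_id} has unknown parent {c.parent_id}")

    def channels(self) -> List[int]:
        return sorted({c.channel_id for c in self.cells})

    def children(self, cell_id: int) -> List[LineageCell]:
        return [c for c in self.cells if c.parent_id == cell_id]

    def lineage_survives(self, cell: LineageCell, t_end: float) -> bool:
        """True if the cell or any descendant is alive at ``t_end``."""
        if cell.end_time >= t_end and cell.end_cause in ("movie_end",):
            return True
        if cell.end_cause == "division":
            return any(self.lineage_survives(ch, t_end) for ch in self.children(cell.cell_id))
        return False


def _top_cells(forest: LineageForest, channel: int, t: float, k: int) -> List[LineageCell]:
    alive = [c for c in forest.cells
             if c.channel_id == channel and c.birth_time <= t < c.end_time]
    alive.sort(key=lambda c: c.rank_at if np.isfinite(c.rank_at) else c.position)
    return alive[:k] if len(alive) >= k else []


def survival_fraction(forest: LineageForest, method: str = "top3_longest",
                      assay_start: Optional[float] = None,
                      assay_end: Optional[float] = None,
                      k_sd: float = 6.0) -> Tuple[float, float]:
    """Surviving fraction after lethal stress, by one of two counting rules.

    ``top3_longest``: only the top three cells (closest to the closed
    channel end) at assay start are scored; each contributes 1 when any
    of its descendant lineages survives to assay end (the longest
    lineage counted once, so divisions cannot inflate the count).
    Channels with fewer than three cells at assay start are skipped.

    ``channel_end_exclusion``: all cells present at assay start are
    scored, but cells whose last recorded position lies within ``k_sd``
    standard deviations of the estimated open channel end are excluded
    as washed out rather than dead.  The channel end is estimated from
    the last-observed positions of cells that left the channel before
    the stress.

    Returns ``(fraction, sd)`` where sd is the standard deviation of
    per-channel fractions (0 when only one channel contributes).
    """
    t0 = forest.stress_time if assay_start is None else assay_start
    t1 = max(c.end_time for c in forest.cells) if assay_end is None else assay_end
    per_channel: List[Tuple[int, int]] = []  # (survivors, scored)

    if method == "top3_longest":
        for ch in forest.channels():
            top = _top_cells(forest, ch, t0, 3)
            if not top:
                continue
            surv = sum(1 for c in top if forest.lineage_survives(c, t1))
            per_channel.append((surv, 3))
    elif method == "channel_end_exclusion":
        exits = [c.position for c in forest.cells
                 if c.end_cause == "left_channel" and c.end_time <= t0
                 and np.isfinite(c.position)]
        if len(exits) >= 2:
            end_mean = float(np.mean(exits))
            end_sd = float(np.std(exits, ddof=1))
        elif forest.channel_length is not None:
            end_mean, end_sd = float(forest.channel_length), 0.0
        else:
            raise ValueError("cannot estimate channel end: no pre-stress exits "
                             "and no channel_length given")
        for ch in forest.channels():
            alive = [c for c in forest.cells
                     if c.channel_id == ch and c.birth_time <= t0 < c.end_time]
            surv = scored = 0
            for c in alive:
                last = _last_descendant_position(forest, c)
                if np.isfinite(last) and abs(last - end_mean) <= k_sd * end_sd:
                    continue  # assumed washed out, excluded
                scored += 1
                if forest.lineage_survives(c, t1):
                    surv += 1
            if scored:
                per_channel.append((surv, scored))
    else:
        raise ValueError(f"unknown method {method!r}")

    if not per_channel:
        raise ValueError("no channels could be scored")
    total_surv = sum(s for s, _ in per_channel)
    total_scored = sum(n for _, n in per_channel)
    fracs = np.array([s / n for s, n in per_channel])
    sd = float(fracs.std(ddof=1)) if len(fracs) > 1 else 0.0
    return total_surv / total_scored, sd


def _last_descendant_position(forest: LineageForest, cell: LineageCell) -> float:
    """Position of the last observation along the cell's own branch
    (follows the cell itself; divisions keep the mother's record)."""
    return cell.position
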