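"""Piecewise-constant lysozyme stress protocols."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

__all__ = ["StressProtocol", "step_protocol", "memory_protocol", "constant_protocol"]


@dataclass(frozen=True)
class StressProtocol:
    """Lysozyme input L(t), constant within each segment.

    ``segments`` is an ordered tuple of ``(start_time_min, L)`` pairs
    with strictly increasing start times, the first at 0; ``duration``
    is the total simulated time in minutes.
    """

    segments: Tuple[Tuple[float, float], ...]
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration!r}")
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        starts = [s for s, _ in self.segments]
        if starts[0] != 0:
            raise ValueError("first segment must start at time 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError(f"segment start times must strictly increase: {starts}")
        if any(L < 0 for _, L in self.segments):
            raise ValueError("lysozyme levels must be >= 0")

    def level_at(self, t: float) -> float:
        """L at time t (right-continuous)."""
        L = self.segments[0][1]
        for start, level in self.segments:
            if t >= start:
                L = level
            else:
                break
        return L

    def segment_bounds(self, t_end: float | None = None):
        """List of (t0, t1, L) covering [0, t_end] (default: duration)."""
        if t_end is None:
            t_end = self.duration
        starts = [s for s, _ in self.segments] + [t_end]
        return [
            (starts[i], starts[i + 1], self.segments[i][1])
            for i in range(len(self.segments))
            if starts[i] < t_end
        ]

    def arrays(self):
        """(segment start times, segment levels) as float arrays."""
        starts = np.array([s for s, _ in self.segments], dtype=np.float64)
        levels = np.array([L for _, L in self.segments], dtype=np.float64)
        return starts, levels

    def as_dict(self) -> dict:
        return {"segments": [list(s) for s in self.segments],
                "duration": self.duration}

    @classmethod
    def from_dict(cls, d: dict) -> "StressProtocol":
        return cls(segments=tuple(tuple(s) for s in d["segments"]),
                   duration=float(d["duration"]))


def constant_protocol(L: float, duration: float) -> StressProtocol:
    return StressProtocol(segments=((0.0, float(L)),), duration=float(duration))


def step_protocol(t_on: float, L_level: float, duration: float) -> StressProtocol:
    """Stress off on [0, t_on), then L = ``L_level`` until ``duration``."""
    if not 0 <= t_on < duration:
        raise ValueError(f"need 0 <= t_on < duration, got t_on={t_on}, duration={duration}")
    if t_on == 0:
        return constant_protocol(L_level, duration)
    return StressProtocol(segments=((0.0, 0.0), (float(t_on), float(L_level))),
                          duration=float(duration))


def memory_protocol(t_on: float, t_off: float, gap: float, L_level: float,
                    post_duration: float) -> StressProtocol:
    """Stress, break, restress: L on [t_on, t_off), off for ``gap`` min,
    then back on for ``post_duration`` min."""
    if gap < 0:
        raise ValueError(f"gap must be >= 0, got {gap!r}")
    if not 0 <= t_on < t_off:
        raise ValueError(f"need 0 <= t_on < t_off, got {t_on}, {t_off}")
    duration = t_off + gap + post_duration
    segs = [(float(t_on), float(L_level))] if t_on == 0 else \
        [(0.0, 0.0), (float(t_on), float(L_level))]
    if gap > 0:
        segs += [(float(t_off), 0.0), (float(t_off + gap), float(L_level))]
    return StressProtocol(segments=tuple(segs), duration=float(duration))
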