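"""Clean-segment selection for fixation recordings.

Fixation analysis uses only stretches of recording free of saccades and
other fast events.  Velocity is computed with a six-point central
difference, and 2048-sample segments containing any velocity above
25 deg/s are rejected.  The search is a left-to-right greedy scan that
accepts the earliest feasible window and jumps past it, which yields the
maximum number of non-overlapping clean segments (earliest-deadline
argument for fixed-length intervals).  Accepted segments are split into
eight contiguous 256-sample blocks for spectral averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace import GazeTrace

__all__ = [
    "SegmentSet",
    "sixpoint_velocity",
    "find_clean_segments",
    "split_blocks",
]


@dataclass
class SegmentSet:
    """Accepted segment start indices over a source trace."""

    source: GazeTrace
    starts: np.ndarray
    seg_len: int
    block_len: int = 256

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=int)

    @property
    def n_segments(self) -> int:
        return len(self.starts)

    def segments(self, channel: str = "x"):
        """Accepted segments as a list of 1-D sample arrays."""
        sig = getattr(self.source, channel)
        return [sig[s:s + self.seg_len] for s in self.starts]

    def blocks(self, channel: str = "x", block_len: int | None = None):
        """All blocks from all accepted segments, in order."""
        block_len = block_len or self.block_len
        out = []
        for seg in self.segments(channel):
            out.extend(split_blocks(seg, block_len))
        return out

    def block_bounds(self, block_len: int | None = None):
        """(start, stop) sample indices of every block in the source trace."""
        block_len = block_len or self.block_len
        per_seg = self.seg_len // block_len
        bounds = []
        for s in self.starts:
            for k in range(per_seg):
                a = int(s + k * block_len)
                bounds.append((a, a + block_len))
        return bounds

    def to_csv(self, path) -> None:
        pd.DataFrame({"segment_index": np.arange(self.n_segments),
                      "start_sample": self.starts}).to_csv(path, index=False)


def sixpoint_velocity(trace: GazeTrace, channel: str = "x") -> np.ndarray:
    """Six-point central-difference velocity, deg/s.

    v[t] = (x[t+3] - x[t-3]) / (6/fs).  The difference spans six sample
    intervals, so the denominator is the six-sample span (the screening
    threshold is only meaningful in deg/s with the span-correct
    denominator).  The first and last three samples are NaN.
    """
    x = getattr(trace, channel)
    if x is None:
        raise ValueError(f"trace has no {channel!r} channel")
    if len(x) < 7:
        raise ValueError("trace must have at least 7 samples")
    v = np.full(len(x), np.nan)
    v[3:-3] = (x[6:] - x[:-6]) * trace.fs_hz / 6.0
    return v


def find_clean_segments(trace: GazeTrace, seg_len: int = 2048,
                        vmax: float = 25.0, seg_set_block_len: int = 256,
                        channel: str = "x") -> SegmentSet:
    """Maximum number of non-overlapping clean ``seg_len`` windows.

    A window is clean when every *defined* |six-point velocity| sample
    inside it is at most ``vmax`` deg/s.  With ``channel='both'`` the
    screen uses the vector magnitude of horizontal and vertical
    velocity.  An empty result is valid.
    """
    if channel == "both":
        vx = sixpoint_velocity(trace, "x")
        vy = sixpoint_velocity(trace, "y")
        speed = np.hypot(vx, vy)
    else:
        speed = np.abs(sixpoint_velocity(trace, channel))
    bad = speed > vmax  # NaN compares False: undefined samples never block
    n = len(bad)
    bad_idx = np.flatnonzero(bad)
    starts = []
    i = 0
    while i + seg_len <= n:
        j = np.searchsorted(bad_idx, i)
        if j < len(bad_idx) and bad_idx[j] < i + seg_len:
            i = int(bad_idx[j]) + 1  # earliest start that excludes the violator
        else:
            starts.append(i)
            i += seg_len
    return SegmentSet(source=trace, starts=np.array(starts, dtype=int),
                      seg_len=seg_len, block_len=seg_set_block_len)


def split_blocks(seg: np.ndarray, block_len: int = 256):
    """Contiguous, non-overlapping, order-preserving blocks of a segment."""
    seg = np.asarray(seg)
    if block_len <= 0 or len(seg) % block_len:
        raise ValueError(
            f"segment length {len(seg)} not divisible by block length {block_len}")
    return list(seg.reshape(-1, block_len))
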