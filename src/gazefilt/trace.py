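"""Uniformly sampled gaze-position time series.

The :class:`GazeTrace` is the signal container used throughout the
package: gaze position in degrees of visual angle (dva), one sample per
1/fs seconds, horizontal channel mandatory and vertical optional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GazeTrace"]

CSV_COLUMNS = ("t_s", "x_dva", "y_dva")


@dataclass
class GazeTrace:
    """Uniformly sampled gaze positions in degrees of visual angle.

    Parameters
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing with step ``1/fs_hz``.
    x : ndarray
        Horizontal gaze position (dva).
    fs_hz : float
        Sampling rate in Hz.
    y : ndarray, optional
        Vertical gaze position (dva).
    """

    t: np.ndarray
    x: np.ndarray
    fs_hz: float
    y: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs_hz}")
        if self.t.shape != self.x.shape:
            raise ValueError("t and x must have equal length")
        if self.y is not None and self.y.shape != self.x.shape:
            raise ValueError("y must have the same length as x")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("sample times must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.fs_hz, rtol=1e-6, atol=1e-9):
                raise ValueError("sample times must be uniform with step 1/fs_hz")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        return len(self.x) / self.fs_hz

    @classmethod
    def from_samples(cls, x: np.ndarray, fs_hz: float,
                     y: np.ndarray | None = None, t0: float = 0.0) -> "GazeTrace":
        """Build a trace from samples alone, synthesising the time axis."""
        x = np.asarray(x, dtype=float)
        t = t0 + np.arange(len(x)) / fs_hz
        return cls(t=t, x=x, y=y, fs_hz=fs_hz)

    def with_x(self, x: np.ndarray) -> "GazeTrace":
        """Copy of this trace with the horizontal channel replaced."""
        return GazeTrace(t=self.t.copy(), x=np.asarray(x, dtype=float),
                         y=None if self.y is None else self.y.copy(),
                         fs_hz=self.fs_hz)

    def to_csv(self, path) -> None:
        """Write the trace as ``t_s,x_dva[,y_dva]`` CSV, one row per sample."""
        data = {"t_s": self.t, "x_dva": self.x}
        if self.y is not None:
            data["y_dva"] = self.y
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path, fs_hz: float | None = None) -> "GazeTrace":
        """Read a trace written by :meth:`to_csv`.

        The sampling rate is inferred from the time column unless given.
        """
        df = pd.read_csv(path)
        for col in ("t_s", "x_dva"):
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        t = df["t_s"].to_numpy(float)
        if fs_hz is None:
            if len(t) < 2:
                raise ValueError("cannot infer sampling rate from a single sample")
            fs_hz = 1.0 / float(np.median(np.diff(t)))
            # undo round-off from the text representation of sample times
            if abs(fs_hz - round(fs_hz)) < 1e-4 * fs_hz:
                fs_hz = float(round(fs_hz))
        y = df["y_dva"].to_numpy(float) if "y_dva" in df.columns else None
        return cls(t=t, x=df["x_dva"].to_numpy(float), y=y, fs_hz=fs_hz)
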