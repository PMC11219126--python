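"""Design and application of the study's low-pass filters.

Three filter families are supported, all aimed at a final -3 dB point
near 75 Hz at a 1000 Hz sampling rate:

* Savitzky-Golay smoothing (window 23, polynomial order 5), applied as a
  single centred convolution (the symmetric kernel is inherently
  zero-phase);
* a 7th-order Butterworth low-pass with 81 Hz design cutoff, applied
  forward-backward (zero-phase, which squares the magnitude response);
* an 80-tap windowed-sinc FIR low-pass with 84 Hz design cutoff, also
  applied forward-backward.

A Bellanger-style estimate of the FIR tap count from ripple, stop-band
suppression and transition width is provided, along with a unit-circle
stability check and plain-text coefficient round-tripping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import signal

from .trace import GazeTrace

__all__ = [
    "LowpassSpec",
    "DesignedFilter",
    "TapEstimateSpec",
    "design_savgol",
    "design_butterworth_lowpass",
    "design_fir_lowpass",
    "estimate_fir_taps",
    "apply_filter",
    "is_stable",
    "save_filter",
    "load_filter",
    "table1_filters",
]

FAMILIES = ("savitzky_golay", "butterworth", "fir_window")


@dataclass(frozen=True)
class LowpassSpec:
    """Design parameters of one low-pass filter."""

    family: str
    fs_hz: float
    order: int | None = None          # polynomial order (SG) / filter order (IIR)
    window_length: int | None = None  # SG window in samples (odd)
    num_taps: int | None = None       # FIR coefficient count
    cutoff_hz: float | None = None    # nominal -3 dB design cutoff (single pass)
    zero_phase: bool = False
    fir_window: str = "hamming"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown filter family {self.family!r}")
        if self.cutoff_hz is not None and not (0 < self.cutoff_hz < self.fs_hz / 2):
            raise ValueError("cutoff_hz must lie strictly below the Nyquist rate")
        if self.family == "savitzky_golay":
            if self.window_length is None or self.order is None:
                raise ValueError("SG spec needs window_length and order")
            if self.window_length % 2 == 0:
                raise ValueError("SG window_length must be odd")
            if self.order >= self.window_length:
                raise ValueError("SG order must be smaller than window_length")
        if self.family == "fir_window" and (self.num_taps is None or self.num_taps < 2):
            raise ValueError("FIR design needs num_taps >= 2")


@dataclass
class DesignedFilter:
    """Coefficient sets plus the spec that produced them.

    ``a`` is ``[1.0]`` for the FIR and Savitzky-Golay kernels.
    """

    b: np.ndarray
    a: np.ndarray
    spec: LowpassSpec

    def __post_init__(self) -> None:
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        if self.a[0] != 1.0:
            self.b = self.b / self.a[0]
            self.a = self.a / self.a[0]

    @property
    def is_fir(self) -> bool:
        return len(self.a) == 1

    @property
    def passes(self) -> int:
        """Number of filter passes the design calls for (2 if zero-phase)."""
        return 2 if self.spec.zero_phase else 1


@dataclass(frozen=True)
class TapEstimateSpec:
    """Inputs to the FIR tap-count estimate.

    delta1 is the passband ripple and delta2 the stop-band suppression,
    both linear; transition_hz is the transition width in Hz.
    """

    delta1: float
    delta2: float
    fs_hz: float
    transition_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.delta1 < 1 and 0 < self.delta2 < 1):
            raise ValueError("delta1 and delta2 must lie in (0, 1)")
        if self.transition_hz <= 0:
            raise ValueError("transition_hz must be positive")


def design_savgol(window_length: int, polyorder: int, fs_hz: float) -> DesignedFilter:
    """Symmetric Savitzky-Golay smoothing kernel.

    The output at each sample equals the centre value of the
    least-squares polynomial of degree ``polyorder`` fitted over the
    surrounding ``window_length`` samples.
    """
    spec = LowpassSpec(family="savitzky_golay", fs_hz=fs_hz,
                       window_length=window_length, order=polyorder)
    b = signal.savgol_coeffs(window_length, polyorder)
    return DesignedFilter(b=b, a=np.array([1.0]), spec=spec)


def design_butterworth_lowpass(order: int, cutoff_hz: float, fs_hz: float,
                               zero_phase: bool = True) -> DesignedFilter:
    """Digital Butterworth low-pass (analog prototype + bilinear transform)."""
    spec = LowpassSpec(family="butterworth", fs_hz=fs_hz, order=order,
                       cutoff_hz=cutoff_hz, zero_phase=zero_phase)
    b, a = signal.butter(order, cutoff_hz, btype="lowpass", fs=fs_hz)
    return DesignedFilter(b=b, a=a, spec=spec)


def design_fir_lowpass(num_taps: int, cutoff_hz: float, fs_hz: float,
                       zero_phase: bool = True,
                       window: str = "hamming") -> DesignedFilter:
    """Windowed-sinc linear-phase FIR low-pass with unit DC gain."""
    spec = LowpassSpec(family="fir_window", fs_hz=fs_hz, num_taps=num_taps,
                       cutoff_hz=cutoff_hz, zero_phase=zero_phase,
                       fir_window=window)
    b = signal.firwin(num_taps, cutoff_hz, fs=fs_hz, window=window)
    b = b / b.sum()
    return DesignedFilter(b=b, a=np.array([1.0]), spec=spec)


def estimate_fir_taps(spec: TapEstimateSpec) -> int:
    """Estimate the FIR length N ~ (2/3)*log10(1/(10*d1*d2))*(fs/df).

    Returns the ceiling of the estimate, with a floor of 2 taps (the
    shortest meaningful FIR).
    """
    n = (2.0 / 3.0) * np.log10(1.0 / (10.0 * spec.delta1 * spec.delta2)) \
        * (spec.fs_hz / spec.transition_hz)
    return max(2, int(np.ceil(n)))


def _centered_convolution(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Centred FIR smoothing with odd-length kernel and reflected edges."""
    half = (len(kernel) - 1) // 2
    padded = np.pad(x, half, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def _filter_channel(filt: DesignedFilter, x: np.ndarray, mode: str) -> np.ndarray:
    if filt.spec.family == "savitzky_golay":
        # The symmetric kernel is inherently zero-phase; a second pass
        # squares its magnitude response.
        y = _centered_convolution(x, filt.b)
        if mode == "zero_phase":
            y = _centered_convolution(y, filt.b)
        return y
    if mode == "single_pass":
        return signal.lfilter(filt.b, filt.a, x)
    if mode == "zero_phase":
        padlen = 3 * max(len(filt.b), len(filt.a))
        if len(x) <= padlen:
            raise ValueError(
                f"trace of {len(x)} samples too short for zero-phase "
                f"filtering (needs > {padlen})")
        return signal.filtfilt(filt.b, filt.a, x, padtype="odd", padlen=padlen)
    raise ValueError(f"unknown mode {mode!r}")


def apply_filter(filt: DesignedFilter, trace: GazeTrace,
                 mode: str | None = None) -> GazeTrace:
    """Filter every channel of a trace.

    ``zero_phase`` runs the signal forward and backward through the
    filter (odd-reflection padding), which removes phase and delay and
    squares the magnitude response.  Savitzky-Golay kernels are applied
    as centred convolutions and are zero-phase in either mode.  With
    ``mode=None`` the mode the filter was designed for is used
    (``spec.zero_phase``).
    """
    if mode is None:
        mode = "zero_phase" if filt.spec.zero_phase else "single_pass"
    x = _filter_channel(filt, trace.x, mode)
    y = None if trace.y is None else _filter_channel(filt, trace.y, mode)
    return GazeTrace(t=trace.t.copy(), x=x, y=y, fs_hz=trace.fs_hz)


def is_stable(filt: DesignedFilter) -> bool:
    """Unit-circle test: all feedback-polynomial roots strictly inside."""
    if filt.is_fir:
        return True
    roots = np.roots(filt.a)
    return bool(np.all(np.abs(roots) < 1.0))


# -- coefficient files -------------------------------------------------------

def save_filter(filt: DesignedFilter, path) -> None:
    """Write coefficients as two-column text plus a JSON metadata sidecar."""
    path = Path(path)
    n = max(len(filt.b), len(filt.a))
    b = np.zeros(n)
    a = np.zeros(n)
    b[:len(filt.b)] = filt.b
    a[:len(filt.a)] = filt.a
    with open(path, "w") as fh:
        fh.write("# b a\n")
        for bi, ai in zip(b, a):
            fh.write(f"{bi:.6e} {ai:.6e}\n")
    meta = asdict(filt.spec)
    meta["n_b"] = len(filt.b)
    meta["n_a"] = len(filt.a)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_filter(path) -> DesignedFilter:
    """Read a filter written by :func:`save_filter`."""
    path = Path(path)
    data = np.loadtxt(path, comments="#")
    data = np.atleast_2d(data)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        meta = json.load(fh)
    n_b = meta.pop("n_b")
    n_a = meta.pop("n_a")
    spec = LowpassSpec(**meta)
    return DesignedFilter(b=data[:n_b, 0], a=data[:n_a, 1], spec=spec)


def table1_filters(fs_hz: float = 1000.0) -> dict[str, DesignedFilter]:
    """The study's reference filter triple (SG 23/5, Butterworth 7/81 Hz
    zero-phase, FIR 80 taps/84 Hz zero-phase)."""
    return {
        "sg": design_savgol(23, 5, fs_hz),
        "iir": design_butterworth_lowpass(7, 81.0, fs_hz, zero_phase=True),
        "fir": design_fir_lowpass(80, 84.0, fs_hz, zero_phase=True),
    }
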