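"""Block-averaged amplitude spectra of fixation data.

Each 256-sample block is detrended with a 2nd-order polynomial, tapered
with a (periodic) Hann window and Fourier transformed; the magnitude
spectra of all blocks are then averaged bin-wise.  Averaging magnitudes
rather than complex FFT values keeps phase-incoherent power from
cancelling across blocks.  At 1000 Hz a 256-sample block yields 128
non-negative-frequency bins below Nyquist with a resolution of
1000/256 = 3.90625 Hz.

Spectra are scaled by 2/sum(window) so a unit-amplitude sinusoid that
falls exactly on a bin reports a magnitude of ~1 dva.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import get_window

__all__ = [
    "SpectrumSet",
    "detrend_poly2",
    "block_amplitude_spectrum",
    "average_spectra",
    "frequency_resolution_hz",
    "n_discriminable_frequencies",
]


@dataclass
class SpectrumSet:
    """Per-block magnitude spectra on a common frequency grid."""

    freq_hz: np.ndarray          # bin centres, 0 .. fs/2 (exclusive)
    magnitudes: np.ndarray       # (n_blocks, n_bins) per-block magnitudes
    mean_magnitude: np.ndarray   # bin-wise arithmetic mean across blocks
    fs_hz: float
    block_len: int

    @property
    def n_blocks(self) -> int:
        return self.magnitudes.shape[0]

    @property
    def resolution_hz(self) -> float:
        return self.fs_hz / self.block_len

    def to_csv(self, path) -> None:
        """CSV with freq_hz first, one column per block, mean last."""
        cols = {"freq_hz": self.freq_hz}
        for i in range(self.n_blocks):
            cols[f"block_{i}"] = self.magnitudes[i]
        cols["mean"] = self.mean_magnitude
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")


def frequency_resolution_hz(fs_hz: float, block_len: int) -> float:
    """FFT bin spacing: sampling rate divided by block length."""
    return fs_hz / block_len


def n_discriminable_frequencies(block_len: int) -> int:
    """Number of distinct non-negative-frequency bins below Nyquist."""
    return block_len // 2


def detrend_poly2(block: np.ndarray) -> np.ndarray:
    """Residuals of a least-squares quadratic fit over the block.

    The residuals have zero mean (the fit includes a constant term).
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 1 or len(block) < 3:
        raise ValueError("block must be 1-D with at least 3 samples")
    t = np.arange(len(block), dtype=float)
    t = (t - t.mean()) / t.std()  # conditioning only; same fit space
    design = np.column_stack([np.ones_like(t), t, t * t])
    coef, *_ = np.linalg.lstsq(design, block, rcond=None)
    return block - design @ coef


def block_amplitude_spectrum(block: np.ndarray, fs_hz: float,
                             detrend: bool = True) -> np.ndarray:
    """Magnitude spectrum of one detrended, Hann-windowed block.

    Returns the ``len(block)//2`` bins from 0 Hz up to (excluding) the
    Nyquist frequency.
    """
    block = np.asarray(block, dtype=float)
    n = len(block)
    if n < 8 or n % 2:
        raise ValueError("block length must be even and >= 8 samples")
    if detrend:
        block = detrend_poly2(block)
    win = get_window("hann", n, fftbins=True)
    spec = np.fft.rfft(block * win)
    return np.abs(spec[: n // 2]) * 2.0 / win.sum()


def average_spectra(blocks, fs_hz: float, detrend: bool = True) -> SpectrumSet:
    """Bin-wise arithmetic mean of per-block magnitude spectra.

    Never averages complex FFT values; see module docstring.
    """
    blocks = [np.asarray(b, dtype=float) for b in blocks]
    if len(blocks) == 0:
        raise ValueError("need at least one block")
    n = len(blocks[0])
    if any(len(b) != n for b in blocks):
        raise ValueError("all blocks must have equal length")
    mags = np.array([block_amplitude_spectrum(b, fs_hz, detrend=detrend)
                     for b in blocks])
    freq = np.arange(n // 2) * fs_hz / n
    return SpectrumSet(freq_hz=freq, magnitudes=mags,
                       mean_magnitude=mags.mean(axis=0),
                       fs_hz=fs_hz, block_len=n)
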