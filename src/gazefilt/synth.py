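"""Seeded synthetic gaze-signal generators.

Real eye-tracking recordings are optional inputs to this package; every
analysis stage can instead run on synthetic traces that reproduce the
qualitative structure of 1000 Hz video-oculography data:

* fixation traces whose amplitude spectrum is largest below 30 Hz,
  passes through a minimum between 100 and 200 Hz and rises again toward
  the Nyquist frequency, while the six-point velocity stays below the
  25 deg/s saccade screen, and
* short "random saccade" exemplars: a smooth ~1.25 dva saccade embedded
  in heavy sensor noise, used for the velocity-noise comparison.

The fixation model is a three-component sum: slow drift (a low-pass
filtered random walk), band-limited mid-frequency physiological noise
("tremor"), and white sensor noise shaped with a gentle high-frequency
emphasis so the spectral minimum falls in the 100-200 Hz region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .trace import GazeTrace

__all__ = [
    "FixationModel",
    "SaccadeModel",
    "generate_fixation",
    "generate_saccade_segment",
]


@dataclass
class FixationModel:
    """Generative model for a 30 s stationary-fixation trace.

    Amplitudes are in dva; the three components are mutually independent
    Gaussian processes.  Identical seeds give bit-identical traces.
    """

    fs_hz: float = 1000.0
    duration_s: float = 30.0
    #: RMS of the slow drift component (low-pass filtered random walk).
    drift_amp_dva: float = 0.11
    #: Low-pass corner of the drift component, Hz.
    drift_lp_hz: float = 30.0
    #: Passband of the mid-frequency physiological component, Hz.
    tremor_band_hz: tuple[float, float] = (15.0, 65.0)
    #: RMS of the mid-frequency component.
    tremor_amp_dva: float = 0.007
    #: RMS of the shaped high-frequency sensor noise.
    hf_noise_sd_dva: float = 0.012
    #: Relative broadband floor of the sensor-noise shaping gain.
    hf_floor: float = 0.022
    #: Spectral slope of the noise rise toward Nyquist.
    hf_rise_exponent: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for name in ("drift_amp_dva", "tremor_amp_dva", "hf_noise_sd_dva",
                     "hf_floor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        lo, hi = self.tremor_band_hz
        if not (0 < lo < hi < self.fs_hz / 2):
            raise ValueError("tremor_band_hz must satisfy 0 < lo < hi < Nyquist")


@dataclass
class SaccadeModel:
    """A single smooth saccade plus additive white sensor noise.

    The noiseless displacement follows a raised-cosine sigmoid, giving a
    bell-shaped velocity profile with peak speed ``pi*A/(2*T)``.
    """

    amplitude_dva: float = 1.25
    duration_ms: float = 24.0
    onset_s: float = 0.7
    #: SD of additive white noise; the default emulates a very noisy
    #: recording whose instantaneous-velocity SD is of order 100 deg/s.
    noise_sd_dva: float = 0.07
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.noise_sd_dva < 0:
            raise ValueError("noise_sd_dva must be non-negative")

    @property
    def peak_velocity_deg_s(self) -> float:
        """Peak of the analytic (noiseless) velocity profile."""
        return np.pi * abs(self.amplitude_dva) / (2 * self.duration_ms / 1000.0)


def _scaled(x: np.ndarray, rms: float) -> np.ndarray:
    sd = x.std()
    if sd == 0 or rms == 0:
        return np.zeros_like(x)
    return x * (rms / sd)


def generate_fixation(model: FixationModel) -> GazeTrace:
    """Generate a stationary-fixation gaze trace.

    Returns a trace of ``round(fs*duration)`` samples.  With default
    parameters the six-point velocity stays below the 25 deg/s screen
    and the block-averaged amplitude spectrum peaks below 30 Hz with a
    local minimum between 100 and 200 Hz.
    """
    n = round(model.fs_hz * model.duration_s)
    if n < 16:
        raise ValueError("trace too short; increase duration_s")
    rng = np.random.default_rng(model.seed)

    # Slow drift: random walk, low-passed and scaled to the target RMS.
    walk = np.cumsum(rng.standard_normal(n))
    b, a = signal.butter(2, model.drift_lp_hz, fs=model.fs_hz)
    drift = signal.filtfilt(b, a, walk)
    drift = _scaled(drift - drift.mean(), model.drift_amp_dva)

    # Mid-frequency physiological component: band-limited Gaussian noise.
    b, a = signal.butter(2, model.tremor_band_hz, btype="bandpass",
                         fs=model.fs_hz)
    tremor = _scaled(signal.filtfilt(b, a, rng.standard_normal(n)),
                     model.tremor_amp_dva)

    # Sensor noise: white Gaussian, shaped in the frequency domain with a
    # broadband floor plus a power-law emphasis toward Nyquist.
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / model.fs_hz)
    gain = model.hf_floor + (1.0 - model.hf_floor) * (
        f / (model.fs_hz / 2.0)) ** model.hf_rise_exponent
    hf = _scaled(np.fft.irfft(spec * gain, n), model.hf_noise_sd_dva)

    return GazeTrace.from_samples(drift + tremor + hf, fs_hz=model.fs_hz)


def generate_saccade_segment(model: SaccadeModel, fs_hz: float = 1000.0,
                             duration_s: float = 1.5) -> GazeTrace:
    """Generate a noisy segment containing one smooth saccade.

    The noiseless position follows a raised-cosine sigmoid so the
    end-minus-start displacement equals ``amplitude_dva`` exactly and
    the velocity profile is bell-shaped.
    """
    if fs_hz <= 0 or duration_s <= 0:
        raise ValueError("fs_hz and duration_s must be positive")
    dur = model.duration_ms / 1000.0
    if model.onset_s < 0 or model.onset_s + dur > duration_s:
        raise ValueError("saccade must fit inside the trace")
    n = round(fs_hz * duration_s)
    t = np.arange(n) / fs_hz
    tau = np.clip((t - model.onset_s) / dur, 0.0, 1.0)
    x = model.amplitude_dva * (1.0 - np.cos(np.pi * tau)) / 2.0
    rng = np.random.default_rng(model.seed)
    noise = model.noise_sd_dva * rng.standard_normal(n)
    return GazeTrace(t=t, x=x + noise, fs_hz=fs_hz)


def saccade_position_profile(model: SaccadeModel, t: np.ndarray) -> np.ndarray:
    """Noiseless raised-cosine position profile evaluated at times ``t``."""
    dur = model.duration_ms / 1000.0
    tau = np.clip((np.asarray(t, float) - model.onset_s) / dur, 0.0, 1.0)
    return model.amplitude_dva * (1.0 - np.cos(np.pi * tau)) / 2.0
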