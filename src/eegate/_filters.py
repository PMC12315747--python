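"""Zero-phase Butterworth/notch filtering on plain arrays (internal)."""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = ["butter_bandpass", "butter_bandstop", "notch_iir", "analytic_envelope"]


def _check_band(low: float, high: float, fs: float) -> None:
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({fs / 2} Hz)")


def butter_bandpass(x: np.ndarray, low: float, high: float, fs: float,
                    order: int = 4) -> np.ndarray:
    """Forward-backward Butterworth band-pass along the last axis."""
    _check_band(low, high, fs)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def butter_bandstop(x: np.ndarray, low: float, high: float, fs: float,
                    order: int = 4) -> np.ndarray:
    _check_band(low, high, fs)
    sos = signal.butter(order, [low, high], btype="bandstop", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def notch_iir(x: np.ndarray, freq: float, fs: float, quality: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch at ``freq`` Hz."""
    if not (0 < freq < fs / 2):
        raise ValueError(f"notch frequency {freq} Hz must lie below Nyquist ({fs / 2} Hz)")
    b, a = signal.iirnotch(freq, quality, fs=fs)
    return signal.filtfilt(b, a, x, axis=-1)


def analytic_envelope(x: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic (Hilbert) signal along the last axis."""
    return np.abs(signal.hilbert(x, axis=-1))
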