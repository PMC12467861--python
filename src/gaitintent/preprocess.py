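"""Signal conditioning: zero-phase Butterworth filtering and windowing.

sEMG channels pass through a fourth-order 20-250 Hz Butterworth bandpass
and a narrow 50 Hz IIR notch (Q = 30); IMU axes through a fourth-order 6 Hz
low-pass.  All filters are applied forward-backward (zero net phase).
Signals are then cut into non-overlapping 100 ms windows; a Hamming taper
is recorded with the window set but applied only when estimating spectra,
never to time-domain amplitude features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .modes import ModeLabel

__all__ = [
    "FilterSpec",
    "WindowSet",
    "design_semg_filters",
    "design_imu_filter",
    "zero_phase_filter",
    "segment",
]


@dataclass(frozen=True)
class FilterSpec:
    """A designed digital IIR filter with its transfer-function coefficients."""

    kind: str  # bandpass | notch | lowpass
    order: int
    cutoffs: tuple[float, ...]
    fs: float
    b: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        if np.max(self.cutoffs) >= self.fs / 2:
            raise ValueError("cutoff at or above Nyquist")
        if self.max_pole_modulus() >= 1.0:
            raise ValueError("unstable filter: pole on or outside the unit circle")

    def max_pole_modulus(self) -> float:
        poles = np.roots(self.a)
        return float(np.max(np.abs(poles))) if poles.size else 0.0

    def magnitude_db(self, freqs_hz) -> np.ndarray:
        """Magnitude response in dB at the given frequencies."""
        w, h = signal.freqz(self.b, self.a, worN=np.atleast_1d(freqs_hz), fs=self.fs)
        return 20.0 * np.log10(np.maximum(np.abs(h), 1e-300))


def design_semg_filters(fs: float) -> tuple[FilterSpec, FilterSpec]:
    """Bandpass (20-250 Hz, order 4) and 50 Hz notch for sEMG at rate ``fs``."""
    if fs <= 500.0:
        raise ValueError(f"fs={fs} too low for a 250 Hz cutoff (need fs > 500)")
    b, a = signal.butter(4, [20.0, 250.0], btype="bandpass", fs=fs)
    bandpass = FilterSpec("bandpass", 4, (20.0, 250.0), fs, b, a)
    bn, an = signal.iirnotch(50.0, Q=30.0, fs=fs)
    notch = FilterSpec("notch", 2, (50.0,), fs, bn, an)
    return bandpass, notch


def design_imu_filter(fs: float) -> FilterSpec:
    """6 Hz order-4 Butterworth low-pass for IMU axes at rate ``fs``."""
    if fs <= 12.0:
        raise ValueError(f"fs={fs} too low for a 6 Hz cutoff (need fs > 12)")
    b, a = signal.butter(4, 6.0, btype="lowpass", fs=fs)
    return FilterSpec("lowpass", 4, (6.0,), fs, b, a)


def zero_phase_filter(x: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Forward-backward filtering; output has the input's length and no
    net phase shift.  Edges are handled by odd-reflection padding."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n <= 3 * spec.order:
        raise ValueError(
            f"input of {n} samples too short for order-{spec.order} zero-phase filtering"
        )
    padlen = min(3 * (max(len(spec.a), len(spec.b)) - 1), n - 1)
    return signal.filtfilt(spec.b, spec.a, x, padtype="odd", padlen=padlen)


@dataclass
class WindowSet:
    """Non-overlapping 100 ms windows of a multichannel signal.

    ``windows`` is [n_channels x n_windows x window_len]; windows are cut
    rectangular, ``taper`` only marks which taper spectral estimation
    should use.
    """

    windows: np.ndarray
    fs: float
    window_ms: float = 100.0
    taper: str = "hamming"
    labels: list[ModeLabel] | None = None

    @property
    def n_windows(self) -> int:
        return self.windows.shape[1]

    @property
    def window_len(self) -> int:
        return self.windows.shape[2]


def segment(
    x: np.ndarray,
    fs: float,
    labels: list[ModeLabel] | None = None,
    window_ms: float = 100.0,
    taper: str = "hamming",
) -> WindowSet:
    """Cut ``x`` ([n_channels x n_samples] or 1-D) into non-overlapping
    windows of ``window_ms``; a trailing partial window is discarded."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[-1] == 0:
        raise ValueError("cannot segment an empty signal")
    wlen = int(round(fs * window_ms / 1000.0))
    if wlen < 2:
        raise ValueError(f"window of {window_ms} ms holds <2 samples at fs={fs}")
    n_windows = x.shape[-1] // wlen
    if n_windows == 0:
        raise ValueError("signal shorter than one window")
    trimmed = x[:, : n_windows * wlen]
    windows = trimmed.reshape(x.shape[0], n_windows, wlen)
    if labels is not None:
        labels = list(labels[:n_windows])
        if len(labels) != n_windows:
            raise ValueError(
                f"{len(labels)} labels for {n_windows} windows"
            )
    return WindowSet(windows=windows, fs=fs, window_ms=window_ms, taper=taper, labels=labels)
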