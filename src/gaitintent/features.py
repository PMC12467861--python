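"""Per-window bidomain feature extraction.

sEMG windows yield five features per channel — three amplitude statistics
(MAV, RMS, VAR) and two spectral ones (median frequency MF, mean power
frequency MPF) — for a 30-dimensional vector with the default six channels.
IMU windows yield MAV and VAR per axis: 12 features per six-axis unit, 36
dimensions with three units.  Fusion concatenates both blocks to 66 columns.

Spectral features come from a Hamming-tapered, mean-removed one-sided
periodogram; MF is the first frequency at which cumulative power reaches
half the total, MPF the power-weighted mean frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .modes import ModeLabel
from .preprocess import WindowSet

__all__ = [
    "FeatureMatrix",
    "Spectrum",
    "mav",
    "rms",
    "var",
    "psd",
    "median_frequency",
    "mean_power_frequency",
    "extract_features",
    "SEMG_FEATURES",
    "IMU_FEATURES",
]

SEMG_FEATURES: tuple[str, ...] = ("mav", "rms", "var", "mf", "mpf")
IMU_FEATURES: tuple[str, ...] = ("mav", "var")


def _as_window(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty window")
    return x


def mav(x) -> float:
    """Mean absolute value: (1/N) sum |x_i|."""
    x = _as_window(x)
    return float(np.mean(np.abs(x)))


def rms(x) -> float:
    """Root mean square: sqrt((1/N) sum x_i^2)."""
    x = _as_window(x)
    return float(np.sqrt(np.mean(x**2)))


def var(x) -> float:
    """Unbiased sample variance (N-1 denominator, mean removed)."""
    x = _as_window(x)
    if x.size < 2:
        raise ValueError("variance needs at least 2 samples")
    return float(np.var(x, ddof=1))


@dataclass(frozen=True)
class Spectrum:
    """One-sided power spectral density on a discrete frequency grid."""

    freqs: np.ndarray
    powers: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.powers < 0):
            raise ValueError("negative spectral power")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    @property
    def total_power(self) -> float:
        return float(np.sum(self.powers))


def psd(x, fs: float, taper: str = "hamming") -> Spectrum:
    """Single-taper periodogram of a mean-removed window."""
    x = _as_window(x)
    if x.size < 4:
        raise ValueError("window too short for spectral estimation")
    win = taper if taper != "none" else "boxcar"
    freqs, powers = sps.periodogram(
        x, fs=fs, window=win, detrend="constant", scaling="density"
    )
    return Spectrum(freqs=freqs, powers=powers)


def median_frequency(s: Spectrum) -> float:
    """Smallest frequency at which cumulative power reaches half the total."""
    total = s.total_power
    if total <= 0:
        raise ValueError("median frequency undefined for a zero spectrum")
    cum = np.cumsum(s.powers)
    k = int(np.searchsorted(cum, 0.5 * total))
    return float(s.freqs[k])


def mean_power_frequency(s: Spectrum) -> float:
    """Power-weighted mean frequency, sum(f_j p_j) / sum(p_j)."""
    total = s.total_power
    if total <= 0:
        raise ValueError("mean power frequency undefined for a zero spectrum")
    return float(np.sum(s.freqs * s.powers) / total)


@dataclass
class FeatureMatrix:
    """Windows-by-features table with named columns and per-window labels."""

    values: np.ndarray
    names: list[str]
    labels: list[ModeLabel] | None
    modality_mask: np.ndarray  # per-column tag: "semg" or "imu"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains NaN/Inf")
        if self.values.shape[1] != len(self.names):
            raise ValueError("column count does not match names")

    @property
    def y(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("feature matrix has no labels")
        return np.array([lab.code for lab in self.labels])

    def columns(self, modality: str) -> np.ndarray:
        return self.values[:, self.modality_mask == modality]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        if self.labels is not None:
            df["label"] = [lab.code for lab in self.labels]
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = None
        if "label" in df.columns:
            labels = [ModeLabel(c) for c in df.pop("label")]
        names = list(df.columns)
        mask = np.array(["semg" if n.startswith("semg") else "imu" for n in names])
        return cls(values=df.to_numpy(), names=names, labels=labels, modality_mask=mask)


def _semg_block(ws: WindowSet) -> tuple[np.ndarray, list[str]]:
    # vectorized over windows; matches the scalar mav/rms/var/psd/mf/mpf
    # functions exactly (shared estimator settings)
    n_ch, n_win, _ = ws.windows.shape
    cols = np.empty((n_win, n_ch * len(SEMG_FEATURES)))
    names = []
    taper = ws.taper if ws.taper != "none" else "boxcar"
    for ch in range(n_ch):
        names += [f"semg.ch{ch + 1}.{f}" for f in SEMG_FEATURES]
        W = ws.windows[ch]
        j = ch * 5
        cols[:, j] = np.mean(np.abs(W), axis=1)
        cols[:, j + 1] = np.sqrt(np.mean(W**2, axis=1))
        cols[:, j + 2] = np.var(W, axis=1, ddof=1)
        freqs, P = sps.periodogram(
            W, fs=ws.fs, window=taper, detrend="constant",
            scaling="density", axis=-1,
        )
        total = P.sum(axis=1)
        ok = total > 0
        cum = np.cumsum(P, axis=1)
        k = np.sum(cum < 0.5 * total[:, None], axis=1)
        mf = np.where(ok, freqs[np.minimum(k, freqs.size - 1)], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mpf = np.where(ok, (P * freqs).sum(axis=1) / np.where(ok, total, 1.0), 0.0)
        cols[:, j + 3] = mf
        cols[:, j + 4] = mpf
    return cols, names


def _imu_block(ws: WindowSet) -> tuple[np.ndarray, list[str]]:
    n_ax, n_win, _ = ws.windows.shape
    cols = np.empty((n_win, n_ax * len(IMU_FEATURES)))
    names = []
    for ax in range(n_ax):
        names += [f"imu.ax{ax + 1}.{f}" for f in IMU_FEATURES]
        W = ws.windows[ax]
        cols[:, 2 * ax] = np.mean(np.abs(W), axis=1)
        cols[:, 2 * ax + 1] = np.var(W, axis=1, ddof=1)
    return cols, names


def extract_features(
    windows_semg: WindowSet | None,
    windows_imu: WindowSet | None,
    modality: str = "fusion",
) -> FeatureMatrix:
    """Assemble the per-window feature matrix for one or both modalities.

    With the default channel layout: ``semg`` gives 30 columns, ``imu`` 36,
    ``fusion`` their 66-column concatenation.  Both window sets must sit on
    the same 100 ms grid (equal window counts).
    """
    if modality not in ("semg", "imu", "fusion"):
        raise ValueError(f"unknown modality {modality!r}")
    blocks, names, tags = [], [], []
    labels = None
    if modality in ("semg", "fusion"):
        if windows_semg is None:
            raise ValueError("sEMG windows required")
        vals, nm = _semg_block(windows_semg)
        blocks.append(vals)
        names += nm
        tags += ["semg"] * len(nm)
        labels = windows_semg.labels
    if modality in ("imu", "fusion"):
        if windows_imu is None:
            raise ValueError("IMU windows required")
        vals, nm = _imu_block(windows_imu)
        blocks.append(vals)
        names += nm
        tags += ["imu"] * len(nm)
        labels = labels if labels is not None else windows_imu.labels
    if len(blocks) == 2 and blocks[0].shape[0] != blocks[1].shape[0]:
        raise ValueError(
            f"window-count mismatch: {blocks[0].shape[0]} sEMG vs "
            f"{blocks[1].shape[0]} IMU windows"
        )
    return FeatureMatrix(
        values=np.hstack(blocks),
        names=names,
        labels=labels,
        modality_mask=np.array(tags),
    )
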