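"""Synthetic sEMG/IMU gait generator.

Produces labelled multichannel recordings with the statistical structure a
locomotion-intent pipeline assumes: per-mode muscle-activation envelopes
modulating a 20-250 Hz stochastic carrier (sEMG), periodic segment
kinematics built from gait-cycle harmonics (IMU), plus the usual nuisance
terms — 50 Hz powerline interference, slow baseline drift, high-frequency
soft-tissue artifact noise, and optional additive white Gaussian noise at a
prescribed SNR.

The activation model is deliberately simple: per gait cycle and muscle, a
tonic (baseline) level plus a sum of Gaussian bursts parameterised by
(center % of cycle, width %, amplitude).  Transition modes cross-fade the
two endpoint steady-mode templates linearly over one gait cycle, which makes
them intermediate between — and naturally confusable with — their endpoints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .modes import MODE_CODES, STEADY_CODES, ModeLabel, transition_endpoints

__all__ = [
    "SimConfig",
    "Recording",
    "default_config",
    "generate_trial",
    "inject_awgn",
    "generate_dataset",
    "oracle_window_features",
    "write_recording",
    "read_recording",
    "write_dataset",
    "read_dataset",
]

#: Muscle order: right then left — rectus femoris, tibialis anterior, soleus.
MUSCLES: tuple[str, ...] = (
    "r_rf", "r_ta", "r_sol", "l_rf", "l_ta", "l_sol",
)

#: IMU axis order: thigh/shank/ankle units, accel xyz then gyro xyz each.
IMU_SITES: tuple[str, ...] = ("thigh", "shank", "ankle")
IMU_AXES: tuple[str, ...] = tuple(
    f"{site}_{sensor}{ax}"
    for site in IMU_SITES
    for sensor in ("acc", "gyr")
    for ax in "xyz"
)

_N_HARMONICS = 4

# Hand-designed burst templates for the right-leg muscles of the five
# steady gaits: (center % of gait cycle, width %, amplitude mV).  Left-leg
# muscles reuse them shifted by half a cycle (antiphase gait).  Centers and
# amplitudes differ across modes so that amplitude and spectral features
# separate the classes.
_STEADY_BURSTS: dict[str, dict[str, list[tuple[float, float, float]]]] = {
    "LW": {
        "rf": [(5.0, 6.0, 0.60)],
        "ta": [(60.0, 8.0, 0.80), (2.0, 5.0, 0.40)],
        "sol": [(40.0, 9.0, 1.00)],
    },
    "SA": {
        "rf": [(20.0, 10.0, 1.20)],
        "ta": [(70.0, 7.0, 0.50)],
        "sol": [(48.0, 10.0, 1.30)],
    },
    "SD": {
        "rf": [(85.0, 10.0, 0.90)],
        "ta": [(15.0, 8.0, 1.00)],
        "sol": [(30.0, 6.0, 0.50)],
    },
    "RA": {
        "rf": [(10.0, 9.0, 1.00)],
        "ta": [(65.0, 7.0, 0.70)],
        "sol": [(52.0, 10.0, 1.20)],
    },
    "RD": {
        "rf": [(90.0, 8.0, 0.70)],
        "ta": [(25.0, 9.0, 0.90)],
        "sol": [(35.0, 6.0, 0.60)],
    },
}


def _default_templates() -> tuple[dict, dict, dict, dict, dict]:
    """Build the full per-mode template tables.

    Tonic activation levels, IMU harmonic coefficients and the transition
    signatures are drawn once from a fixed internal generator so the
    default configuration is a constant, not a function of the run seed.
    """
    rng = np.random.default_rng(20240613)
    tonic: dict[str, np.ndarray] = {}
    bursts: dict[str, list[list[tuple[float, float, float]]]] = {}
    kinematics: dict[str, np.ndarray] = {}

    for code in STEADY_CODES:
        tonic[code] = rng.uniform(0.15, 0.55, size=len(MUSCLES))
        # mean (gravity-projection / posture) term per axis: segment
        # orientation differs between level, stair and ramp gaits, so each
        # steady mode carries its own accelerometer and gyro baselines
        offsets = np.where(
            np.array(["_acc" in a for a in IMU_AXES]),
            rng.uniform(-4.0, 4.0, len(IMU_AXES)),
            rng.uniform(-20.0, 20.0, len(IMU_AXES)),
        )
        per_muscle: list[list[tuple[float, float, float]]] = []
        for m in MUSCLES:
            side_shift = 50.0 if m.startswith("l_") else 0.0
            base = _STEADY_BURSTS[code][m.split("_")[1]]
            per_muscle.append(
                [((c + side_shift) % 100.0, w, a) for c, w, a in base]
            )
        bursts[code] = per_muscle
        # slot 0 holds the DC (posture) term; slots 1..4 the gait-cycle
        # harmonics as (amplitude, phase).  Accel axes ~ m/s^2, gyro ~ deg/s.
        coef = np.empty((len(IMU_AXES), _N_HARMONICS + 1, 2))
        coef[:, 0, 0] = offsets
        coef[:, 0, 1] = 0.0
        for ax_i, ax_name in enumerate(IMU_AXES):
            scale = 2.5 if "_acc" in ax_name else 45.0
            amps = rng.uniform(0.2, 1.0, _N_HARMONICS) * scale
            amps *= 1.0 / np.arange(1, _N_HARMONICS + 1) ** 0.5
            phases = rng.uniform(0.0, 2 * np.pi, _N_HARMONICS)
            coef[ax_i, 1:, 0] = amps
            coef[ax_i, 1:, 1] = phases
        kinematics[code] = coef

    # Transition strides carry preparatory adjustments of their own — a
    # mild co-contraction boost and a distinct postural lean — which makes
    # the A->B and B->A patterns between the same two gaits separable.
    trans_tonic: dict[str, np.ndarray] = {}
    trans_kin_offset: dict[str, np.ndarray] = {}
    for code in MODE_CODES:
        if code in STEADY_CODES:
            continue
        trans_tonic[code] = rng.uniform(0.0, 0.35, size=len(MUSCLES))
        trans_kin_offset[code] = np.where(
            np.array(["_acc" in a for a in IMU_AXES]),
            rng.uniform(-1.5, 1.5, len(IMU_AXES)),
            rng.uniform(-8.0, 8.0, len(IMU_AXES)),
        )
    return tonic, bursts, kinematics, trans_tonic, trans_kin_offset


@dataclass
class SimConfig:
    """Generator configuration: sampling, templates and artifact levels.

    Amplitudes are in the units of the channel they perturb (mV for sEMG
    terms).  ``tonic``, ``bursts`` and ``kinematics`` map *steady* mode codes
    to their templates; transition modes are derived by cross-fading and
    need no entries of their own.
    """

    fs_semg: float = 1000.0
    fs_imu: float = 200.0
    n_semg_channels: int = 6
    n_imu: int = 3
    cadence_hz: float = 1.0
    window_ms: float = 100.0
    powerline_amp: float = 0.05
    drift_amp: float = 0.08
    artifact_level: float = 0.15
    trial_duration_s: float = 2.0
    transition_pad_s: float = 0.5
    tonic: dict = field(default_factory=dict)
    bursts: dict = field(default_factory=dict)
    kinematics: dict = field(default_factory=dict)
    transition_tonic: dict = field(default_factory=dict)
    transition_kin_offset: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tonic:
            (
                self.tonic,
                self.bursts,
                self.kinematics,
                self.transition_tonic,
                self.transition_kin_offset,
            ) = _default_templates()
        if not self.transition_tonic:
            self.transition_tonic = {
                c: np.zeros(self.n_semg_channels)
                for c in MODE_CODES if c not in STEADY_CODES
            }
        if not self.transition_kin_offset:
            self.transition_kin_offset = {
                c: np.zeros(self.n_imu_axes)
                for c in MODE_CODES if c not in STEADY_CODES
            }
        for tbl in (self.tonic, self.bursts, self.kinematics):
            missing = [c for c in STEADY_CODES if c not in tbl]
            if missing:
                raise ValueError(f"templates missing for steady modes {missing}")
        if any(np.any(np.asarray(v) < 0) for v in self.tonic.values()):
            raise ValueError("tonic activation amplitudes must be non-negative")

    @property
    def n_imu_axes(self) -> int:
        return self.n_imu * 6


def default_config(**overrides) -> SimConfig:
    """The default study configuration (6 sEMG channels, 3 six-axis IMUs)."""
    return SimConfig(**overrides)


@dataclass
class Recording:
    """A synchronized multichannel sEMG + IMU trial.

    ``semg`` is [n_semg_channels x n_semg_samples] in mV, ``imu`` is
    [(n_imu*6) x n_imu_samples] (accel m/s^2, gyro deg/s), and
    ``window_labels`` holds one :class:`ModeLabel` per 100 ms window.
    """

    semg: np.ndarray
    fs_semg: float
    imu: np.ndarray
    fs_imu: float
    window_labels: list[ModeLabel]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.semg = np.asarray(self.semg, dtype=float)
        self.imu = np.asarray(self.imu, dtype=float)
        if not (np.all(np.isfinite(self.semg)) and np.all(np.isfinite(self.imu))):
            raise ValueError("recording contains non-finite samples")
        dur_semg = self.semg.shape[1] / self.fs_semg
        dur_imu = self.imu.shape[1] / self.fs_imu
        if abs(dur_semg - dur_imu) > 0.1 + 1e-9:
            raise ValueError(
                f"sEMG duration {dur_semg:.3f}s and IMU duration "
                f"{dur_imu:.3f}s disagree by more than one window"
            )

    @property
    def duration_s(self) -> float:
        return self.semg.shape[1] / self.fs_semg

    def copy(self) -> "Recording":
        return Recording(
            semg=self.semg.copy(),
            fs_semg=self.fs_semg,
            imu=self.imu.copy(),
            fs_imu=self.fs_imu,
            window_labels=list(self.window_labels),
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# template evaluation


def _blend_weights(code: str, phase: np.ndarray) -> tuple[str, str, np.ndarray]:
    """Endpoint modes and cross-fade weight u(phase) for a mode.

    Steady modes have u = 0 (pure first endpoint).  Transition modes ramp
    u linearly within each gait cycle, from 0.2 to 0.8: the transition
    stride is a moving mixture of its endpoint gaits but never coincides
    with either (preparatory adjustments begin before and persist after
    the terrain change), which keeps the class distinct while leaving it
    naturally confusable with its endpoints.
    """
    a, b = transition_endpoints(code)
    if a == b:
        return a, b, np.zeros_like(phase)
    return a, b, 0.2 + 0.6 * np.mod(phase, 1.0)


def _steady_envelope(cfg: SimConfig, code: str, mi: int, phase: np.ndarray) -> np.ndarray:
    env = np.full_like(phase, cfg.tonic[code][mi])
    frac = np.mod(phase, 1.0) * 100.0
    for center, width, amp in cfg.bursts[code][mi]:
        d = np.abs(frac - center)
        d = np.minimum(d, 100.0 - d)  # circular distance in % of cycle
        env = env + amp * np.exp(-0.5 * (d / width) ** 2)
    return env


def activation_envelope(cfg: SimConfig, code: str, mi: int, t: np.ndarray) -> np.ndarray:
    """Noise-free activation envelope of muscle ``mi`` for mode ``code``."""
    phase = t * cfg.cadence_hz
    a, b, u = _blend_weights(code, phase)
    env = _steady_envelope(cfg, a, mi, phase)
    if a != b:
        env = (1.0 - u) * env + u * _steady_envelope(cfg, b, mi, phase)
        env = env + cfg.transition_tonic[code][mi % len(MUSCLES)]
    return env


def _steady_kinematic(cfg: SimConfig, code: str, ax: int, t: np.ndarray) -> np.ndarray:
    coef = cfg.kinematics[code][ax]
    out = np.full_like(t, coef[0, 0])  # DC posture term
    for h in range(1, coef.shape[0]):
        amp, ph = coef[h]
        out += amp * np.cos(2 * np.pi * h * cfg.cadence_hz * t + ph)
    return out


def kinematic_template(cfg: SimConfig, code: str, ax: int, t: np.ndarray) -> np.ndarray:
    """Noise-free kinematic trajectory of IMU axis ``ax`` for mode ``code``."""
    phase = t * cfg.cadence_hz
    a, b, u = _blend_weights(code, phase)
    out = _steady_kinematic(cfg, a, ax, t)
    if a != b:
        out = (1.0 - u) * out + u * _steady_kinematic(cfg, b, ax, t)
        out = out + cfg.transition_kin_offset[code][ax % len(IMU_AXES)]
    return out


# ---------------------------------------------------------------------------
# signal synthesis


def _carrier(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance Gaussian carrier band-shaped to 20-250 Hz."""
    white = rng.standard_normal(n)
    sos = signal.butter(4, [20.0, 250.0], btype="bandpass", fs=fs, output="sos")
    shaped = signal.sosfiltfilt(sos, white)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _drift(rng: np.random.Generator, n: int, amp: float) -> np.ndarray:
    if amp == 0 or n < 2:
        return np.zeros(n)
    walk = np.cumsum(rng.standard_normal(n))
    walk -= walk.mean()
    sd = walk.std()
    return amp * walk / sd if sd > 0 else walk


def generate_trial(
    cfg: SimConfig,
    mode_sequence: list[tuple[ModeLabel | str, float]],
    seed: int,
) -> Recording:
    """Synthesize one labelled trial from a sequence of (mode, duration s).

    The same ``(cfg, mode_sequence, seed)`` always yields a bit-identical
    recording.  Durations are rounded down to whole 100 ms windows.
    """
    if not mode_sequence:
        raise ValueError("mode_sequence is empty")
    seq: list[tuple[ModeLabel, float]] = []
    for mode, dur in mode_sequence:
        label = mode if isinstance(mode, ModeLabel) else ModeLabel(mode)
        if dur <= 0:
            raise ValueError("segment durations must be positive")
        seq.append((label, float(dur)))

    win_s = cfg.window_ms / 1000.0
    seg_windows = [int(round(dur / win_s)) for _, dur in seq]
    if any(w < 1 for w in seg_windows):
        raise ValueError("every segment must span at least one window")
    labels: list[ModeLabel] = []
    for (label, _), w in zip(seq, seg_windows):
        labels.extend([label] * w)
    n_windows = len(labels)
    duration = n_windows * win_s

    n_semg = int(round(duration * cfg.fs_semg))
    n_imu_samp = int(round(duration * cfg.fs_imu))
    t_semg = np.arange(n_semg) / cfg.fs_semg
    t_imu = np.arange(n_imu_samp) / cfg.fs_imu

    # per-sample mode assignment from the window grid
    win_idx_semg = np.minimum((t_semg / win_s).astype(int), n_windows - 1)
    win_idx_imu = np.minimum((t_imu / win_s).astype(int), n_windows - 1)
    codes = np.array([lab.code for lab in labels])

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    semg = np.empty((cfg.n_semg_channels, n_semg))
    powerline_phase = rng.uniform(0, 2 * np.pi)
    for mi in range(cfg.n_semg_channels):
        env = np.empty(n_semg)
        for code in np.unique(codes):
            mask = codes[win_idx_semg] == code
            env[mask] = activation_envelope(cfg, code, mi % len(MUSCLES), t_semg[mask])
        x = env * _carrier(rng, n_semg, cfg.fs_semg)
        if cfg.powerline_amp:
            x = x + cfg.powerline_amp * np.sin(
                2 * np.pi * 50.0 * t_semg + powerline_phase
            )
        x = x + _drift(rng, n_semg, cfg.drift_amp)
        semg[mi] = x

    imu = np.empty((cfg.n_imu_axes, n_imu_samp))
    for ax in range(cfg.n_imu_axes):
        kin = np.empty(n_imu_samp)
        for code in np.unique(codes):
            mask = codes[win_idx_imu] == code
            kin[mask] = kinematic_template(cfg, code, ax % len(IMU_AXES), t_imu[mask])
        scale = 2.5 if "_acc" in IMU_AXES[ax % len(IMU_AXES)] else 45.0
        imu[ax] = kin + cfg.artifact_level * scale * rng.standard_normal(n_imu_samp)

    return Recording(
        semg=semg,
        fs_semg=cfg.fs_semg,
        imu=imu,
        fs_imu=cfg.fs_imu,
        window_labels=labels,
        meta={"seed": int(seed), "mode_sequence": [(l.code, d) for l, d in seq]},
    )


def inject_awgn(rec: Recording, snr_db: float | None, seed: int) -> Recording:
    """Add white Gaussian noise to every sEMG channel at a target SNR.

    ``snr_db=None`` (or +inf) returns an unmodified copy.  The noise standard
    deviation per channel is set from the channel's empirical power so the
    realized SNR matches ``snr_db`` up to sampling fluctuation.  Labels and
    IMU streams are untouched.
    """
    out = rec.copy()
    if snr_db is None or np.isinf(snr_db):
        return out
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for ch in range(out.semg.shape[0]):
        p_sig = np.mean(out.semg[ch] ** 2)
        if p_sig <= 0:
            raise ValueError(f"sEMG channel {ch} has zero power; SNR undefined")
        sigma = np.sqrt(p_sig * 10.0 ** (-snr_db / 10.0))
        out.semg[ch] = out.semg[ch] + sigma * rng.standard_normal(out.semg.shape[1])
    out.meta["snr_db"] = float(snr_db)
    return out


def generate_dataset(
    cfg: SimConfig, trials_per_mode: int, seed: int
) -> list[Recording]:
    """Generate a balanced labelled dataset covering all 13 modes.

    Steady modes get single-mode trials of ``cfg.trial_duration_s``.
    Transition modes get trials that embed the transition between short
    steady pads of its two endpoint gaits, e.g. RD-LW is generated as
    RD pad -> one cross-fade gait cycle -> LW pad.
    """
    if trials_per_mode < 1:
        raise ValueError("trials_per_mode must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(MODE_CODES) * trials_per_mode) % (2**31)
    recs: list[Recording] = []
    k = 0
    for code in MODE_CODES:
        for trial in range(trials_per_mode):
            if code in STEADY_CODES:
                seq = [(code, cfg.trial_duration_s)]
            else:
                a, b = transition_endpoints(code)
                trans_dur = 1.0 / cfg.cadence_hz
                seq = [
                    (a, cfg.transition_pad_s),
                    (code, trans_dur),
                    (b, cfg.transition_pad_s),
                ]
            rec = generate_trial(cfg, seq, int(child_seeds[k]))
            rec.meta.update({"trial": trial, "primary_mode": code})
            recs.append(rec)
            k += 1
    return recs


def oracle_window_features(
    cfg: SimConfig, code: str, duration_s: float
) -> np.ndarray:
    """Noise-free per-window template descriptors for one mode.

    Returns [n_windows x (n_muscles + 2 n_imu_axes)]: the window-mean
    activation envelope per muscle, plus the window mean and RMS of the
    kinematic template per IMU axis.  Used as the simulator's own
    separability oracle.
    """
    win_s = cfg.window_ms / 1000.0
    n_windows = int(np.floor(duration_s / win_s))
    n_per = max(int(round(win_s * cfg.fs_semg)), 8)
    feats = np.empty((n_windows, len(MUSCLES) + 2 * cfg.n_imu_axes))
    for w in range(n_windows):
        t = w * win_s + np.arange(n_per) / cfg.fs_semg
        for mi in range(len(MUSCLES)):
            feats[w, mi] = activation_envelope(cfg, code, mi, t).mean()
        for ax in range(cfg.n_imu_axes):
            kin = kinematic_template(cfg, code, ax % len(IMU_AXES), t)
            feats[w, len(MUSCLES) + 2 * ax] = kin.mean()
            feats[w, len(MUSCLES) + 2 * ax + 1] = np.sqrt(np.mean(kin**2))
    return feats


# ---------------------------------------------------------------------------
# plain-text I/O


def _channel_frame(data: np.ndarray, prefix: str) -> pd.DataFrame:
    return pd.DataFrame(data.T, columns=[f"{prefix}{i + 1}" for i in range(data.shape[0])])


def write_recording(rec: Recording, directory: str | Path, name: str) -> None:
    """Write one trial as two CSV tables plus a JSON metadata header."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _channel_frame(rec.semg, "semg_ch").to_csv(directory / f"{name}_semg.csv", index=False)
    _channel_frame(rec.imu, "imu_ax").to_csv(directory / f"{name}_imu.csv", index=False)
    meta = {
        "fs_semg_hz": rec.fs_semg,
        "fs_imu_hz": rec.fs_imu,
        "semg_units": "mV",
        "imu_units": "m/s^2 (acc), deg/s (gyr)",
        "window_labels": [lab.code for lab in rec.window_labels],
        "meta": rec.meta,
    }
    (directory / f"{name}_meta.json").write_text(json.dumps(meta, indent=1))


def read_recording(directory: str | Path, name: str) -> Recording:
    directory = Path(directory)
    meta = json.loads((directory / f"{name}_meta.json").read_text())
    semg = pd.read_csv(directory / f"{name}_semg.csv").to_numpy().T
    imu = pd.read_csv(directory / f"{name}_imu.csv").to_numpy().T
    return Recording(
        semg=semg,
        fs_semg=meta["fs_semg_hz"],
        imu=imu,
        fs_imu=meta["fs_imu_hz"],
        window_labels=[ModeLabel(c) for c in meta["window_labels"]],
        meta=meta["meta"],
    )


def write_dataset(recs: list[Recording], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = []
    for i, rec in enumerate(recs):
        name = f"trial{i:04d}"
        write_recording(rec, directory, name)
        index.append(name)
    (directory / "index.json").write_text(json.dumps(index))


def read_dataset(directory: str | Path) -> list[Recording]:
    directory = Path(directory)
    index = json.loads((directory / "index.json").read_text())
    return [read_recording(directory, name) for name in index]
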