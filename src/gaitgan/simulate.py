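"""Synthetic lumbar-IMU gait cohort generator.

Emulates walk sessions recorded by a lower-back inertial sensor during a
clinic walk test: alternating straight-walk bouts and turnaround events,
with severity-dependent gait dynamics.  Each simulated subject carries a
latent postural-instability/gait-disorder (PIGD) trait on the 0-20 clinical
scale; medication state (ON/OFF) shifts the effective severity of a visit.

The gait model is deliberately minimal: during a straight walk the vertical
acceleration is a short harmonic series at the cadence fundamental with
per-stride timing jitter, severity lowers both cadence and amplitude while
raising timing variability and band-limited (4-6 Hz) tremor energy.  Turns
are raised-cosine angular-rate pulses on the first gyroscope axis whose
integral comfortably exceeds the downstream 120 deg excision threshold.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import signal as _signal

PIGD_MAX = 20  # five items (chair, gait, freezing, postural stability, posture), 0-4 each


class MedState(str, Enum):
    """Self-reported levodopa medication state at a visit."""

    ON = "ON"
    OFF = "OFF"
    TRANSITIONING_TO_ON = "TRANSITIONING_TO_ON"
    TRANSITIONING_TO_OFF = "TRANSITIONING_TO_OFF"


@dataclass(frozen=True)
class SimConfig:
    """Cohort-simulation parameters.

    Defaults describe a paired two-visit design (one ON and one OFF visit per
    subject) with conventional adult gait values; severity slopes encode that
    worse PIGD means slower, smaller, more variable strides.
    """

    n_subjects: int = 35
    visits_per_subject: int = 2
    sample_rate: float = 128.0          # Hz
    walk_bout_duration: float = 6.0     # s per straight walk
    n_bouts_per_session: int = 4
    cadence_base: float = 2.0           # Hz, step frequency at severity 0
    severity_to_cadence_slope: float = -0.02   # Hz per PIGD point
    amplitude_base: float = 0.25        # g, vertical gait amplitude at severity 0
    severity_to_amplitude_slope: float = -0.008  # g per PIGD point
    tremor_band: tuple[float, float] = (4.0, 6.0)  # Hz
    tremor_gain: float = 0.004          # g RMS per PIGD point
    noise_sd: float = 0.02              # g white accelerometer noise
    gyro_noise_sd: float = 3.0          # deg/s
    on_off_gap: float = 6.0             # mean OFF - ON severity difference, PIGD points
    score_skew: float = 2.0             # gamma shape for right-skewed trait draws
    severity_scale: float = 2.5         # gamma scale for trait draws
    stride_cv_base: float = 0.03        # per-stride timing CV at severity 0
    stride_cv_slope: float = 0.0035     # CV increase per PIGD point
    turn_duration: float = 2.0          # s
    turn_angle_range: tuple[float, float] = (150.0, 200.0)  # deg, total rotation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.on_off_gap <= 0:
            raise ValueError("on_off_gap must be > 0 (OFF strictly more severe)")
        for name in ("sample_rate", "walk_bout_duration", "turn_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_subjects", "visits_per_subject", "n_bouts_per_session"):
            if getattr(self, name) < 0 or (name != "n_subjects" and getattr(self, name) < 1):
                raise ValueError(f"{name} must be positive")


@dataclass
class RawSession:
    """One walk-session recording: 3-axis acceleration (g) and angular rate (deg/s).

    ``true_turns`` / ``true_bouts`` are ground-truth sample intervals kept for
    validation of downstream turn excision; a real recording would not have them.
    """

    accel: np.ndarray            # (3, T) in g
    gyro: np.ndarray             # (3, T) in deg/s
    subject_id: str
    visit_id: str
    state: MedState
    pigd_score: int
    sample_rate: float = 128.0
    true_turns: list[tuple[int, int]] = field(default_factory=list)
    true_bouts: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.accel.shape[0] != 3 or self.gyro.shape[0] != 3:
            raise ValueError("accel and gyro must each have 3 channels")
        if self.accel.shape[1] != self.gyro.shape[1]:
            raise ValueError("accel and gyro must have equal length")
        if not 0 <= self.pigd_score <= PIGD_MAX:
            raise ValueError(f"pigd_score must lie in [0, {PIGD_MAX}]")


def effective_severity(severity: float, state: MedState, on_off_gap: float) -> float:
    """Visit-level severity: latent trait plus the medication-state shift.

    ON is the baseline; OFF adds the full gap, TRANSITIONING states half of it.
    """
    if state is MedState.OFF:
        return severity + on_off_gap
    if state in (MedState.TRANSITIONING_TO_ON, MedState.TRANSITIONING_TO_OFF):
        return severity + 0.5 * on_off_gap
    return severity


def _stride_phase(n: int, fs: float, cadence: float, cv: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Cumulative gait phase (radians) with per-stride period jitter.

    Stride boundaries are laid down iteratively with durations
    ``(1/cadence) * (1 + cv*eps)``; phase grows by 2*pi per stride and is
    linearly interpolated between boundaries.
    """
    duration = n / fs
    mean_period = 1.0 / cadence
    n_strides = int(np.ceil(duration / mean_period)) + 3
    eps = np.clip(rng.standard_normal(n_strides), -2.5, 2.5)
    periods = mean_period * np.clip(1.0 + cv * eps, 0.3, 2.0)
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])
    phases = 2.0 * np.pi * np.arange(boundaries.size)
    t = np.arange(n) / fs
    return np.interp(t, boundaries, phases)


def _tremor(n: int, fs: float, band: tuple[float, float], rms: float,
            rng: np.random.Generator) -> np.ndarray:
    if rms <= 0 or n < 24:
        return np.zeros(n)
    sos = _signal.butter(3, band, btype="bandpass", fs=fs, output="sos")
    x = _signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x * (rms / sd) if sd > 0 else np.zeros(n)


def _walk_bout(n: int, eff: float, config: SimConfig,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Acceleration (3, n) and gyro (3, n) for one straight-walk bout."""
    fs = config.sample_rate
    cadence = max(0.5, config.cadence_base + config.severity_to_cadence_slope * eff)
    amp = max(0.02, config.amplitude_base + config.severity_to_amplitude_slope * eff)
    cv = config.stride_cv_base + config.stride_cv_slope * eff
    phase = _stride_phase(n, fs, cadence, cv, rng)

    accel = np.zeros((3, n))
    harmonics = (1.0, 0.4, 0.2)
    psi = rng.uniform(0, 2 * np.pi, size=len(harmonics))
    vertical = sum(a * np.cos(h * phase + p)
                   for h, (a, p) in enumerate(zip(harmonics, psi), start=1))
    accel[2] = amp * vertical
    # Antero-posterior sways at the step frequency, medio-lateral at half of it.
    accel[0] = 0.5 * amp * np.cos(phase + rng.uniform(0, 2 * np.pi))
    accel[1] = 0.3 * amp * np.cos(0.5 * phase + rng.uniform(0, 2 * np.pi))

    trem = _tremor(n, fs, config.tremor_band, config.tremor_gain * eff, rng)
    accel[2] += trem
    accel[0] += 0.5 * trem

    t = np.arange(n) / fs
    # Gravity plus slow drift: removed later by the high-pass stage.
    accel[2] += 1.0 + 0.05 * np.sin(2 * np.pi * 0.02 * t + rng.uniform(0, 2 * np.pi))
    accel += rng.normal(0.0, config.noise_sd, size=(3, n))

    gyro = rng.normal(0.0, config.gyro_noise_sd, size=(3, n))
    # Mild trunk yaw sway; integrates to a few degrees at most.
    gyro[0] += 8.0 * np.sin(np.pi * t * cadence / 2 + rng.uniform(0, 2 * np.pi))
    return accel, gyro


def _turn(n: int, config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Turnaround: raised-cosine yaw-rate pulse integrating to 150-200 degrees."""
    fs = config.sample_rate
    angle = rng.uniform(*config.turn_angle_range) * rng.choice([-1.0, 1.0])
    t = np.arange(n) / fs
    dur = n / fs
    peak = 2.0 * angle / dur
    pulse = 0.5 * peak * (1.0 - np.cos(2 * np.pi * t / dur))
    gyro = rng.normal(0.0, config.gyro_noise_sd, size=(3, n))
    gyro[0] += pulse
    accel = rng.normal(0.0, config.noise_sd, size=(3, n))
    accel[2] += 1.0
    accel[0] += 0.1 * np.sin(2 * np.pi * t / dur)
    return accel, gyro


def simulate_session(subject_severity: float, state: MedState, config: SimConfig,
                     rng: np.random.Generator, subject_id: str = "S000",
                     visit_id: str = "V0") -> RawSession:
    """Simulate one walk session: alternating straight bouts and turns.

    ``subject_severity`` is the latent ON-state PIGD trait in [0, 20]; the
    medication state shifts it by the configured gap before it shapes the
    gait signal, and the shifted value (rounded, clipped) becomes the
    session's clinician PIGD score.
    """
    if not 0.0 <= subject_severity <= PIGD_MAX:
        raise ValueError(f"severity must lie in [0, {PIGD_MAX}], got {subject_severity}")
    state = MedState(state)
    eff = min(float(effective_severity(subject_severity, state, config.on_off_gap)), PIGD_MAX)

    fs = config.sample_rate
    n_bout = int(round(config.walk_bout_duration * fs))
    n_turn = int(round(config.turn_duration * fs))

    accel_parts, gyro_parts = [], []
    bouts, turns = [], []
    cursor = 0
    for b in range(config.n_bouts_per_session):
        a, g = _walk_bout(n_bout, eff, config, rng)
        accel_parts.append(a)
        gyro_parts.append(g)
        bouts.append((cursor, cursor + n_bout))
        cursor += n_bout
        if b < config.n_bouts_per_session - 1:
            a, g = _turn(n_turn, config, rng)
            accel_parts.append(a)
            gyro_parts.append(g)
            turns.append((cursor, cursor + n_turn))
            cursor += n_turn

    accel = np.concatenate(accel_parts, axis=1) if accel_parts else np.zeros((3, 0))
    gyro = np.concatenate(gyro_parts, axis=1) if gyro_parts else np.zeros((3, 0))
    score = int(np.clip(round(eff), 0, PIGD_MAX))
    return RawSession(accel=accel, gyro=gyro, subject_id=subject_id, visit_id=visit_id,
                      state=state, pigd_score=score, sample_rate=fs,
                      true_turns=turns, true_bouts=bouts)


def _draw_states(visits: int, rng: np.random.Generator) -> list[MedState]:
    """Visit states: a shuffled ON/OFF pair for two-visit designs, otherwise a
    mixed draw (as in multi-visit recordings spanning a medication cycle)."""
    if visits == 2:
        states = [MedState.ON, MedState.OFF]
        rng.shuffle(states)
        return states
    pool = [MedState.ON, MedState.OFF,
            MedState.TRANSITIONING_TO_ON, MedState.TRANSITIONING_TO_OFF]
    idx = rng.choice(4, size=visits, p=[0.35, 0.35, 0.15, 0.15])
    return [pool[i] for i in idx]


def simulate_cohort(config: SimConfig) -> list[RawSession]:
    """Simulate a cohort of subjects, each with ``visits_per_subject`` sessions.

    The latent ON-state trait is drawn from a right-skewed gamma distribution
    (shape ``score_skew``) and clipped so the OFF shift cannot saturate the
    scale; everything is reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    sessions: list[RawSession] = []
    ceiling = PIGD_MAX - config.on_off_gap
    for s in range(config.n_subjects):
        severity = float(np.clip(rng.gamma(config.score_skew, config.severity_scale),
                                 0.0, ceiling))
        states = _draw_states(config.visits_per_subject, rng)
        for v, state in enumerate(states):
            sessions.append(simulate_session(
                severity, state, config, rng,
                subject_id=f"S{s:03d}", visit_id=f"V{v}"))
    return sessions


# ---------------------------------------------------------------------------
# On-disk format: one CSV + JSON sidecar per session, one manifest per cohort.

def save_cohort(sessions: list[RawSession], out_dir: str | pathlib.Path) -> pathlib.Path:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for sess in sessions:
        stem = f"{sess.subject_id}_{sess.visit_id}"
        t = np.arange(sess.accel.shape[1]) / sess.sample_rate
        df = pd.DataFrame({
            "time_s": t,
            "ax": sess.accel[0], "ay": sess.accel[1], "az": sess.accel[2],
            "gx": sess.gyro[0], "gy": sess.gyro[1], "gz": sess.gyro[2],
        })
        df.to_csv(out / f"{stem}.csv", index=False, float_format="%.6f")
        meta = {
            "subject_id": sess.subject_id, "visit_id": sess.visit_id,
            "state": sess.state.value, "pigd_score": sess.pigd_score,
            "sample_rate": sess.sample_rate,
            "true_turns": [list(iv) for iv in sess.true_turns],
            "true_bouts": [list(iv) for iv in sess.true_bouts],
        }
        (out / f"{stem}.json").write_text(json.dumps(meta, indent=1))
        entries.append(stem)
    manifest = {"n_sessions": len(entries), "sessions": entries}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out / "manifest.json"


def load_cohort(in_dir: str | pathlib.Path) -> list[RawSession]:
    src = pathlib.Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    sessions = []
    for stem in manifest["sessions"]:
        df = pd.read_csv(src / f"{stem}.csv")
        meta = json.loads((src / f"{stem}.json").read_text())
        sessions.append(RawSession(
            accel=df[["ax", "ay", "az"]].to_numpy().T,
            gyro=df[["gx", "gy", "gz"]].to_numpy().T,
            subject_id=meta["subject_id"], visit_id=meta["visit_id"],
            state=MedState(meta["state"]), pigd_score=meta["pigd_score"],
            sample_rate=meta["sample_rate"],
            true_turns=[tuple(iv) for iv in meta.get("true_turns", [])],
            true_bouts=[tuple(iv) for iv in meta.get("true_bouts", [])],
        ))
    return sessions
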