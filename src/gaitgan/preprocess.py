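"""Raw walk sessions -> fixed-size log-spectral examples.

The feature pipeline: detect turnarounds from the yaw gyroscope (cumulative
rotation above 120 deg), keep only straight-walk snippets, truncate each to
3 s at 128 Hz (384 samples), remove drift and gravity with a zero-phase
high-pass Butterworth filter, and take the log-magnitude of the 384-point
discrete Fourier transform of each acceleration channel.  The result is a
3 x 384 tensor per walk, the input representation of the networks.
"""

from __future__ import annotations

import logging
import pathlib
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy import integrate, signal as _signal

from .simulate import MedState, RawSession

log = logging.getLogger(__name__)

SEGMENT_SAMPLES = 384  # 3 s at 128 Hz


@dataclass(frozen=True)
class PreprocessConfig:
    """Feature-processing knobs.

    ``highpass_cutoff_hz`` interprets the filter's "0.25 cutoff" as 0.25 Hz:
    the corner must sit below the gait band (~1.5-2.5 Hz fundamental) to
    remove only drift and gravity.  ``spectrum`` chooses between the full
    symmetric 384-bin DFT magnitude (default) and a zero-padded one-sided
    spectrum with the same 384-bin dimensionality.
    """

    turn_angle_deg: float = 120.0
    turn_window_s: float = 2.0
    turn_merge_gap_s: float = 0.5
    segment_duration_s: float = 3.0
    sample_rate: float = 128.0
    highpass_cutoff_hz: float = 0.25
    filter_order: int = 4
    zero_phase: bool = True
    log_floor: float = 1e-8
    spectrum: str = "full"  # "full" | "half"


@dataclass
class WalkSegment:
    """One straight-walk example: 3 acceleration channels x 384 samples."""

    accel: np.ndarray
    subject_id: str = ""
    visit_id: str = ""
    state: MedState = MedState.ON
    pigd_score: int = 0

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        if self.accel.shape != (3, SEGMENT_SAMPLES):
            raise ValueError(f"WalkSegment must be (3, {SEGMENT_SAMPLES}), "
                             f"got {self.accel.shape}")


@dataclass
class SpectralExample:
    """Log-spectral feature tensor (3 x 384) with its clinical PIGD label."""

    logspec: np.ndarray
    pigd_score: int
    subject_id: str
    visit_id: str
    state: MedState

    def __post_init__(self) -> None:
        self.logspec = np.asarray(self.logspec, dtype=float)
        if self.logspec.shape != (3, SEGMENT_SAMPLES):
            raise ValueError("logspec must be (3, 384)")
        if not np.all(np.isfinite(self.logspec)):
            raise ValueError("logspec must be finite everywhere")


def detect_turns(gyro_x: np.ndarray, sample_rate: float,
                 angle_threshold: float = 120.0, window: float = 2.0,
                 merge_gap: float = 0.5) -> list[tuple[int, int]]:
    """Find turn intervals: periods whose windowed cumulative rotation about
    the yaw axis exceeds ``angle_threshold`` degrees.

    Angular rate is integrated with the trapezoidal rule over a sliding
    ``window``-second span; every span whose |rotation| exceeds the threshold
    is marked, marked spans are merged when separated by less than
    ``merge_gap`` seconds, and maximal half-open sample intervals are
    returned sorted.
    """
    gyro_x = np.asarray(gyro_x, dtype=float)
    if gyro_x.size == 0:
        return []
    if not np.all(np.isfinite(gyro_x)):
        raise ValueError("gyro series contains non-finite samples")
    if angle_threshold <= 0:
        raise ValueError("angle_threshold must be > 0")

    n = gyro_x.size
    dt = 1.0 / sample_rate
    cum = np.concatenate([[0.0], integrate.cumulative_trapezoid(gyro_x, dx=dt)])
    w = min(n, max(2, int(round(window * sample_rate))))
    rot = cum[w:] - cum[:-w] if n > w else np.array([cum[-1] - cum[0]])
    hits = np.flatnonzero(np.abs(rot) > angle_threshold)
    if hits.size == 0:
        return []

    marked = np.zeros(n + 1, dtype=int)
    marked[hits] += 1
    marked[np.minimum(hits + w, n)] -= 1
    mask = np.cumsum(marked[:-1]) > 0

    intervals = _mask_to_intervals(mask)
    gap = int(round(merge_gap * sample_rate))
    merged: list[tuple[int, int]] = []
    for start, stop in intervals:
        if merged and start - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))
    return merged


def _mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(int), [0]])))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, edges.size, 2)]


def segment_walks(session: RawSession, turn_intervals: list[tuple[int, int]],
                  min_samples: int = SEGMENT_SAMPLES) -> list[tuple[int, np.ndarray]]:
    """Complement of the turn intervals along the session's time axis.

    Returns ``(start_index, accel_snippet)`` pairs; snippets shorter than
    ``min_samples`` are dropped (too short to yield one example).
    """
    n = session.accel.shape[1]
    for start, stop in turn_intervals:
        if not (0 <= start <= stop <= n):
            raise ValueError(f"turn interval ({start}, {stop}) outside session bounds")
    keep = np.ones(n, dtype=bool)
    for start, stop in turn_intervals:
        keep[start:stop] = False
    snippets = []
    dropped = 0
    for start, stop in _mask_to_intervals(keep):
        if stop - start >= min_samples:
            snippets.append((start, session.accel[:, start:stop]))
        else:
            dropped += 1
    if dropped:
        log.debug("segment_walks: dropped %d sub-length snippets "
                  "(%s %s)", dropped, session.subject_id, session.visit_id)
    return snippets


def truncate(snippet: np.ndarray, duration: float = 3.0,
             sample_rate: float = 128.0) -> np.ndarray:
    """First ``duration * sample_rate`` samples of every channel."""
    snippet = np.asarray(snippet, dtype=float)
    n = int(round(duration * sample_rate))
    if snippet.shape[-1] < n:
        raise ValueError(f"snippet of {snippet.shape[-1]} samples is shorter "
                         f"than the {n}-sample truncation length")
    return snippet[..., :n].copy()


def highpass(accel: np.ndarray, cutoff: float = 0.25, order: int = 4,
             sample_rate: float = 128.0, zero_phase: bool = True) -> np.ndarray:
    """Per-channel high-pass Butterworth; removes drift and the gravity offset.

    Applied forward-backward by default so the gait waveform is not phase
    shifted.  Reflect padding is extended up to the record length because the
    sub-gait-band corner has a settling time of several seconds; the pipeline
    applies this filter to whole sessions, where edge transients sit far from
    the walks of interest.
    """
    accel = np.asarray(accel, dtype=float)
    n = accel.shape[-1]
    sos = _signal.butter(order, cutoff, btype="highpass", fs=sample_rate,
                         output="sos")
    if zero_phase:
        padlen = min(n - 1, int(3 * sample_rate / cutoff))
        return _signal.sosfiltfilt(sos, accel, axis=-1, padlen=padlen)
    return _signal.sosfilt(sos, accel, axis=-1)


def log_spectrum(accel: np.ndarray, floor: float = 1e-8,
                 spectrum: str = "full") -> np.ndarray:
    """log(|DFT| + floor) per channel, keeping 384 bins.

    ``full`` keeps the complete symmetric 384-point DFT magnitude; ``half``
    zero-pads to 766 points and keeps the 384 one-sided bins.  Either way
    the feature dimensionality matches the networks' 3 x 384 contract.
    """
    accel = np.asarray(accel, dtype=float)
    if accel.shape[-1] != SEGMENT_SAMPLES:
        raise ValueError(f"expected {SEGMENT_SAMPLES} samples, got {accel.shape[-1]}")
    if not np.all(np.isfinite(accel)):
        raise ValueError("input contains non-finite samples")
    if spectrum == "full":
        mag = np.abs(np.fft.fft(accel, n=SEGMENT_SAMPLES, axis=-1))
    elif spectrum == "half":
        mag = np.abs(np.fft.rfft(accel, n=2 * SEGMENT_SAMPLES - 2, axis=-1))
    else:
        raise ValueError("spectrum must be 'full' or 'half'")
    return np.log(mag + floor)


class ExampleSet:
    """Column-oriented container for preprocessed examples.

    ``logspec`` is an ``(n, 3, 384)`` array; ``meta`` a DataFrame with
    subject_id, visit_id, state, pigd_score per row.
    """

    def __init__(self, logspec: np.ndarray, meta: pd.DataFrame):
        self.logspec = np.asarray(logspec, dtype=np.float32)
        self.meta = meta.reset_index(drop=True)
        if self.logspec.shape[0] != len(self.meta):
            raise ValueError("logspec and meta lengths differ")
        if self.logspec.ndim != 3 or self.logspec.shape[1:] != (3, SEGMENT_SAMPLES):
            raise ValueError("logspec must be (n, 3, 384)")

    def __len__(self) -> int:
        return self.logspec.shape[0]

    def __getitem__(self, i: int) -> SpectralExample:
        row = self.meta.iloc[i]
        return SpectralExample(self.logspec[i].astype(float), int(row.pigd_score),
                               str(row.subject_id), str(row.visit_id),
                               MedState(row.state))

    @property
    def labels(self) -> np.ndarray:
        return self.meta["pigd_score"].to_numpy(dtype=float)

    @property
    def subjects(self) -> np.ndarray:
        return np.asarray(sorted(self.meta["subject_id"].unique()))

    def subset(self, mask: np.ndarray) -> "ExampleSet":
        mask = np.asarray(mask)
        return ExampleSet(self.logspec[mask], self.meta.loc[mask])

    def for_subjects(self, subject_ids) -> "ExampleSet":
        return self.subset(self.meta["subject_id"].isin(list(subject_ids)).to_numpy())

    @staticmethod
    def empty() -> "ExampleSet":
        meta = pd.DataFrame(columns=["subject_id", "visit_id", "state", "pigd_score"])
        return ExampleSet(np.zeros((0, 3, SEGMENT_SAMPLES), dtype=np.float32), meta)

    def save_h5(self, path: str | pathlib.Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("logspec", data=self.logspec, compression="gzip")
            f.create_dataset("pigd_score", data=self.meta["pigd_score"].to_numpy(int))
            str_dt = h5py.string_dtype()
            for col in ("subject_id", "visit_id", "state"):
                f.create_dataset(col, data=self.meta[col].astype(str).to_numpy(),
                                 dtype=str_dt)

    @staticmethod
    def load_h5(path: str | pathlib.Path) -> "ExampleSet":
        with h5py.File(path, "r") as f:
            logspec = f["logspec"][...]
            meta = pd.DataFrame({
                "subject_id": [s.decode() if isinstance(s, bytes) else s
                               for s in f["subject_id"][...]],
                "visit_id": [s.decode() if isinstance(s, bytes) else s
                             for s in f["visit_id"][...]],
                "state": [s.decode() if isinstance(s, bytes) else s
                          for s in f["state"][...]],
                "pigd_score": f["pigd_score"][...].astype(int),
            })
        return ExampleSet(logspec, meta)


def preprocess_session(session: RawSession,
                       config: PreprocessConfig = PreprocessConfig()
                       ) -> list[SpectralExample]:
    """Full feature pipeline for one session; one example per straight walk.

    The high-pass filter is applied to the whole session before segmentation:
    the 0.25 Hz corner needs seconds of context to settle, so filtering
    isolated 3-s segments would distort their passband.
    """
    turns = detect_turns(session.gyro[0], session.sample_rate,
                         angle_threshold=config.turn_angle_deg,
                         window=config.turn_window_s,
                         merge_gap=config.turn_merge_gap_s)
    filtered = RawSession(
        accel=highpass(session.accel, config.highpass_cutoff_hz,
                       config.filter_order, session.sample_rate,
                       config.zero_phase),
        gyro=session.gyro, subject_id=session.subject_id,
        visit_id=session.visit_id, state=session.state,
        pigd_score=session.pigd_score, sample_rate=session.sample_rate,
        true_turns=session.true_turns, true_bouts=session.true_bouts)
    min_samples = int(round(config.segment_duration_s * config.sample_rate))
    examples = []
    for _, snippet in segment_walks(filtered, turns, min_samples=min_samples):
        seg = truncate(snippet, config.segment_duration_s, config.sample_rate)
        spec = log_spectrum(seg, config.log_floor, config.spectrum)
        examples.append(SpectralExample(spec, session.pigd_score,
                                        session.subject_id, session.visit_id,
                                        session.state))
    return examples


def preprocess_cohort(sessions: list[RawSession],
                      config: PreprocessConfig = PreprocessConfig()) -> ExampleSet:
    """Apply the pipeline to every session and stack the results."""
    specs, rows = [], []
    empty_sessions = 0
    for session in sessions:
        examples = preprocess_session(session, config)
        if not examples:
            empty_sessions += 1
            log.warning("session %s %s yielded no examples",
                        session.subject_id, session.visit_id)
            continue
        for ex in examples:
            specs.append(ex.logspec)
            rows.append((ex.subject_id, ex.visit_id, ex.state.value, ex.pigd_score))
    if not specs:
        return ExampleSet.empty()
    meta = pd.DataFrame(rows, columns=["subject_id", "visit_id", "state", "pigd_score"])
    if empty_sessions:
        log.info("preprocess_cohort: %d sessions yielded no examples", empty_sessions)
    return ExampleSet(np.stack(specs), meta)
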