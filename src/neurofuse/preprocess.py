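"""Signal conditioning for paired EEG/fNIRS recordings.

Raw-style multichannel series are band-pass filtered, rate-converted,
split into the canonical EEG rhythms (theta 4-8, alpha 8-12, beta 12-30,
gamma 30-45 Hz), converted from optical density to hemoglobin via the
modified Beer-Lambert law, segmented into fixed sliding windows, and
assigned to leakage-free train/test partitions at the stimulus-clip level.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import make_interp_spline

__all__ = [
    "Recording",
    "BandDefinition",
    "BANDS",
    "BAND_NAMES",
    "WindowedSegment",
    "ClipMeta",
    "SplitPlan",
    "bandpass",
    "resample",
    "extract_bands",
    "stft_band_power",
    "mbll",
    "segment",
    "make_splits",
]

#: window geometry at the common 200 Hz rate: 3 s windows, 1.5 s hop
WINDOW_SAMPLES = 600
HOP_SAMPLES = 300
COMMON_FS = 200.0


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float


#: the four EEG rhythms used throughout the pipeline
BANDS = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)
BAND_NAMES = tuple(b.name for b in BANDS)


@dataclass
class Recording:
    """One modality's multichannel time series.

    data is [channels x samples]; modality is one of "eeg", "hbo2", "hbr".
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    modality: str = "eeg"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be [channels x samples]")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [
                f"{self.modality}{i}" for i in range(self.data.shape[0])
            ]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must equal channel count")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel_labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray, fs: float | None = None) -> "Recording":
        return Recording(
            data=data,
            fs=self.fs if fs is None else fs,
            channel_labels=list(self.channel_labels),
            modality=self.modality,
        )


def bandpass(rec: Recording, low: float, high: float) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass, applied forward-backward."""
    nyq = rec.fs / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"band edges ({low}, {high}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(4, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(out)


def resample(rec: Recording, fs_out: float) -> Recording:
    """Rate conversion preserving duration to within one output sample.

    Downsampling goes through polyphase anti-aliased resampling (with
    linear-trend edge padding so slow offsets survive the filter);
    upsampling interpolates each channel with an interpolating spline
    through the original samples (quintic where enough samples exist,
    which keeps boundary error below 1e-3 of amplitude for band-limited
    signals; the spline passes exactly through the original values).
    """
    if fs_out <= 0:
        raise ValueError("fs_out must be positive")
    if fs_out == rec.fs:
        return rec.copy_with(rec.data.copy())
    n_in = rec.n_samples
    n_out = int(round(n_in * fs_out / rec.fs))
    if fs_out < rec.fs:
        from fractions import Fraction

        frac = Fraction(fs_out / rec.fs).limit_denominator(10000)
        # route the DC level around the polyphase filter: its pass-band
        # gain is not exactly one, which would tilt constant offsets
        mean = rec.data.mean(axis=1, keepdims=True)
        out = signal.resample_poly(
            rec.data - mean, frac.numerator, frac.denominator, axis=1, padtype="line"
        )
        out = out[:, :n_out] + mean
    else:
        t_in = np.arange(n_in) / rec.fs
        t_out = np.arange(n_out) / fs_out
        t_out = np.clip(t_out, t_in[0], t_in[-1])
        k = 5 if n_in > 5 else (3 if n_in > 3 else 1)
        spline = make_interp_spline(t_in, rec.data, k=k, axis=1)
        out = spline(t_out)
    return rec.copy_with(out, fs=fs_out)


def extract_bands(rec: Recording) -> dict[str, Recording]:
    """Split an EEG recording into the four rhythm-band-filtered copies."""
    if rec.modality != "eeg":
        raise ValueError("extract_bands expects an EEG recording")
    return {b.name: bandpass(rec, b.low, b.high) for b in BANDS}


def stft_band_power(
    rec: Recording, window: float = 1.0, overlap: float = 0.5
) -> dict[str, np.ndarray]:
    """Hann-windowed STFT band power per channel and frame.

    Frames cover [k*hop, k*hop + win); a frame count of
    floor((n - win)/hop) + 1 results, trailing partial frames dropped.
    """
    win = int(round(window * rec.fs))
    if win < 32:
        raise ValueError("window must span at least 32 samples")
    if win > rec.n_samples:
        raise ValueError("window longer than recording")
    hop = max(1, int(round(win * (1.0 - overlap))))
    n_frames = (rec.n_samples - win) // hop + 1
    taper = signal.windows.hann(win, sym=False)
    freqs = np.fft.rfftfreq(win, d=1.0 / rec.fs)
    idx = np.arange(n_frames)[:, None] * hop + np.arange(win)[None, :]
    frames = rec.data[:, idx] * taper  # [ch x frames x win]
    spec = np.abs(np.fft.rfft(frames, axis=-1)) ** 2
    out: dict[str, np.ndarray] = {}
    for b in BANDS:
        sel = (freqs >= b.low) & (freqs < b.high)
        out[b.name] = spec[:, :, sel].mean(axis=-1)
    return out


def mbll(
    delta_od: np.ndarray,
    extinction: np.ndarray,
    dpf: tuple[float, float],
    distance: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Modified Beer-Lambert inversion of optical density to hemoglobin.

    Solves, per sample, dOD(lambda) = [eps_HbO2(lambda), eps_HbR(lambda)]
    . [dHbO2, dHbR] * d * DPF(lambda) for the two chromophores.

    Parameters
    ----------
    delta_od : array [2 wavelengths x samples]
    extinction : 2x2 matrix, rows = wavelengths, cols = (HbO2, HbR)
    dpf : differential pathlength factor per wavelength
    distance : source-detector separation in cm
    """
    delta_od = np.asarray(delta_od, dtype=np.float64)
    extinction = np.asarray(extinction, dtype=np.float64)
    if delta_od.shape[0] != 2 or extinction.shape != (2, 2):
        raise ValueError("expected 2 wavelengths and a 2x2 extinction matrix")
    if distance <= 0:
        raise ValueError("source-detector distance must be positive")
    a = extinction * (distance * np.asarray(dpf, dtype=np.float64)[:, None])
    if abs(np.linalg.det(a)) < 1e-300:
        raise np.linalg.LinAlgError("singular extinction system")
    conc = np.linalg.solve(a, delta_od)
    return conc[0], conc[1]


@dataclass
class WindowedSegment:
    """One 3 s multimodal window: four EEG bands plus both chromophores.

    All streams are [channels x 600] at 200 Hz; start_sample indexes the
    0-based half-open window [start, start + 600) in the source clip.
    """

    eeg_bands: dict[str, np.ndarray]
    hbo2: np.ndarray
    hbr: np.ndarray
    label: int
    clip_id: str
    subject_id: str
    start_sample: int


def segment(
    eeg_bands: dict[str, Recording],
    hbo2: Recording,
    hbr: Recording,
    label: int = 0,
    clip_id: str = "clip0",
    subject_id: str = "s0",
    window_s: float = 3.0,
    hop_s: float = 1.5,
) -> list[WindowedSegment]:
    """Slide a 3 s window with 1.5 s hop over the aligned 200 Hz streams.

    Each stream is baseline-corrected per window by removing the
    per-channel mean. Trailing partial windows are dropped; a clip shorter
    than one window yields an empty list with a warning.
    """
    streams = list(eeg_bands.values()) + [hbo2, hbr]
    for s in streams:
        if s.fs != COMMON_FS:
            raise ValueError("all streams must be at 200 Hz before segmentation")
    n = streams[0].n_samples
    if any(s.n_samples != n for s in streams):
        raise ValueError("all streams must share the same duration")
    win = int(round(window_s * COMMON_FS))
    hop = int(round(hop_s * COMMON_FS))
    if n < win:
        warnings.warn("recording shorter than one window; no segments produced")
        return []
    n_win = (n - win) // hop + 1
    out = []
    for k in range(n_win):
        lo = k * hop
        sl = slice(lo, lo + win)

        def baselined(x: np.ndarray) -> np.ndarray:
            w = x[:, sl]
            return w - w.mean(axis=1, keepdims=True)

        out.append(
            WindowedSegment(
                eeg_bands={name: baselined(r.data) for name, r in eeg_bands.items()},
                hbo2=baselined(hbo2.data),
                hbr=baselined(hbr.data),
                label=label,
                clip_id=clip_id,
                subject_id=subject_id,
                start_sample=lo,
            )
        )
    return out


@dataclass(frozen=True)
class ClipMeta:
    clip_id: str
    subject_id: str
    label: int


@dataclass
class SplitPlan:
    """Clip-level train/test assignment; splitting precedes windowing."""

    mode: str
    assignments: dict[str, str]
    fold_index: int

    def train_clips(self) -> set[str]:
        return {c for c, p in self.assignments.items() if p == "train"}

    def test_clips(self) -> set[str]:
        return {c for c, p in self.assignments.items() if p == "test"}

    def validate(self) -> None:
        parts = set(self.assignments.values())
        if not parts <= {"train", "test"}:
            raise ValueError(f"unknown partitions {parts - {'train', 'test'}}")
        if self.train_clips() & self.test_clips():
            raise ValueError("clip assigned to both partitions")


def make_splits(
    clips: list[ClipMeta],
    mode: str = "subject_dependent",
    fold_index: int = 0,
    seed: int = 0,
    n_folds: int = 5,
) -> SplitPlan:
    """Build a leakage-free clip-level split.

    subject_dependent: per (subject, class), a seeded permutation of that
    cell's clips is rotated across the folds, holding out 1/n_folds of the
    clips (3 of 15 with the standard 15-clip protocol) as the test set.
    loso: all clips of one subject (the fold_index-th in sorted order)
    form the test set.
    """
    if mode not in {"subject_dependent", "loso"}:
        raise ValueError(f"unknown split mode {mode!r}")
    assignments: dict[str, str] = {}
    if mode == "loso":
        subjects = sorted({c.subject_id for c in clips})
        if not 0 <= fold_index < len(subjects):
            raise ValueError("fold_index out of range for LOSO")
        held_out = subjects[fold_index]
        for c in clips:
            assignments[c.clip_id] = "test" if c.subject_id == held_out else "train"
    else:
        if not 0 <= fold_index < n_folds:
            raise ValueError("fold_index out of range")
        cells: dict[tuple[str, int], list[str]] = {}
        for c in clips:
            cells.setdefault((c.subject_id, c.label), []).append(c.clip_id)
        for (subject, label), ids in sorted(cells.items()):
            if len(ids) < n_folds:
                raise ValueError(
                    f"subject {subject} class {label} has {len(ids)} clips; "
                    f"at least {n_folds} are required"
                )
            ids = sorted(ids)
            subject_key = zlib.crc32(subject.encode()) & 0x7FFFFFFF
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, subject_key, label])
            )
            perm = [ids[i] for i in rng.permutation(len(ids))]
            n_test = len(ids) // n_folds
            lo = fold_index * n_test
            test_ids = set(perm[lo : lo + n_test])
            for cid in ids:
                assignments[cid] = "test" if cid in test_ids else "train"
    plan = SplitPlan(mode=mode, assignments=assignments, fold_index=fold_index)
    plan.validate()
    return plan
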