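"""Single-lead ECG to per-beat grayscale images.

Mirrors the preprocessing stage of the wearable stress-prediction case
study: detect R peaks, cut the recording into cycles around each peak,
render every cycle as a 128x128 image, and attach a per-beat binary
condition label (baseline=0, stress=1) by majority vote over the beat
span.

The R-peak detector is a Pan–Tompkins-style chain (band-pass 5–15 Hz,
derivative, squaring, moving-window integration, adaptive threshold with
a 0.2 s refractory period) built on scipy.signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import signal as sps

from .synthetic import ClientDataset, SyntheticECGRecord

__all__ = [
    "BeatImageSet",
    "CycleSegment",
    "detect_r_peaks",
    "segment_cycles",
    "cycle_to_image",
    "preprocess_client",
    "load_wesad_pkl",
]

DEFAULT_FS = 700.0           # chest-device sampling rate in the case study
DEFAULT_IMAGE_SIZE = 128
RETAINED_TAGS = {"baseline": 0, "stress": 1}
REFRACTORY_S = 0.2


@dataclass
class BeatImageSet:
    """Per-beat images with labels; the preprocessed form of one client."""

    images: np.ndarray              # (beats, size, size) in [0,1]
    beat_labels: np.ndarray         # (beats,) ints in {0,1}
    source_peak_index: np.ndarray   # (beats,) sample index of each R peak
    client_id: str

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        self.beat_labels = np.asarray(self.beat_labels, dtype=np.intp)
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise ValueError("images must be (beats, size, size)")
        if len(self.images) != len(self.beat_labels):
            raise ValueError("one label per beat required")

    def __len__(self):
        return len(self.images)

    def to_client_dataset(self) -> ClientDataset:
        return ClientDataset(images=self.images, class_labels=self.beat_labels,
                             client_id=self.client_id)


class CycleSegment(NamedTuple):
    start: int          # inclusive
    stop: int           # exclusive
    peak_index: int
    samples: np.ndarray


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Pan–Tompkins-style R-peak detection.

    Returns strictly increasing sample indices of R peaks, at least
    REFRACTORY_S apart. A constant signal yields an empty result.
    """
    ecg = np.asarray(ecg, dtype=np.float64)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if len(ecg) < 2 * fs:
        raise ValueError("signal must be at least 2 s long")
    if not np.all(np.isfinite(ecg)):
        raise ValueError("non-finite samples in ECG signal")
    if np.ptp(ecg) == 0:
        return np.empty(0, dtype=np.intp)

    nyq = fs / 2.0
    b, a = sps.butter(2, [5.0 / nyq, min(15.0, 0.95 * nyq) / nyq], btype="band")
    band = sps.filtfilt(b, a, ecg)
    deriv = np.gradient(band)
    squared = deriv ** 2
    win = max(1, int(round(0.150 * fs)))
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    # adaptive threshold: fraction of a robust running ceiling
    ceiling = np.quantile(integrated, 0.98)
    if ceiling <= 0:
        return np.empty(0, dtype=np.intp)
    thresh = 0.25 * ceiling
    distance = max(1, int(round(REFRACTORY_S * fs)))
    cand, _ = sps.find_peaks(integrated, height=thresh, distance=distance)

    # refine each candidate to the raw-signal maximum nearby (the R apex)
    half = int(round(0.10 * fs))
    peaks = []
    for c in cand:
        lo, hi = max(0, c - half), min(len(ecg), c + half + 1)
        peaks.append(lo + int(np.argmax(ecg[lo:hi])))
    peaks = np.unique(np.asarray(peaks, dtype=np.intp))
    # enforce refractory after refinement
    kept: list[int] = []
    for p in peaks:
        if not kept or p - kept[-1] >= distance:
            kept.append(int(p))
        elif ecg[p] > ecg[kept[-1]]:
            kept[-1] = int(p)
    return np.asarray(kept, dtype=np.intp)


def segment_cycles(ecg: np.ndarray, peaks: Sequence[int], fs: float
                   ) -> list[CycleSegment]:
    """One segment per interior peak, spanning midpoint-to-midpoint.

    Segment d runs from midpoint(peak_{d-1}, peak_d) to
    midpoint(peak_d, peak_{d+1}); the first and last peaks are dropped
    because they lack a neighbor on one side.
    """
    ecg = np.asarray(ecg, dtype=np.float64)
    peaks = np.asarray(peaks, dtype=np.intp)
    if len(peaks) < 3:
        return []
    out = []
    for i in range(1, len(peaks) - 1):
        start = (peaks[i - 1] + peaks[i]) // 2
        stop = (peaks[i] + peaks[i + 1]) // 2
        out.append(CycleSegment(int(start), int(stop), int(peaks[i]),
                                ecg[start:stop]))
    return out


def cycle_to_image(segment: np.ndarray, size: int = DEFAULT_IMAGE_SIZE) -> np.ndarray:
    """Rasterize one beat as a size x size polyline image.

    The segment is resampled to `size` points, min–max normalized to
    [0,1] (a constant segment maps to a centered horizontal line), and
    drawn as a connected waveform: foreground 1 on background 0. The
    rendering is deterministic and invariant to positive affine
    amplitude changes.
    """
    segment = np.asarray(segment, dtype=np.float64)
    if segment.ndim != 1 or len(segment) < 2:
        raise ValueError("segment must be a 1-D array of length >= 2")
    x_old = np.linspace(0.0, 1.0, len(segment))
    x_new = np.linspace(0.0, 1.0, size)
    resampled = np.interp(x_new, x_old, segment)
    span = resampled.max() - resampled.min()
    if span == 0:
        norm = np.full(size, 0.5)
    else:
        norm = (resampled - resampled.min()) / span
    rows = np.round((1.0 - norm) * (size - 1)).astype(np.intp)
    img = np.zeros((size, size))
    img[rows, np.arange(size)] = 1.0
    # connect consecutive columns so the trace is a polyline, not dots
    for c in range(size - 1):
        lo, hi = sorted((rows[c], rows[c + 1]))
        img[lo:hi + 1, c] = 1.0
    return img


def preprocess_client(record: SyntheticECGRecord, fs: float | None = None,
                      size: int = DEFAULT_IMAGE_SIZE, purity: float = 0.8,
                      client_id: str = "0") -> BeatImageSet:
    """Full per-client pipeline: peaks -> cycles -> images -> beat labels.

    A beat keeps the majority condition tag over its span when that tag
    is retained (baseline/stress) and the majority holds at least
    `purity` of the span's samples; other beats — transition-straddling
    or carrying excluded tags — are dropped.
    """
    fs = record.fs if fs is None else fs
    peaks = detect_r_peaks(record.signal, fs)
    segments = segment_cycles(record.signal, peaks, fs)
    images, labels, srcs = [], [], []
    for seg in segments:
        tags, counts = np.unique(record.condition_labels[seg.start:seg.stop].astype(str),
                                 return_counts=True)
        major = tags[np.argmax(counts)]
        if major not in RETAINED_TAGS:
            continue
        if counts.max() / counts.sum() < purity:
            continue
        images.append(cycle_to_image(seg.samples, size))
        labels.append(RETAINED_TAGS[major])
        srcs.append(seg.peak_index)
    if not images:
        raise ValueError("no retained beats (empty beat set after filtering)")
    return BeatImageSet(images=np.stack(images), beat_labels=np.asarray(labels),
                        source_peak_index=np.asarray(srcs, dtype=np.intp),
                        client_id=client_id)


def load_wesad_pkl(path, subject_key: str | None = None):
    """Optional adapter for the public wearable stress dataset's native
    pickle container (one file per subject: chest ECG at 700 Hz plus
    per-sample protocol labels 1=baseline, 2=stress).

    Returns a SyntheticECGRecord-shaped object so the rest of the
    pipeline applies unchanged. Requires the external download; not
    exercised by the test suite.
    """
    import pickle
    with open(path, "rb") as fh:
        data = pickle.load(fh, encoding="latin1")
    ecg = np.asarray(data["signal"]["chest"]["ECG"]).ravel()
    raw_labels = np.asarray(data["label"]).ravel()
    tag_map = {1: "baseline", 2: "stress"}
    labels = np.empty(len(ecg), dtype=object)
    labels[:] = "other"
    for code, tag in tag_map.items():
        labels[raw_labels == code] = tag
    return SyntheticECGRecord(signal=ecg, fs=DEFAULT_FS,
                              true_peak_indices=np.empty(0, dtype=np.intp),
                              condition_labels=labels,
                              domain_regimes=np.zeros(len(ecg), dtype=np.intp))
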