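"""Beat segmentation around annotated R peaks and mean-range normalization.

A beat is a fixed window of 0.2 s before the R peak and 0.46 s after it
(0.66 s total, roughly one cardiac cycle).  At 360 Hz that is 72 + 1 + 165 =
238 samples, with the R sample at position 72.  Each beat is normalized by
subtracting its mean and dividing by its range, so every beat has zero mean
and unit peak-to-peak span regardless of recording gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .wfdb_io import CLASS_ORDER, BeatAnnotation, ECGRecord

__all__ = [
    "Beat",
    "BeatMatrix",
    "PRE_SECONDS",
    "POST_SECONDS",
    "segment_beat",
    "segment_record",
    "normalize_beat",
    "window_lengths",
]

logger = logging.getLogger(__name__)

#: Default window: 0.2 s before the R peak, 0.46 s after.
PRE_SECONDS = 0.2
POST_SECONDS = 0.46


@dataclass(frozen=True)
class Beat:
    """A fixed-length sample window around one R peak."""

    samples: np.ndarray
    label: str
    record_id: str = ""
    r_index: int = -1

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.label not in CLASS_ORDER:
            raise ValueError(f"unknown beat label {self.label!r}")


@dataclass
class BeatMatrix:
    """Rectangular stack of beats: one row per beat, one column per sample."""

    matrix: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise ValueError("matrix rows and labels must align")

    @property
    def n_beats(self) -> int:
        return self.matrix.shape[0]

    @property
    def beat_length(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"s{i}" for i in range(self.beat_length)]
        df = pd.DataFrame(self.matrix, columns=cols)
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BeatMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy(dtype=object)
        return cls(matrix=df.to_numpy(dtype=float), labels=labels)


def window_lengths(fs: float, pre_s: float = PRE_SECONDS, post_s: float = POST_SECONDS):
    """Number of samples before/after the R peak: floor(duration * fs)."""
    return int(np.floor(pre_s * fs)), int(np.floor(post_s * fs))


def normalize_beat(samples: np.ndarray) -> np.ndarray:
    """Mean-range normalization: (x - mean(x)) / (max(x) - min(x)).

    A constant input has zero range; by convention it maps to the all-zero
    vector so flat-line artifacts flow on to the outlier filter instead of
    raising.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("cannot normalize non-finite samples")
    rng = x.max() - x.min()
    if rng == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / rng


def segment_beat(
    record: ECGRecord,
    r_index: int,
    pre_s: float = PRE_SECONDS,
    post_s: float = POST_SECONDS,
    label: str = "NB",
    normalize: bool = True,
) -> Beat | None:
    """Cut the window [r_index - pre_n, r_index + post_n] out of the record.

    Returns ``None`` (with a logged warning) when the window would leave the
    record, so edge beats are silently dropped rather than failing the run.
    """
    pre_n, post_n = window_lengths(record.fs, pre_s, post_s)
    lo, hi = r_index - pre_n, r_index + post_n
    if lo < 0 or hi >= record.n_samples:
        logger.warning(
            "beat at sample %d skipped: window [%d, %d] exceeds record bounds",
            r_index, lo, hi,
        )
        return None
    window = record.signal[lo : hi + 1]
    if normalize:
        window = normalize_beat(window)
    return Beat(samples=window, label=label, record_id=record.record_id, r_index=r_index)


def segment_record(
    record: ECGRecord,
    annotations: list[BeatAnnotation],
    pre_s: float = PRE_SECONDS,
    post_s: float = POST_SECONDS,
    normalize: bool = True,
) -> BeatMatrix:
    """Segment every annotated beat of a record into a BeatMatrix."""
    pre_n, post_n = window_lengths(record.fs, pre_s, post_s)
    length = pre_n + 1 + post_n
    rows, labels = [], []
    for ann in annotations:
        beat = segment_beat(record, ann.sample_index, pre_s, post_s,
                            label=ann.label, normalize=normalize)
        if beat is not None:
            rows.append(beat.samples)
            labels.append(beat.label)
    matrix = np.array(rows, dtype=float) if rows else np.empty((0, length))
    return BeatMatrix(matrix=matrix, labels=np.array(labels, dtype=object))
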