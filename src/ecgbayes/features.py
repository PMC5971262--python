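"""The 80-dimensional FSC/SFE time + DFT feature vector.

Each normalized beat is split into four quarters.  Every quarter contributes
20 features: FSC (Feature Statistic Calculation — mean, sample standard
deviation, max, min) and SFE (Samples Features Extraction — first sample,
last sample and four equally spaced interior samples) of the quarter in the
time domain, then FSC and SFE of the quarter's DFT magnitude spectrum.
4 quarters x 20 features = 80.

Block layout per quarter q (1-based):
``[FSC_time(4), SFE_time(6), FSC_freq(4), SFE_freq(6)]``, quarters
concatenated in order — 80 named columns in serialized form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beats import Beat, BeatMatrix
from .wfdb_io import CLASS_ORDER

__all__ = [
    "N_FEATURES",
    "FEATURE_NAMES",
    "FeatureVector",
    "FeatureDataset",
    "quarter",
    "fsc",
    "sfe",
    "dft_magnitude",
    "extract_features",
    "extract_dataset",
]

N_FEATURES = 80

_FSC_NAMES = ("mean", "std", "max", "min")
_SFE_NAMES = tuple(f"s{k}" for k in range(6))

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"q{q}_{dom}_{stat}"
    for q in range(1, 5)
    for dom, names in (("time", _FSC_NAMES + _SFE_NAMES),
                       ("freq", _FSC_NAMES + _SFE_NAMES))
    for stat in names
)
assert len(FEATURE_NAMES) == N_FEATURES


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    label: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have length {N_FEATURES}")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature vector contains non-finite values")


@dataclass
class FeatureDataset:
    """N x 80 feature matrix with aligned class labels."""

    matrix: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise ValueError("matrix rows and labels must align")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def subset(self, indices) -> "FeatureDataset":
        idx = np.asarray(indices)
        return FeatureDataset(matrix=self.matrix[idx], labels=self.labels[idx])

    def to_frame(self) -> pd.DataFrame:
        if self.n_features == N_FEATURES:
            cols = list(FEATURE_NAMES)
        else:
            cols = [f"f{i}" for i in range(self.n_features)]
        df = pd.DataFrame(self.matrix, columns=cols)
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureDataset":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy(dtype=object)
        return cls(matrix=df.to_numpy(dtype=float), labels=labels)


def quarter(beat: np.ndarray, min_length: int = 24) -> list[np.ndarray]:
    """Split a beat into four contiguous quarters.

    Quarter i (1-based) is the half-open slice
    ``[floor((i-1)*L/4), floor(i*L/4))``; the quarters concatenate back to
    the beat exactly.  Beats shorter than ``min_length`` are rejected because
    every quarter must hold at least the 6 samples SFE needs.
    """
    v = np.asarray(beat, dtype=float)
    L = v.shape[0]
    if L < min_length:
        raise ValueError(f"beat of length {L} too short to quarter (min {min_length})")
    bounds = [(i * L) // 4 for i in range(5)]
    return [v[bounds[i] : bounds[i + 1]] for i in range(4)]


def fsc(v: np.ndarray) -> np.ndarray:
    """Feature Statistic Calculation: (mean, sample std, max, min)."""
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ValueError("FSC needs at least 2 samples (sample std undefined)")
    return np.array([v.mean(), v.std(ddof=1), v.max(), v.min()])


def _sfe_indices(m: int) -> np.ndarray:
    # round(k*(m-1)/5), half away from zero (values are non-negative)
    k = np.arange(6)
    return np.floor(k * (m - 1) / 5 + 0.5).astype(int)


def sfe(v: np.ndarray) -> np.ndarray:
    """Samples Features Extraction: first, last and 4 equally spaced samples.

    Picks v[round(k*(m-1)/5)] for k = 0..5, so the endpoints anchor the grid
    and the four interior samples are equally spaced between them.
    """
    v = np.asarray(v, dtype=float)
    m = v.shape[0]
    if m < 6:
        raise ValueError("SFE needs at least 6 samples")
    return v[_sfe_indices(m)]


def dft_magnitude(v: np.ndarray) -> np.ndarray:
    """Magnitude of the full discrete Fourier transform, same length as input."""
    v = np.asarray(v, dtype=float)
    if v.size < 1:
        raise ValueError("DFT of an empty vector")
    return np.abs(np.fft.fft(v))


def _quarter_features(q: np.ndarray) -> np.ndarray:
    mag = dft_magnitude(q)
    return np.concatenate([fsc(q), sfe(q), fsc(mag), sfe(mag)])


def extract_features(beat: Beat | np.ndarray, label: str | None = None) -> FeatureVector:
    """Build the 80-dimensional feature vector of one (normalized) beat."""
    if isinstance(beat, Beat):
        samples, lab = beat.samples, beat.label
    else:
        samples = np.asarray(beat, dtype=float)
        lab = label if label is not None else CLASS_ORDER[0]
    quarters = quarter(samples)
    values = np.concatenate([_quarter_features(q) for q in quarters])
    return FeatureVector(values=values, label=lab)


def extract_dataset(beats: BeatMatrix) -> FeatureDataset:
    """Featurize every row of a BeatMatrix into a FeatureDataset."""
    if beats.n_beats == 0:
        return FeatureDataset(matrix=np.empty((0, N_FEATURES)),
                              labels=np.array([], dtype=object))
    rows = [extract_features(row, label=str(lab)).values
            for row, lab in zip(beats.matrix, beats.labels)]
    return FeatureDataset(matrix=np.array(rows), labels=beats.labels.copy())
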