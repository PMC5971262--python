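"""Synthetic test data: 360 Hz beat waveforms and 80-d Gaussian feature sets.

Two generators make every pipeline stage testable without any download:

* :func:`generate_beats` emits an ECG-like stream at 360 Hz in which each
  beat is a sum of Gaussian bumps (P, Q, R, S, T waves) with class-dependent
  morphology, plus white noise.  The normal class (NB) has a P wave and a
  narrow QRS (< 120 ms); the PVC class has no P wave, a wide QRS (> 120 ms
  at half the R amplitude) and an enlarged T wave; the "other" class (OB) is
  a perturbed morphology in between (no P wave, reduced R, inverted T).
  Annotated R-peak indices are returned alongside, so the stream plugs
  straight into segmentation — or can be written out in WFDB form.

* :func:`generate_features` draws class-conditional multivariate-normal
  samples in feature space, for testing the outlier filter, the classifiers
  and the evaluation protocol against known ground truth.

Both are bit-reproducible given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureDataset, N_FEATURES
from .wfdb_io import NB, OB, PVC, BeatAnnotation, ECGRecord

__all__ = [
    "WaveComponent",
    "ClassMorphology",
    "WaveformSpec",
    "FeatureSpaceSpec",
    "generate_beats",
    "generate_features",
    "well_separated_feature_spec",
]

FS_DEFAULT = 360.0


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian bump: amplitude (mV), center offset from R (s), width (s)."""

    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("wave width must be positive")


@dataclass(frozen=True)
class ClassMorphology:
    """P/Q/R/S/T bump parameters for one beat class."""

    waves: tuple[WaveComponent, ...]

    def render(self, t: np.ndarray) -> np.ndarray:
        out = np.zeros_like(t)
        for w in self.waves:
            out += w.amplitude * np.exp(-0.5 * ((t - w.center) / w.width) ** 2)
        return out


# Default morphologies.  NB: full PQRST, narrow QRS, upright T.  PVC: no P,
# wide high-amplitude R (half-amplitude width ~0.14 s > 0.12 s), deep wide S,
# enlarged T.  OB: no P, smaller narrow R, inverted T (a bundle-branch-like
# "other" shape distinct from both).
_DEFAULT_MORPHOLOGY: dict[str, ClassMorphology] = {
    NB: ClassMorphology(waves=(
        WaveComponent(0.15, -0.16, 0.025),   # P
        WaveComponent(-0.10, -0.030, 0.010), # Q
        WaveComponent(1.00, 0.0, 0.012),     # R
        WaveComponent(-0.15, 0.030, 0.010),  # S
        WaveComponent(0.30, 0.26, 0.060),    # T
    )),
    PVC: ClassMorphology(waves=(
        WaveComponent(1.20, 0.0, 0.060),     # wide R, FWHM ~0.141 s
        WaveComponent(-0.40, 0.11, 0.030),   # deep S
        WaveComponent(0.60, 0.30, 0.090),    # enlarged T
    )),
    OB: ClassMorphology(waves=(
        WaveComponent(-0.15, -0.035, 0.012), # Q
        WaveComponent(0.70, 0.0, 0.020),     # R
        WaveComponent(-0.30, 0.045, 0.015),  # S
        WaveComponent(-0.25, 0.27, 0.055),   # inverted T
    )),
}


@dataclass(frozen=True)
class WaveformSpec:
    """Generator settings for the Gaussian-bump beat stream."""

    fs: float = FS_DEFAULT
    morphology: dict[str, ClassMorphology] = field(
        default_factory=lambda: dict(_DEFAULT_MORPHOLOGY))
    rr_seconds: float = 0.8
    jitter_sd_seconds: float = 0.005
    noise_sd: float = 0.02
    amplitude_jitter: float = 0.05

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.jitter_sd_seconds < 0 or self.noise_sd < 0:
            raise ValueError("jitter and noise SDs must be non-negative")


def generate_beats(
    spec: WaveformSpec,
    counts: dict[str, int],
    seed: int = 0,
) -> tuple[ECGRecord, list[BeatAnnotation]]:
    """Generate an annotated ECG-like stream with the requested beat counts.

    Beats of the requested classes are interleaved in a seeded random order
    at a regular RR interval.  Returns the record and the R-peak
    annotations (symbols 'N'/'V'/'L' for NB/PVC/OB).
    """
    for cls, n in counts.items():
        if cls not in spec.morphology:
            raise ValueError(f"no morphology defined for class {cls!r}")
        if n < 1:
            raise ValueError(f"count for class {cls!r} must be >= 1")
    rng = np.random.default_rng(seed)
    order = [cls for cls in sorted(counts) for _ in range(counts[cls])]
    rng.shuffle(order)
    fs = spec.fs
    rr_n = int(round(spec.rr_seconds * fs))
    pad_n = int(round(0.7 * fs))  # breathing room at both ends
    n_beats = len(order)
    n_total = 2 * pad_n + (n_beats - 1) * rr_n + 1
    t_axis = np.arange(n_total) / fs
    signal = np.zeros(n_total)
    symbol_of = {NB: "N", PVC: "V", OB: "L"}
    annotations: list[BeatAnnotation] = []
    for b, cls in enumerate(order):
        center_idx = pad_n + b * rr_n
        jitter = rng.normal(0.0, spec.jitter_sd_seconds) if spec.jitter_sd_seconds else 0.0
        amp = 1.0 + (rng.normal(0.0, spec.amplitude_jitter) if spec.amplitude_jitter else 0.0)
        t_rel = t_axis - (center_idx / fs + jitter)
        signal += amp * spec.morphology[cls].render(t_rel)
        r_idx = center_idx + int(round(jitter * fs))
        annotations.append(BeatAnnotation(sample_index=r_idx, symbol=symbol_of[cls]))
    if spec.noise_sd:
        signal += rng.normal(0.0, spec.noise_sd, size=n_total)
    record = ECGRecord(record_id=f"synthetic-{seed}", fs=fs, signal=signal)
    return record, sorted(annotations, key=lambda a: a.sample_index)


@dataclass(frozen=True)
class FeatureSpaceSpec:
    """Class-conditional Gaussian spec: per-class mean, covariance, count."""

    means: dict[str, np.ndarray]
    covariances: dict[str, np.ndarray]
    counts: dict[str, int]

    def __post_init__(self) -> None:
        for cls, n in self.counts.items():
            if n < 2:
                raise ValueError(f"count for class {cls!r} must be >= 2")
            if cls not in self.means or cls not in self.covariances:
                raise ValueError(f"class {cls!r} missing a mean or covariance")


def generate_features(spec: FeatureSpaceSpec, seed: int = 0) -> FeatureDataset:
    """Draw class-by-class multivariate-normal feature rows."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for cls in sorted(spec.counts):
        mean = np.asarray(spec.means[cls], dtype=float)
        cov = np.asarray(spec.covariances[cls], dtype=float)
        if cov.ndim == 1:
            cov = np.diag(cov)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"covariance for class {cls!r} is not positive "
                             "definite") from exc
        X = rng.multivariate_normal(mean, cov, size=spec.counts[cls],
                                    method="cholesky")
        rows.append(X)
        labels.extend([cls] * spec.counts[cls])
    return FeatureDataset(matrix=np.vstack(rows),
                          labels=np.array(labels, dtype=object))


def well_separated_feature_spec(
    n_per_class: int = 300,
    dim: int = N_FEATURES,
    separation: float = 10.0,
    classes: tuple[str, ...] = (NB, OB, PVC),
) -> FeatureSpaceSpec:
    """Unit-variance Gaussian classes with means `separation` SDs apart.

    Convenience spec for separability tests: class k's mean is `separation`
    along coordinate k, all covariances identity.
    """
    means = {cls: np.zeros(dim) for cls in classes}
    for k, cls in enumerate(classes):
        means[cls][k] = separation
    covs = {cls: np.ones(dim) for cls in classes}
    counts = {cls: n_per_class for cls in classes}
    return FeatureSpaceSpec(means=means, covariances=covs, counts=counts)
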