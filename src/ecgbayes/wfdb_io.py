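"""Reading and writing WFDB records and beat annotations (MIT-BIH dialect).

Supports the subset of the WFDB family that the MIT-BIH Arrhythmia Database
uses: ``.hea`` headers, format-212 packed ``.dat`` signals (two 12-bit
two's-complement samples in three bytes) and MIT-format ``.atr`` annotation
streams.  Amplitudes are returned in physical units (mV) via the per-signal
gain and baseline from the header.

Beat labels follow the three-class scheme used throughout this package:
``'N'`` stays a normal beat (NB), ``'V'`` stays a premature ventricular
contraction (PVC), and every other *beat* symbol collapses to "other beat"
(OB).  Non-beat markers (rhythm changes, signal-quality flags) are never
beats and are rejected by :func:`map_symbol`.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ECGRecord",
    "BeatAnnotation",
    "NB",
    "PVC",
    "OB",
    "CLASS_ORDER",
    "BEAT_SYMBOLS",
    "map_symbol",
    "read_record",
    "read_annotations",
    "write_record",
    "write_annotations",
    "annotations_to_table",
]

NB = "NB"
PVC = "PVC"
OB = "OB"
#: Fixed class order used for priors, confusion matrices and tie-breaking.
CLASS_ORDER = (NB, OB, PVC)

# MIT annotation code <-> symbol table (codes 1..49 of the standard map).
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}

#: Annotation symbols that mark a QRS complex (a beat), per the standard map.
BEAT_SYMBOLS = frozenset("NLRBAaJSVrFejn/fQ?E")

# Special annotation codes in the MIT format.
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass(frozen=True)
class ECGRecord:
    """One channel of an ECG record, in physical units.

    Attributes
    ----------
    record_id : str
        Record name (header base name).
    fs : float
        Sampling rate in Hz.
    signal : numpy.ndarray
        1-D array of amplitudes in mV for the selected channel.
    """

    record_id: str
    fs: float
    signal: np.ndarray

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "signal", sig)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if sig.ndim != 1:
            raise ValueError("signal must be one-dimensional")
        if not np.all(np.isfinite(sig)):
            raise ValueError("signal contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]


@dataclass(frozen=True)
class BeatAnnotation:
    """A single annotated beat: R-peak sample index, symbol and class label."""

    sample_index: int
    symbol: str
    label: str = field(default="")

    def __post_init__(self) -> None:
        if self.sample_index < 0:
            raise ValueError("sample_index must be non-negative")
        if not self.label:
            object.__setattr__(self, "label", map_symbol(self.symbol))
        elif self.label not in CLASS_ORDER:
            raise ValueError(f"unknown label {self.label!r}")


def map_symbol(symbol: str) -> str:
    """Map a beat annotation symbol to one of the three classes.

    ``'N'`` -> NB, ``'V'`` -> PVC, any other beat symbol -> OB.  Non-beat
    symbols (rhythm changes, noise flags, ...) raise ``ValueError``: callers
    must pre-filter to beat annotations.
    """
    if symbol not in BEAT_SYMBOLS:
        raise ValueError(f"{symbol!r} is not a beat annotation symbol")
    if symbol == "N":
        return NB
    if symbol == "V":
        return PVC
    return OB


# ---------------------------------------------------------------------------
# Header parsing
# ---------------------------------------------------------------------------

def _parse_header(hea_path: Path):
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ValueError(f"empty header file {hea_path}")
    top = lines[0].split()
    if len(top) < 3:
        raise ValueError(f"corrupt header line {lines[0]!r} in {hea_path}")
    record_id = top[0].split("/")[0]
    n_sig = int(top[1])
    fs = float(top[2].split("/")[0])
    n_samples = int(top[3]) if len(top) > 3 else None
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        if len(tok) < 3:
            raise ValueError(f"corrupt signal line {ln!r} in {hea_path}")
        fname, fmt = tok[0], tok[1]
        gain_spec = tok[2]
        # gain may carry "(baseline)/units", e.g. "200(1024)/mV"
        units = "mV"
        if "/" in gain_spec:
            gain_spec, units = gain_spec.split("/", 1)
        baseline = None
        if "(" in gain_spec:
            gain_spec, rest = gain_spec.split("(", 1)
            baseline = int(rest.rstrip(")"))
        gain = float(gain_spec) if gain_spec else 200.0
        if gain == 0:
            gain = 200.0
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        signals.append(
            {"file": fname, "format": fmt.split("x")[0], "gain": gain,
             "baseline": baseline, "units": units}
        )
    if len(signals) != n_sig:
        raise ValueError(f"header {hea_path} declares {n_sig} signals, "
                         f"found {len(signals)} signal lines")
    return record_id, fs, n_samples, signals


def _read_dat_212(path: Path, n_sig: int) -> np.ndarray:
    raw = np.frombuffer(path.read_bytes(), dtype=np.uint8)
    n_triplets = raw.size // 3
    raw = raw[: n_triplets * 3].reshape(-1, 3).astype(np.int32)
    s1 = raw[:, 0] | ((raw[:, 1] & 0x0F) << 8)
    s2 = raw[:, 2] | ((raw[:, 1] & 0xF0) << 4)
    samples = np.empty(2 * n_triplets, dtype=np.int32)
    samples[0::2], samples[1::2] = s1, s2
    samples[samples > 2047] -= 4096  # 12-bit two's complement
    n_frames = samples.size // n_sig
    return samples[: n_frames * n_sig].reshape(n_frames, n_sig)


def _read_dat_16(path: Path, n_sig: int) -> np.ndarray:
    samples = np.frombuffer(path.read_bytes(), dtype="<i2").astype(np.int32)
    n_frames = samples.size // n_sig
    return samples[: n_frames * n_sig].reshape(n_frames, n_sig)


def read_record(path: str | Path, channel: int = 0) -> ECGRecord:
    """Read one channel of a WFDB record as an :class:`ECGRecord` in mV.

    Parameters
    ----------
    path : path-like
        Path to the record, with or without the ``.hea`` extension.
    channel : int
        Zero-based signal index (default 0, the MLII lead in most MIT-BIH
        records).
    """
    path = Path(path)
    hea_path = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea_path.exists():
        raise FileNotFoundError(f"header file not found: {hea_path}")
    record_id, fs, n_samples, signals = _parse_header(hea_path)
    n_sig = len(signals)
    if not 0 <= channel < n_sig:
        raise IndexError(
            f"channel {channel} out of range for record with {n_sig} signals"
        )
    sig_info = signals[channel]
    dat_path = hea_path.parent / sig_info["file"]
    if not dat_path.exists():
        raise FileNotFoundError(f"signal file not found: {dat_path}")
    fmt = sig_info["format"]
    if fmt == "212":
        adc = _read_dat_212(dat_path, n_sig)
    elif fmt == "16":
        adc = _read_dat_16(dat_path, n_sig)
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt!r}")
    if n_samples is not None:
        if adc.shape[0] < n_samples:
            raise ValueError(
                f"signal file {dat_path} holds {adc.shape[0]} frames but the "
                f"header declares {n_samples}"
            )
        adc = adc[:n_samples]
    physical = (adc[:, channel] - sig_info["baseline"]) / sig_info["gain"]
    return ECGRecord(record_id=record_id, fs=fs, signal=physical)


def write_record(
    path: str | Path,
    signals: np.ndarray,
    fs: float,
    gain: float = 200.0,
    baseline: int = 0,
) -> None:
    """Write a multichannel signal as a WFDB format-212 record.

    ``signals`` is (n_samples, n_sig) in mV; samples are quantized with the
    given gain (adu/mV) and clipped to the 12-bit range, mirroring the
    11-bit-over-10-mV digitization of the source database.
    """
    path = Path(path)
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[0] < signals.shape[1]:
        signals = signals.T
    n_samples, n_sig = signals.shape
    adc = np.clip(np.rint(signals * gain) + baseline, -2048, 2047).astype(np.int32)
    record_id = path.stem
    dat_name = record_id + ".dat"
    flat = adc.reshape(-1)
    if flat.size % 2:
        flat = np.concatenate([flat, [0]])
    u = np.where(flat < 0, flat + 4096, flat).astype(np.uint32)
    s1, s2 = u[0::2], u[1::2]
    packed = np.empty((s1.size, 3), dtype=np.uint8)
    packed[:, 0] = s1 & 0xFF
    packed[:, 1] = ((s1 >> 8) & 0x0F) | (((s2 >> 8) & 0x0F) << 4)
    packed[:, 2] = s2 & 0xFF
    (path.parent / dat_name).write_bytes(packed.tobytes())
    lines = [f"{record_id} {n_sig} {fs:g} {n_samples}"]
    for _ in range(n_sig):
        lines.append(f"{dat_name} 212 {gain:g}({baseline})/mV 12 {baseline} 0 0 0 ECG")
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# MIT annotation format
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> list[BeatAnnotation]:
    """Read an MIT-format annotation file, keeping beat annotations only.

    Returns annotations sorted by sample index.  Non-beat markers (rhythm
    changes ``'+'``, quality flags, aux notes) are skipped.
    """
    path = Path(path)
    if path.suffix != ".atr" and not path.exists():
        path = path.with_suffix(".atr")
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    data = path.read_bytes()
    if len(data) % 2:
        raise ValueError(f"corrupt annotation stream (odd byte count): {path}")
    out: list[BeatAnnotation] = []
    t = 0
    i = 0
    while i + 2 <= len(data):
        (word,) = struct.unpack_from("<H", data, i)
        i += 2
        code = word >> 10
        a = word & 0x3FF
        if word == 0:  # EOF
            break
        if code == _SKIP:
            if i + 4 > len(data):
                raise ValueError(f"corrupt annotation stream (truncated SKIP): {path}")
            (hi,) = struct.unpack_from("<H", data, i)
            (lo,) = struct.unpack_from("<H", data, i + 2)
            i += 4
            t += (hi << 16) | lo
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += a + (a & 1)  # aux string, padded to even length
            continue
        symbol = _CODE_TO_SYMBOL.get(code)
        if symbol is None:
            raise ValueError(
                f"corrupt annotation stream (unknown code {code}): {path}"
            )
        t += a
        if symbol in BEAT_SYMBOLS:
            out.append(BeatAnnotation(sample_index=t, symbol=symbol))
    out.sort(key=lambda ann: ann.sample_index)
    return out


def write_annotations(path: str | Path, annotations: list[BeatAnnotation]) -> None:
    """Write annotations in the MIT format (sorted, with SKIP for long gaps)."""
    path = Path(path)
    anns = sorted(annotations, key=lambda a: a.sample_index)
    buf = bytearray()
    t = 0
    for ann in anns:
        code = _SYMBOL_TO_CODE.get(ann.symbol)
        if code is None:
            raise ValueError(f"symbol {ann.symbol!r} has no MIT annotation code")
        delta = ann.sample_index - t
        if delta < 0:
            raise ValueError("annotations out of order after sorting")
        if delta >= 1024:
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<H", (delta >> 16) & 0xFFFF)
            buf += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        buf += struct.pack("<H", (code << 10) | delta)
        t = ann.sample_index
    buf += struct.pack("<H", 0)  # EOF
    path.write_bytes(bytes(buf))


def annotations_to_table(record_id: str, annotations: list[BeatAnnotation]):
    """Tabulate annotations as a DataFrame (record_id, sample_index, symbol, label)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "record_id": record_id,
            "sample_index": [a.sample_index for a in annotations],
            "symbol": [a.symbol for a in annotations],
            "label": [a.label for a in annotations],
        }
    )
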