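"""Anatomy of the 80-dimensional beat descriptor.

Takes one synthetic normal beat, splits it into quarters and prints the 20
features of the first quarter: FSC (mean, sample SD, max, min) and SFE (6
anchored samples) of the quarter itself, then the same two summaries of its
DFT magnitude spectrum.  Four quarters x 20 features = 80.
"""

import numpy as np

from ecgbayes import (
    WaveformSpec, dft_magnitude, extract_features, fsc,
    generate_beats, quarter, sfe,
)
from ecgbayes.beats import segment_record

record, anns = generate_beats(WaveformSpec(noise_sd=0.0), {"NB": 3}, seed=0)
beats = segment_record(record, anns)
beat = beats.matrix[1]  # middle beat, clean window
print(f"beat: {beat.size} samples (72 before R, R, 165 after), "
      f"mean-range normalized (mean {beat.mean():+.1e}, range "
      f"{beat.max() - beat.min():.3f})")

quarters = quarter(beat)
print(f"quarter lengths: {[len(q) for q in quarters]}")

q1 = quarters[0]
print("\nquarter 1, time domain:")
print(f"  FSC  (mean, sd, max, min) = {np.round(fsc(q1), 4)}")
print(f"  SFE  (6 anchored samples) = {np.round(sfe(q1), 4)}")
mag = dft_magnitude(q1)
print("quarter 1, DFT magnitude:")
print(f"  FSC = {np.round(fsc(mag), 4)}")
print(f"  SFE = {np.round(sfe(mag), 4)}")

fv = extract_features(beat, label="NB")
assert np.allclose(fv.values[:20],
                   np.concatenate([fsc(q1), sfe(q1), fsc(mag), sfe(mag)]))
print(f"\nfull vector: {fv.values.size} features; the first 20 shown above "
      "are its first block.")
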