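"""Per-class Se/PPV/F1 from a test-set confusion matrix.

Builds the published 3-class confusion matrix of a QDA beat classifier
(rows = true class, columns = predicted; order NB, OB, PVC) and recomputes
sensitivity, positive predictive value and F1 for each class.  Se answers
"what fraction of true beats of this class did we find", PPV "when we call
this class, how often are we right", and F1 is their harmonic mean.
"""

import numpy as np

from ecgbayes import ConfusionMatrix, class_metrics, metrics_report

cm = ConfusionMatrix(
    counts=np.array([[8698, 78, 1],
                     [114, 3014, 14],
                     [0, 0, 769]]),
    class_order=["NB", "OB", "PVC"],
)

print(f"{cm.total} test beats\n")
print(f"{'class':>5}  {'Se':>6}  {'PPV':>6}  {'F1':>6}")
for cls in cm.class_order:
    se, ppv, f1 = class_metrics(cm, cls)
    print(f"{cls:>5}  {se:6.3f}  {ppv:6.3f}  {f1:6.3f}")

report = metrics_report(cm)
print(f"\nmacro mean F1 = {report.macro_mean_f1:.3f}")
print("Every PVC row count off the diagonal is zero, so Se(PVC) = 1:")
print("no premature ventricular beat in the test set was missed.")
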