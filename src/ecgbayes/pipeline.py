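"""End-to-end pipeline: beats -> features -> outlier filter -> CV model
selection -> held-out evaluation.

Mirrors the full experiment: segment annotated beats, extract the 80-d
feature vector, drop Mahalanobis/chi-square outliers, split 70/15/15,
select among GNB/LDA/QDA by 10-fold cross-validated mean-of-means F1 on
train+validation, then refit the winner and score the untouched test set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beats import POST_SECONDS, PRE_SECONDS, segment_record
from .evaluation import (
    MetricsReport,
    cross_validate,
    final_evaluation,
    make_cv_plan,
    make_split,
    select_model,
)
from .features import FeatureDataset, extract_dataset
from .models import KINDS
from .outliers import OutlierReport, filter_outliers
from .wfdb_io import BeatAnnotation, ECGRecord

__all__ = ["PipelineResult", "featurize_record", "run_experiment"]


@dataclass
class PipelineResult:
    selected_kind: str
    cv_scores: dict[str, float]          # kind -> mean-of-means F1
    test_report: MetricsReport
    outlier_report: OutlierReport
    n_beats_in: int
    n_beats_kept: int


def featurize_record(
    record: ECGRecord,
    annotations: list[BeatAnnotation],
    pre_s: float = PRE_SECONDS,
    post_s: float = POST_SECONDS,
) -> FeatureDataset:
    """Segment, normalize and featurize every annotated beat of a record."""
    beats = segment_record(record, annotations, pre_s=pre_s, post_s=post_s)
    return extract_dataset(beats)


def run_experiment(
    data: FeatureDataset,
    candidates: tuple[str, ...] = KINDS,
    outlier_quantile: float = 0.975,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    n_folds: int = 10,
    seed: int = 0,
    apply_outlier_filter: bool = True,
) -> PipelineResult:
    """Run the full selection-and-evaluation protocol on a feature dataset."""
    n_in = data.n_samples
    if apply_outlier_filter:
        data, outlier_report = filter_outliers(data, quantile=outlier_quantile)
    else:
        outlier_report = OutlierReport(
            kept_indices=np.arange(n_in), removed_indices=np.array([], dtype=int),
            threshold=float("inf"), distances=np.zeros(n_in))
    split = make_split(data, fractions=fractions, seed=seed)
    trainval = data.subset(np.concatenate([split.train_idx, split.val_idx]))
    cv = make_cv_plan(trainval, n_folds=n_folds, seed=seed)
    selected, cv_scores = select_model(list(candidates), trainval, cv)
    test_report = final_evaluation(selected, split, data)
    return PipelineResult(
        selected_kind=selected,
        cv_scores=cv_scores,
        test_report=test_report,
        outlier_report=outlier_report,
        n_beats_in=n_in,
        n_beats_kept=data.n_samples,
    )
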