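"""Gaussian generative classifiers built from their discriminant equations.

Three Bayesian classifiers share one training recipe — empirical priors
``p(q_k) = n_k / N`` and per-class Gaussian likelihoods — and differ only in
the covariance structure:

* **GNB** (Gaussian naive Bayes): features independent, per-class diagonal
  covariance.  Score: ``sum_j log N(x_j; mu_kj, var_kj) + log p(q_k)``.
* **LDA**: one covariance pooled across classes,
  ``Sigma = sum_k (n_k - 1) S_k / (N - K)``.  The quadratic terms cancel and
  the discriminant is linear:
  ``x' Sigma^-1 mu_k - 1/2 mu_k' Sigma^-1 mu_k + log p(q_k)``.
* **QDA**: per-class full covariance.  Discriminant:
  ``-1/2 log|Sigma_k| - 1/2 (x-mu_k)' Sigma_k^-1 (x-mu_k) + log p(q_k)``.

All scoring is in the log domain; the marginal p(x) and the class-constant
``(d/2) log 2pi`` never enter the argmax and are dropped from the LDA/QDA
discriminants.  Log-determinants come from a Cholesky factorization, never
from an explicit determinant.  Ties at argmax break by the fixed class order
(NB < OB < PVC), i.e. the first maximal class wins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg

from .features import FeatureDataset
from .outliers import regularize_covariance
from .wfdb_io import CLASS_ORDER

__all__ = [
    "GNB",
    "LDA",
    "QDA",
    "KINDS",
    "GaussianClassParams",
    "ClassifierModel",
    "fit",
    "log_scores",
    "predict",
    "save_model",
    "load_model",
]

GNB, LDA, QDA = "GNB", "LDA", "QDA"
KINDS = (GNB, LDA, QDA)

_SERIAL_VERSION = 1

#: Variance floor for GNB, relative to the largest per-feature variance.
VAR_FLOOR_REL = 1e-9


@dataclass
class GaussianClassParams:
    class_label: str
    prior: float
    mean: np.ndarray
    covariance: np.ndarray | None  # diagonal vector (GNB), full (QDA), None (LDA)


@dataclass
class ClassifierModel:
    kind: str
    classes: list[str]
    params: list[GaussianClassParams]
    shared_covariance: np.ndarray | None = None
    feature_dim: int = 0
    # Cholesky caches, rebuilt lazily; never serialized.
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def class_index(self, label: str) -> int:
        return self.classes.index(label)


def _canonical_class_order(labels: np.ndarray) -> list[str]:
    present = sorted(set(labels.astype(str).tolist()))
    if set(present) <= set(CLASS_ORDER):
        return [c for c in CLASS_ORDER if c in present]
    return present


def fit(kind: str, train: FeatureDataset) -> ClassifierModel:
    """Fit a GNB, LDA or QDA model on a labeled feature dataset."""
    if kind not in KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}")
    X = train.matrix
    labels = train.labels.astype(str)
    classes = _canonical_class_order(train.labels)
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    N, d = X.shape
    params: list[GaussianClassParams] = []
    pooled = np.zeros((d, d)) if kind == LDA else None
    global_max_var = max(X.var(axis=0, ddof=1).max(), np.finfo(float).tiny)
    for cls in classes:
        Xc = X[labels == cls]
        n_c = Xc.shape[0]
        if n_c < 2:
            raise ValueError(f"class {cls!r} needs at least 2 training samples")
        mean = Xc.mean(axis=0)
        prior = n_c / N
        if kind == GNB:
            var = Xc.var(axis=0, ddof=1)
            floor = VAR_FLOOR_REL * global_max_var
            var = np.maximum(var, floor)
            cov = var
        elif kind == QDA:
            cov = regularize_covariance(np.cov(Xc, rowvar=False, ddof=1))
        else:  # LDA: accumulate pooled scatter
            centered = Xc - mean
            pooled += centered.T @ centered
            cov = None
        params.append(GaussianClassParams(class_label=cls, prior=prior,
                                          mean=mean, covariance=cov))
    shared = None
    if kind == LDA:
        shared = regularize_covariance(pooled / (N - len(classes)))
    model = ClassifierModel(kind=kind, classes=classes, params=params,
                            shared_covariance=shared, feature_dim=d)
    # fail fast if any training score would be non-finite
    if not np.all(np.isfinite(log_scores(model, X[: min(N, 5)]))):
        raise ValueError("degenerate covariance: non-finite training scores")
    return model


def _chol_logdet(sigma: np.ndarray):
    try:
        L = linalg.cholesky(sigma, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("covariance not positive definite after "
                         "regularization") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return L, logdet


def _model_cache(model: ClassifierModel) -> dict:
    cache = model._cache
    if cache:
        return cache
    if model.kind == LDA:
        L, _ = _chol_logdet(model.shared_covariance)
        means = np.array([p.mean for p in model.params])
        # Sigma^-1 mu_k for every class, via triangular solves
        inv_mu = linalg.cho_solve((L, True), means.T)  # (d, K)
        cache["inv_mu"] = inv_mu
        cache["const"] = np.array(
            [-0.5 * m @ inv_mu[:, k] + np.log(p.prior)
             for k, (m, p) in enumerate(zip(means, model.params))]
        )
    elif model.kind == QDA:
        chols, consts = [], []
        for p in model.params:
            L, logdet = _chol_logdet(p.covariance)
            chols.append(L)
            consts.append(-0.5 * logdet + np.log(p.prior))
        cache["chols"] = chols
        cache["const"] = np.array(consts)
    else:  # GNB
        var = np.array([p.covariance for p in model.params])  # (K, d)
        cache["var"] = var
        cache["log_norm"] = -0.5 * np.sum(np.log(2.0 * np.pi * var), axis=1)
        cache["log_prior"] = np.array([np.log(p.prior) for p in model.params])
    return cache


def log_scores(model: ClassifierModel, x: np.ndarray) -> np.ndarray:
    """Per-class discriminant values, in the model's class order.

    ``x`` may be one 1-D vector (returns shape (K,)) or an (n, d) matrix
    (returns (n, K)).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.feature_dim:
        raise ValueError(
            f"expected {model.feature_dim} features, got {X.shape[1]}")
    cache = _model_cache(model)
    K = len(model.classes)
    scores = np.empty((X.shape[0], K))
    if model.kind == GNB:
        for k, p in enumerate(model.params):
            diff = X - p.mean
            scores[:, k] = (cache["log_norm"][k]
                            - 0.5 * np.sum(diff**2 / cache["var"][k], axis=1)
                            + cache["log_prior"][k])
    elif model.kind == LDA:
        scores = X @ cache["inv_mu"] + cache["const"]
    else:  # QDA
        for k, p in enumerate(model.params):
            diff = (X - p.mean).T
            z = linalg.solve_triangular(cache["chols"][k], diff, lower=True)
            scores[:, k] = cache["const"][k] - 0.5 * np.sum(z**2, axis=0)
    return scores[0] if single else scores


def predict(model: ClassifierModel, x: np.ndarray) -> str | np.ndarray:
    """Argmax-class of the discriminant scores; ties go to the first class."""
    scores = log_scores(model, x)
    if scores.ndim == 1:
        return model.classes[int(np.argmax(scores))]
    idx = np.argmax(scores, axis=1)
    return np.array([model.classes[i] for i in idx], dtype=object)


# ---------------------------------------------------------------------------
# Serialization: versioned JSON with exact float round-trip
# ---------------------------------------------------------------------------

def save_model(model: ClassifierModel, path: str | Path | None = None) -> str:
    """Serialize a model to versioned JSON text (and optionally a file).

    Python's repr-based JSON float encoding round-trips IEEE doubles
    exactly, so a save/load cycle reproduces scores bit for bit.
    """
    payload = {
        "format": "ecgbayes-model",
        "version": _SERIAL_VERSION,
        "kind": model.kind,
        "classes": model.classes,
        "feature_dim": model.feature_dim,
        "params": [
            {
                "class_label": p.class_label,
                "prior": p.prior,
                "mean": p.mean.tolist(),
                "covariance": None if p.covariance is None else p.covariance.tolist(),
            }
            for p in model.params
        ],
        "shared_covariance": (None if model.shared_covariance is None
                              else model.shared_covariance.tolist()),
    }
    text = json.dumps(payload)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_model(source: str | Path) -> ClassifierModel:
    """Inverse of :func:`save_model`; accepts a JSON string or a file path."""
    text = source
    if isinstance(source, Path) or (isinstance(source, str)
                                    and not source.lstrip().startswith("{")):
        text = Path(source).read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt model payload: {exc}") from exc
    if payload.get("format") != "ecgbayes-model":
        raise ValueError("not an ecgbayes model payload")
    if payload.get("version") != _SERIAL_VERSION:
        raise ValueError(f"unsupported model version {payload.get('version')!r}")
    kind = payload["kind"]
    if kind not in KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}")
    params = [
        GaussianClassParams(
            class_label=p["class_label"],
            prior=p["prior"],
            mean=np.array(p["mean"], dtype=float),
            covariance=(None if p["covariance"] is None
                        else np.array(p["covariance"], dtype=float)),
        )
        for p in payload["params"]
    ]
    shared = payload["shared_covariance"]
    return ClassifierModel(
        kind=kind,
        classes=list(payload["classes"]),
        params=params,
        shared_covariance=None if shared is None else np.array(shared, dtype=float),
        feature_dim=int(payload["feature_dim"]),
    )
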