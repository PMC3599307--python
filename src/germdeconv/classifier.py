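"""Soft-margin SVM classifier over gonadal time-course features.

The model minimises ``1/2 ||beta||^2 + C * sum(zeta_i)`` subject to
``y_i (beta' phi(x_i) + beta_0) >= 1 - zeta_i`` with a choice of kernel
(linear, polynomial, sigmoid, radial basis ``K(x_i, x_j) =
exp(-gamma ||x_i - x_j||^2)``).  Features are the per-time-point log2
expression values of each gene; probability outputs come from Platt sigmoid
calibration fitted within training.  Model selection is a grid search over
(kernel, gamma, C) scored by the mean ROC AUC of repeated stratified k-fold
cross-validation.

The quadratic program is solved by :class:`sklearn.svm.SVC`; this module
owns feature extraction, scaling, the CV protocol and determinism contracts.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .curation import TrainingSet
from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

KERNELS = ("linear", "polynomial", "sigmoid", "radial")

#: map this package's kernel names onto sklearn's
_SKLEARN_KERNEL = {
    "linear": "linear",
    "polynomial": "poly",
    "sigmoid": "sigmoid",
    "radial": "rbf",
}

#: published optima for the two gonad models — sensible radial defaults
SPERMATOCYTE_PARAMS = {"kernel": "radial", "gamma": 8.0, "C": 2.0}
OOCYTE_PARAMS = {"kernel": "radial", "gamma": 1.0, "C": 2048.0}


@dataclass
class SVMConfig:
    kernel: str = "radial"
    gamma: float = 1.0
    C: float = 1.0
    degree: int = 3
    coef0: float = 0.0
    scale_features: bool = True

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}, got {self.kernel!r}")
        if self.kernel == "radial" and not self.gamma > 0:
            raise ValueError("gamma must be > 0 for the radial kernel")
        if not self.C > 0:
            raise ValueError("C must be > 0")

    def to_dict(self) -> dict:
        return {
            "kernel": self.kernel, "gamma": self.gamma, "C": self.C,
            "degree": self.degree, "coef0": self.coef0,
            "scale_features": self.scale_features,
        }


@dataclass
class CVSpec:
    """Repeated stratified k-fold cross-validation protocol."""

    n_folds: int = 5
    n_repeats: int = 100
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class FittedModel:
    """A trained SVM plus the feature-scaling statistics it was fit with."""

    svc: SVC
    config: SVMConfig
    feature_names: list[str]
    scale_mean: np.ndarray
    scale_std: np.ndarray
    training_genes: list[str] = field(default_factory=list)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self._transform(X))

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scale_mean) / self.scale_std


def extract_features(
    matrix: ExpressionMatrix, genes: Iterable[str] | None = None
) -> pd.DataFrame:
    """Feature table: one row per gene, one column per matrix sample."""
    feats = matrix.values if genes is None else matrix.subset_genes(genes).values
    return feats


def _make_svc(config: SVMConfig, seed: int) -> SVC:
    with warnings.catch_warnings():
        # sklearn 1.9 deprecation chatter about probability=True; the Platt
        # calibration it provides is exactly the behaviour this model wants
        warnings.simplefilter("ignore", FutureWarning)
        return SVC(
            kernel=_SKLEARN_KERNEL[config.kernel],
            gamma=config.gamma,
            C=config.C,
            degree=config.degree,
            coef0=config.coef0,
            probability=True,
            random_state=np.random.RandomState(seed),
        )


def _fit_svc(svc: SVC, X: np.ndarray, y: np.ndarray) -> SVC:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        svc.fit(X, y)
    return svc


def _scaling(X: np.ndarray, enabled: bool) -> tuple[np.ndarray, np.ndarray]:
    if not enabled:
        return np.zeros(X.shape[1]), np.ones(X.shape[1])
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0  # constant feature: pass through centred
    return mean, std


def fit(
    train: TrainingSet,
    features: ExpressionMatrix,
    config: SVMConfig | None = None,
    seed: int = 0,
) -> FittedModel:
    """Fit the soft-margin SVM on the training genes' feature rows.

    Features are z-scored per column with training-set statistics before
    kernel evaluation; Platt probability calibration is fitted within
    training (its internal folds use a fixed ``seed``).
    """
    config = config or SVMConfig()
    X_df = extract_features(features, train.labels.index)
    y = train.labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    X = X_df.to_numpy(dtype=float)
    mean, std = _scaling(X, config.scale_features)
    svc = _fit_svc(_make_svc(config, seed), (X - mean) / std, y)
    return FittedModel(
        svc=svc,
        config=config,
        feature_names=list(X_df.columns),
        scale_mean=mean,
        scale_std=std,
        training_genes=list(train.labels.index),
    )


def predict_proba(model: FittedModel, features: ExpressionMatrix) -> pd.Series:
    """Per-gene probability of germ-cell expression, in [0, 1].

    Deterministic given the model; invariant to gene order.  Raises on a
    feature-dimension mismatch.
    """
    if list(features.values.columns) != model.feature_names:
        raise ValueError(
            f"feature columns {list(features.values.columns)} do not match "
            f"training features {model.feature_names}"
        )
    X = features.values.to_numpy(dtype=float)
    pos_col = int(np.flatnonzero(model.svc.classes_ == 1)[0])
    proba = model.svc.predict_proba(model._transform(X))[:, pos_col]
    return pd.Series(proba, index=features.genes, name="probability")


def _draw_folds(
    y: np.ndarray, cv: CVSpec, repeat: int, max_retries: int = 10
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold split; redrawn (bounded) if any training side is pure."""
    min_class = int(np.bincount((y == 1).astype(int)).min())
    can_stratify = cv.stratified and cv.n_folds <= min_class
    if cv.stratified and not can_stratify:
        log.info(
            "n_folds=%d exceeds the smaller class (%d); plain shuffled folds",
            cv.n_folds, min_class,
        )
    for attempt in range(max_retries):
        seed = cv.seed + 1000 * repeat + attempt
        if can_stratify:
            splitter = StratifiedKFold(cv.n_folds, shuffle=True, random_state=seed)
            folds = list(splitter.split(np.zeros_like(y), y))
        else:
            rng = np.random.default_rng(seed)
            idx = rng.permutation(len(y))
            parts = np.array_split(idx, cv.n_folds)
            folds = [
                (np.setdiff1d(idx, p, assume_unique=False), p) for p in parts
            ]
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            return folds
        log.warning("single-class fold at repeat %d; redrawing", repeat)
    raise RuntimeError("could not draw folds with both classes on the training side")


def repeated_cv(
    train: TrainingSet,
    features: ExpressionMatrix,
    config: SVMConfig | None = None,
    cv: CVSpec | None = None,
) -> pd.DataFrame:
    """Repeated stratified k-fold CV; out-of-fold probabilities per gene.

    Each training gene receives exactly one out-of-fold probability per
    repeat; the returned frame has one column per repeat plus a ``mean``
    column (the averaged score used for ranking).  Deterministic for a
    fixed ``cv.seed``.
    """
    config = config or SVMConfig()
    cv = cv or CVSpec()
    genes = train.labels.index
    X_df = extract_features(features, genes)
    y = train.labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    X = X_df.to_numpy(dtype=float)

    out = np.full((len(genes), cv.n_repeats), np.nan)
    for rep in range(cv.n_repeats):
        for tr_idx, te_idx in _draw_folds(y, cv, rep):
            mean, std = _scaling(X[tr_idx], config.scale_features)
            svc = _fit_svc(
                _make_svc(config, cv.seed + rep),
                (X[tr_idx] - mean) / std, y[tr_idx],
            )
            pos_col = int(np.flatnonzero(svc.classes_ == 1)[0])
            out[te_idx, rep] = svc.predict_proba(
                (X[te_idx] - mean) / std
            )[:, pos_col]
    result = pd.DataFrame(
        out, index=genes, columns=[f"repeat{r + 1}" for r in range(cv.n_repeats)]
    )
    result["mean"] = result.mean(axis=1)
    return result


def grid_search(
    train: TrainingSet,
    features: ExpressionMatrix,
    kernels: Iterable[str] = ("radial",),
    param_grid: dict | None = None,
    cv: CVSpec | None = None,
) -> tuple[SVMConfig, pd.DataFrame]:
    """Select (kernel, gamma, C) maximising mean cross-validated ROC AUC.

    The default grid spans C in 2^-5..2^15 and gamma in 2^-15..2^5 (powers
    of two).  Returns the winning config and the full score table.
    """
    from .evaluation import roc_auc  # local import to avoid cycle

    cv = cv or CVSpec(n_repeats=5)
    if param_grid is None:
        param_grid = {
            "C": [2.0 ** e for e in range(-5, 16, 2)],
            "gamma": [2.0 ** e for e in range(-15, 6, 2)],
        }
    kernels = list(kernels)
    if not kernels or not param_grid.get("C"):
        raise ValueError("empty grid")

    rows = []
    labels = train.labels
    for kernel in kernels:
        gammas = param_grid.get("gamma", [1.0]) if kernel != "linear" else [1.0]
        for C, gamma in product(param_grid["C"], gammas):
            config = SVMConfig(kernel=kernel, gamma=gamma, C=C)
            oof = repeated_cv(train, features, config, cv)
            aucs = [
                roc_auc(oof[col], labels)[1]
                for col in oof.columns if col.startswith("repeat")
            ]
            rows.append({
                "kernel": kernel, "gamma": gamma, "C": C,
                "mean_auc": float(np.mean(aucs)), "sd_auc": float(np.std(aucs)),
            })
    table = pd.DataFrame(rows).sort_values(
        "mean_auc", ascending=False, kind="stable"
    ).reset_index(drop=True)
    best = table.iloc[0]
    best_config = SVMConfig(
        kernel=str(best["kernel"]), gamma=float(best["gamma"]), C=float(best["C"])
    )
    return best_config, table


# ---------------------------------------------------------------------------
# model persistence (JSON; text-only deliverables)
# ---------------------------------------------------------------------------

def save_model(model: FittedModel, path, train: TrainingSet,
               features: ExpressionMatrix, seed: int = 0) -> None:
    """Persist a model as JSON: config + training data + fit seed.

    Loading refits the (small, fast) SVM deterministically from the stored
    training rows; the solver is deterministic given identical data,
    parameters and calibration seed, so the round-trip reproduces the same
    decision function without serialising solver internals.
    """
    X = extract_features(features, train.labels.index)
    payload = {
        "config": model.config.to_dict(),
        "seed": seed,
        "feature_names": list(X.columns),
        "training_genes": list(X.index),
        "labels": train.labels.loc[X.index].tolist(),
        "X": X.to_numpy(dtype=float).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> FittedModel:
    with open(path) as fh:
        payload = json.load(fh)
    config = SVMConfig(**payload["config"])
    genes = payload["training_genes"]
    labels = pd.Series(payload["labels"], index=genes, dtype=int)
    values = pd.DataFrame(
        payload["X"], index=genes, columns=payload["feature_names"]
    )
    samples = pd.DataFrame(
        {"tissue": pd.NA, "time": pd.NA, "replicate": pd.NA},
        index=values.columns,
    )
    features = ExpressionMatrix(values, samples, "log2")
    return fit(TrainingSet(labels), features, config, seed=payload["seed"])


def write_predictions(proba: pd.Series, path) -> None:
    """Prediction TSV: gene, probability, rank (1 = highest probability)."""
    df = proba.rename("probability").to_frame()
    df["rank"] = proba.rank(ascending=False, method="first").astype(int)
    df.index.name = "gene"
    df.sort_values("rank").to_csv(path, sep="\t")


def read_predictions(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df["probability"]
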