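"""Log-variance features, classification, alpha selection and evaluation.

The end-to-end pipeline mirrors the usual CSP recipe: band-pass the
epoched trials, fit (regularized) spatial filters on the training set,
project every trial through them, summarize each projected time course by
its log variance normalized over the retained filters,

    f_j = log( var(z_j) / sum_k var(z_k) ),    j = 1..2l,

and feed the ``2l`` features to a linear-kernel maximum-margin classifier
(SVM).  The regularization weight alpha of the filters is chosen by
stratified cross-validation on the training set only; the SVM's own cost
parameter is chosen by an inner 5-fold grid search.  For three or more
classes the one-versus-rest construction fits one filter bank and one
binary SVM per class and predicts by argmax of the per-class decision
values.

Everything a fitted model needs to predict (filters, penalty, linear
classifier coefficients, config echo) serializes to a single JSON
document, so models are portable and diffable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import cohen_kappa_score, confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .csp import (
    SpatialFilterSet,
    TRACE_NORMALIZED,
    class_covariance,
    rcsp_filters,
)
from .epochs import EpochedSignal
from .multiclass import OvrFilterBank, ovr_ccsp_filters, ovr_decide
from .penalty import ccsp_filters
from .preprocessing import bandpass_filter, extract_time_segment

logger = logging.getLogger("corrcsp")

__all__ = [
    "PipelineConfig",
    "Metrics",
    "Model",
    "default_alpha_grid",
    "project",
    "log_variance_features",
    "feature_matrix",
    "select_alpha",
    "fit",
    "predict",
    "predict_scores",
    "evaluate",
]


def default_alpha_grid() -> list[float]:
    """The default regularization grid: 1e-6 upward in steps of 5e-5 to 1e-3.

    Read as MATLAB colon notation ``start:step:end``; 20 values result.
    """
    return list(np.arange(1e-6, 1e-3 + 1e-12, 5e-5))


@dataclass
class PipelineConfig:
    """Everything that parameterizes a fit, echoed into every output artifact.

    ``l`` is the number of filter pairs (2l features), ``band`` the
    band-pass edges in Hz (None disables filtering, for already-filtered
    inputs), ``window`` an optional (t_start, t_end) segment in seconds.
    """

    method: str = "ccsp"  # csp | trcsp | ccsp
    alpha_grid: list[float] = field(default_factory=default_alpha_grid)
    l: int = 3
    band: tuple[float, float] | None = (8.0, 30.0)
    filter_order: int = 5
    window: tuple[float, float] | None = None
    cv_folds: int = 5
    seed: int = 0
    normalization: str = TRACE_NORMALIZED
    svm_c_grid: list[float] = field(default_factory=lambda: [0.01, 0.1, 1.0, 10.0, 100.0])

    def __post_init__(self) -> None:
        if self.method not in ("csp", "trcsp", "ccsp"):
            raise ValueError(f"unknown method {self.method!r}")
        grid = [float(a) for a in self.alpha_grid]
        if not grid or any(a < 0 for a in grid):
            raise ValueError("alpha_grid must hold at least one non-negative value")
        if sorted(grid) != grid:
            raise ValueError("alpha_grid must be sorted ascending")
        self.alpha_grid = grid
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(self.band) if self.band else None
        d["window"] = list(self.window) if self.window else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("band"):
            d["band"] = tuple(d["band"])
        if d.get("window"):
            d["window"] = tuple(d["window"])
        return cls(**d)


@dataclass
class Metrics:
    """Accuracy, class-1-positive sensitivity/specificity (two-class), kappa."""

    accuracy: float
    kappa: float
    confusion: np.ndarray
    classes: list[int]
    sensitivity: float | None = None
    specificity: float | None = None
    positive_class: int | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "confusion": np.asarray(self.confusion).tolist(),
            "classes": list(self.classes),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "positive_class": self.positive_class,
        }


# -- feature extraction ------------------------------------------------------

def project(trial: np.ndarray, filters: SpatialFilterSet) -> np.ndarray:
    """Project one ``n x c`` trial through the filters: ``Z = W trial'`` (2l x n)."""
    X = np.asarray(trial, dtype=float)
    if X.ndim != 2 or X.shape[1] != filters.n_channels:
        raise ValueError(
            f"trial shape {X.shape} incompatible with {filters.n_channels}-channel filters"
        )
    return filters.W @ X.T

def log_variance_features(Z: np.ndarray) -> np.ndarray:
    """Per-filter log of variance normalized over all filters.

    The variances enter as proportions, so ``sum_j exp(f_j) = 1`` and the
    features are invariant to rescaling the projected signal.
    """
    Z = np.asarray(Z, dtype=float)
    v = Z.var(axis=1)
    dead = np.flatnonzero(v <= 0)
    if dead.size:
        raise ValueError(f"zero-variance projected signal for filter(s) {dead.tolist()}")
    return np.log(v / v.sum())

def feature_matrix(signal: EpochedSignal, filters: SpatialFilterSet) -> np.ndarray:
    """Stack of log-variance feature vectors, one row per trial."""
    return np.array([log_variance_features(project(t, filters)) for t in signal.data])


# -- filter fitting dispatch -------------------------------------------------

def _fit_pair_filters(
    signal: EpochedSignal, pair: tuple[int, int], alpha: float, config: PipelineConfig
) -> SpatialFilterSet:
    if config.method == "ccsp":
        return ccsp_filters(signal, pair, alpha, config.l, config.normalization)
    C1 = class_covariance(signal, pair[0], config.normalization)
    C2 = class_covariance(signal, pair[1], config.normalization)
    a = 0.0 if config.method == "csp" else alpha
    fs = rcsp_filters(C1, C2, None, None, a, config.l, method=config.method)
    fs.channel_names = signal.channel_names
    return fs


def _fit_ovr_bank(
    signal: EpochedSignal, alpha: float, config: PipelineConfig
) -> OvrFilterBank:
    banks = {}
    for g in signal.classes:
        if config.method == "ccsp":
            banks[int(g)] = ovr_ccsp_filters(signal, g, alpha, config.l, config.normalization)
        else:
            # pooled-rest covariances with identity (trcsp) or no (csp) penalty
            Ct = class_covariance(signal, g, config.normalization)
            rest = [m for m in signal.classes if m != g]
            Crest = sum(class_covariance(signal, m, config.normalization).C for m in rest)
            from .csp import CovarianceEstimate

            Cr = CovarianceEstimate(
                C=Crest, class_id=-1, normalization=config.normalization,
                n_trials=sum(int((signal.labels == m).sum()) for m in rest),
            )
            a = 0.0 if config.method == "csp" else alpha
            fs = rcsp_filters(Ct, Cr, None, None, a, config.l, method=config.method)
            fs.channel_names = signal.channel_names
            banks[int(g)] = fs
    return OvrFilterBank(banks=banks)


# -- linear SVM helpers ------------------------------------------------------

def _fit_linear_svc(
    F: np.ndarray, y: np.ndarray, config: PipelineConfig, tune: bool
) -> SVC:
    """Linear-kernel SVM; cost parameter by stratified 5-fold CV when feasible."""
    counts = np.bincount(np.searchsorted(np.unique(y), y))
    folds = min(config.cv_folds, counts.min())
    if tune and folds >= 2 and len(config.svm_c_grid) > 1:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
        search = GridSearchCV(
            SVC(kernel="linear"), {"C": config.svm_c_grid}, cv=cv, n_jobs=None
        )
        search.fit(F, y)
        return search.best_estimator_
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(F, y)
    return clf


def _linear_params(clf: SVC) -> dict:
    return {
        "coef": clf.coef_.ravel().tolist(),
        "intercept": float(clf.intercept_[0]),
        "C": float(clf.C),
        "positive_class": int(clf.classes_[1]),
        "negative_class": int(clf.classes_[0]),
    }


def _linear_decision(params: dict, F: np.ndarray) -> np.ndarray:
    return F @ np.asarray(params["coef"]) + params["intercept"]


# -- model -------------------------------------------------------------------

@dataclass
class Model:
    """Frozen transform chain: preprocessing config, filters, linear classifier(s)."""

    config: PipelineConfig
    alpha: float
    classes: list[int]
    filters: SpatialFilterSet | None = None       # two-class
    bank: OvrFilterBank | None = None             # >= 3 classes
    classifier: dict | None = None                # two-class linear params
    ovr_classifiers: dict[int, dict] | None = None
    n_channels: int = 0

    @property
    def is_multiclass(self) -> bool:
        return self.bank is not None

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "alpha": self.alpha,
            "classes": self.classes,
            "n_channels": self.n_channels,
            "filters": self.filters.to_dict() if self.filters else None,
            "bank": self.bank.to_dict() if self.bank else None,
            "classifier": self.classifier,
            "ovr_classifiers": (
                {str(k): v for k, v in self.ovr_classifiers.items()}
                if self.ovr_classifiers
                else None
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Model":
        return cls(
            config=PipelineConfig.from_dict(d["config"]),
            alpha=float(d["alpha"]),
            classes=[int(c) for c in d["classes"]],
            n_channels=int(d["n_channels"]),
            filters=SpatialFilterSet.from_dict(d["filters"]) if d.get("filters") else None,
            bank=OvrFilterBank.from_dict(d["bank"]) if d.get("bank") else None,
            classifier=d.get("classifier"),
            ovr_classifiers=(
                {int(k): v for k, v in d["ovr_classifiers"].items()}
                if d.get("ovr_classifiers")
                else None
            ),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _preprocess(signal: EpochedSignal, config: PipelineConfig) -> EpochedSignal:
    if config.window is not None:
        signal = extract_time_segment(signal, *config.window)
    if config.band is not None:
        signal = bandpass_filter(signal, *config.band, order=config.filter_order)
    return signal


def _fit_at_alpha(train: EpochedSignal, alpha: float, config: PipelineConfig) -> Model:
    """Filters + classifier(s) on already-preprocessed training data."""
    classes = [int(c) for c in train.classes]
    model = Model(
        config=config, alpha=float(alpha), classes=classes, n_channels=train.n_channels
    )
    if len(classes) == 2:
        model.filters = _fit_pair_filters(train, (classes[0], classes[1]), alpha, config)
        F = feature_matrix(train, model.filters)
        clf = _fit_linear_svc(F, train.labels, config, tune=True)
        model.classifier = _linear_params(clf)
    else:
        model.bank = _fit_ovr_bank(train, alpha, config)
        model.ovr_classifiers = {}
        for g in classes:
            F = feature_matrix(train, model.bank.banks[g])
            y = (train.labels == g).astype(int)
            clf = _fit_linear_svc(F, y, config, tune=True)
            model.ovr_classifiers[g] = _linear_params(clf)
    return model


def _score_fold(
    train: EpochedSignal,
    val: EpochedSignal,
    alpha: float,
    config: PipelineConfig,
) -> float:
    """Validation accuracy of a fold fit at one alpha (fixed SVM cost)."""
    classes = [int(c) for c in train.classes]
    if len(classes) == 2:
        filters = _fit_pair_filters(train, (classes[0], classes[1]), alpha, config)
        F = feature_matrix(train, filters)
        clf = _fit_linear_svc(F, train.labels, config, tune=False)
        pred = clf.predict(feature_matrix(val, filters))
    else:
        bank = _fit_ovr_bank(train, alpha, config)
        scores = np.empty((val.n_trials, len(classes)))
        for j, g in enumerate(classes):
            F = feature_matrix(train, bank.banks[g])
            clf = _fit_linear_svc(F, (train.labels == g).astype(int), config, tune=False)
            Fv = feature_matrix(val, bank.banks[g])
            d = clf.decision_function(Fv)
            if clf.classes_[1] == 0:  # decision oriented toward "rest"
                d = -d
            scores[:, j] = d
        pred = np.array([ovr_decide({g: s[j] for j, g in enumerate(classes)}) for s in scores])
    return float((pred == val.labels).mean())


def select_alpha(train: EpochedSignal, config: PipelineConfig) -> float:
    """Pick alpha by stratified k-fold CV on the training set; ties -> smallest.

    The training data must already be preprocessed (the full fit handles
    that); every class needs at least ``cv_folds`` trials for
    stratification.
    """
    if len(config.alpha_grid) == 1:
        return config.alpha_grid[0]
    classes, counts = np.unique(train.labels, return_counts=True)
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"stratified {config.cv_folds}-fold CV needs >= {config.cv_folds} "
            f"trials per class; counts are "
            f"{dict(zip(classes.tolist(), counts.tolist()))}"
        )
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    folds = list(skf.split(np.zeros(train.n_trials), train.labels))
    mean_acc = np.empty(len(config.alpha_grid))
    for i, alpha in enumerate(config.alpha_grid):
        accs = [
            _score_fold(train.subset(tr), train.subset(va), alpha, config)
            for tr, va in folds
        ]
        mean_acc[i] = np.mean(accs)
    best = int(np.argmax(mean_acc))  # first max -> smallest alpha on ties
    logger.info(
        "alpha selection: best %g (mean CV accuracy %.4f)",
        config.alpha_grid[best], mean_acc[best],
    )
    return config.alpha_grid[best]


def fit(train: EpochedSignal, config: PipelineConfig | None = None) -> Model:
    """Full training pass: preprocess, select alpha, fit filters and SVM(s)."""
    config = config or PipelineConfig()
    if len(train.classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    pre = _preprocess(train, config)
    if config.method == "csp":
        alpha = 0.0
    else:
        alpha = select_alpha(pre, config)
    return _fit_at_alpha(pre, alpha, config)


def predict_scores(model: Model, test: EpochedSignal) -> np.ndarray:
    """Per-class decision scores, one row per test trial."""
    if test.n_channels != model.n_channels:
        raise ValueError(
            f"test data has {test.n_channels} channels; model was fit on "
            f"{model.n_channels}"
        )
    pre = _preprocess(test, model.config)
    if not model.is_multiclass:
        F = feature_matrix(pre, model.filters)
        d = _linear_decision(model.classifier, F)
        # column j scores model.classes[j]
        scores = np.empty((test.n_trials, 2))
        pos, neg = model.classifier["positive_class"], model.classifier["negative_class"]
        for j, g in enumerate(model.classes):
            scores[:, j] = d if g == pos else -d
        return scores
    scores = np.empty((test.n_trials, len(model.classes)))
    for j, g in enumerate(model.classes):
        F = feature_matrix(pre, model.bank.banks[g])
        d = _linear_decision(model.ovr_classifiers[g], F)
        if model.ovr_classifiers[g]["positive_class"] == 0:
            d = -d
        scores[:, j] = d
    return scores


def predict(model: Model, test: EpochedSignal) -> np.ndarray:
    """Predicted class ids for every test trial."""
    scores = predict_scores(model, test)
    return np.array(
        [
            ovr_decide({g: row[j] for j, g in enumerate(model.classes)})
            for row in scores
        ],
        dtype=int,
    )


# -- evaluation --------------------------------------------------------------

def evaluate(pred: np.ndarray, truth: np.ndarray) -> Metrics:
    """Accuracy, Cohen's kappa and (two-class) sensitivity/specificity.

    The lower class id is the positive class: sensitivity = recall of that
    class, specificity = recall of the other.  Kappa is 0 for chance-level
    agreement and 1 for a diagonal confusion matrix.
    """
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError(f"need equal-length non-empty labels; got {pred.shape} vs {truth.shape}")
    classes = np.unique(np.concatenate([truth, pred])).tolist()
    cm = confusion_matrix(truth, pred, labels=classes)
    accuracy = float((pred == truth).mean())
    kappa = float(cohen_kappa_score(truth, pred, labels=classes))
    m = Metrics(
        accuracy=accuracy, kappa=kappa, confusion=cm, classes=classes
    )
    if len(classes) == 2:
        tp, fn = cm[0, 0], cm[0, 1]
        fp, tn = cm[1, 0], cm[1, 1]
        m.sensitivity = float(tp / (tp + fn)) if (tp + fn) else float("nan")
        m.specificity = float(tn / (tn + fp)) if (tn + fp) else float("nan")
        m.positive_class = classes[0]
    return m
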