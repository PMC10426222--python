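"""Visual embedding and out-of-sample anger classification.

Two uses of UMAP: (1) an unsupervised 2-D embedding of the feature matrix for
visual cluster analysis (with the neighbour-graph edges exported so plots can
show which clusters are connected in the high-dimensional space); and (2) a
supervised 10-D metric learning stage — UMAP fit with the anger labels so the
learnt axes optimize class separation — followed by an RBF-kernel SVM with
balanced class weights, hyperparameters tuned by randomized search with
5-fold cross-validation.

Evaluation is leave-one-session-out: each participant-day is held out in turn
while every other session (including the same participant's other day) trains
the metric and the classifier.  Scores are compared against the minority-class
baseline — the constant all-anger predictor, whose accuracy equals the anger
prevalence pi and whose F1 equals 2*pi / (1 + pi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import loguniform
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import RandomizedSearchCV
from sklearn.svm import SVC
from umap import UMAP

from .tsfeatures import FeatureMatrix

__all__ = [
    "EmbeddingConfig",
    "ClassifierConfig",
    "ClassificationReport",
    "visual_embed",
    "fit_supervised_metric",
    "losocv",
    "minority_baseline",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    n_neighbours: int = 15  # sweep {15, 30, 60, 100} for consistency checks
    min_dist: float = 0.1  # sweep 0.1 - 0.3
    visual_dim: int = 2
    metric_dim: int = 10
    target_weight: float = 0.5  # label/data balance in the simplicial intersection
    n_epochs: int | None = None  # UMAP optimization epochs (None = library default)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neighbours < 2:
            raise ValueError("n_neighbours must be >= 2")
        if not (0.0 < self.min_dist < 1.0):
            raise ValueError("min_dist must lie in (0, 1)")
        if self.visual_dim < 1 or self.metric_dim < 1:
            raise ValueError("embedding dimensions must be >= 1")


@dataclass(frozen=True)
class ClassifierConfig:
    c_range: tuple[float, float] = (0.1, 100.0)
    gamma_range: tuple[float, float] = (1e-4, 10.0)
    n_iter: int = 25  # randomized-search draws, log-uniform over both ranges
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for nm, (lo, hi) in (("c_range", self.c_range), ("gamma_range", self.gamma_range)):
            if lo <= 0 or hi <= lo:
                raise ValueError(f"{nm} must be a positive ordered interval")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class ClassificationReport:
    session_ids: list[str]
    accuracy: dict[str, float]
    f1: dict[str, float]  # anger positive; NaN where the session has no anger
    baseline_accuracy: dict[str, float]
    baseline_f1: dict[str, float]
    per_participant: dict[str, dict[str, float]] = field(default_factory=dict)
    summary: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "type": "classification",
            "sessions": {
                sid: {
                    "accuracy": self.accuracy[sid],
                    "f1": self.f1[sid],
                    "baseline_accuracy": self.baseline_accuracy[sid],
                    "baseline_f1": self.baseline_f1[sid],
                }
                for sid in self.session_ids
            },
            "per_participant": self.per_participant,
            "summary": self.summary,
        }


def minority_baseline(labels: np.ndarray) -> tuple[float, float]:
    """Scores of the constant all-anger predictor on a session.

    With anger prevalence pi: accuracy = pi; F1 = 2*pi / (1 + pi).
    """
    labels = np.asarray(labels, dtype=int)
    pi = float(labels.mean())
    return pi, 2.0 * pi / (1.0 + pi) if pi > 0 else 0.0


def visual_embed(
    matrix: FeatureMatrix,
    config: EmbeddingConfig = EmbeddingConfig(),
) -> tuple[np.ndarray, np.ndarray, "np.ndarray"]:
    """Unsupervised 2-D embedding with the neighbour-graph edges.

    Returns ``(coords, edges, weights)`` where ``edges`` is an (m, 2) array of
    window indices connected in the high-dimensional fuzzy neighbour graph.
    Row order matches the feature matrix, so labels can be overlaid directly.
    """
    X = matrix.values.to_numpy()
    if len(X) <= config.n_neighbours:
        raise ValueError(
            f"need more than n_neighbours={config.n_neighbours} windows, got {len(X)}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        um = UMAP(
            n_neighbors=config.n_neighbours,
            min_dist=config.min_dist,
            n_components=config.visual_dim,
            n_epochs=config.n_epochs,
            random_state=config.seed,
        )
        coords = um.fit_transform(X)
    graph = um.graph_.tocoo()
    mask = graph.row < graph.col
    edges = np.column_stack([graph.row[mask], graph.col[mask]])
    return np.asarray(coords), edges, graph.data[mask]


def fit_supervised_metric(
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: EmbeddingConfig = EmbeddingConfig(),
):
    """Supervised UMAP to a 10-D metric space; returns the fitted transform.

    The labels intersect the data's fuzzy topology so that connections
    between differently-labelled points are suppressed; new points embed by
    similarity to the training topology.
    """
    y_train = np.asarray(y_train, dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data must contain both classes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        um = UMAP(
            n_neighbors=config.n_neighbours,
            min_dist=config.min_dist,
            n_components=config.metric_dim,
            target_weight=config.target_weight,
            n_epochs=config.n_epochs,
            random_state=config.seed,
        )
        um.fit(np.asarray(X_train, dtype=float), y=y_train)
    return um


def _fit_svm(Z: np.ndarray, y: np.ndarray, cfg: ClassifierConfig) -> SVC:
    param_distributions = {
        "C": loguniform(*cfg.c_range),
        "gamma": loguniform(*cfg.gamma_range),
    }
    folds = min(cfg.cv_folds, int(np.bincount(y).min()))
    if folds < 2:
        # too few minority examples to cross-validate: fall back to mid-range
        svc = SVC(kernel="rbf", class_weight="balanced", C=1.0, gamma="scale")
        svc.fit(Z, y)
        return svc
    search = RandomizedSearchCV(
        SVC(kernel="rbf", class_weight="balanced"),
        param_distributions,
        n_iter=cfg.n_iter,
        cv=folds,
        random_state=cfg.seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(Z, y)
    return search.best_estimator_


def losocv(
    matrix: FeatureMatrix,
    embed_config: EmbeddingConfig = EmbeddingConfig(),
    clf_config: ClassifierConfig = ClassifierConfig(),
) -> ClassificationReport:
    """Leave-one-session-out cross-validated anger classification.

    For each held-out participant-day, the supervised metric and the SVM are
    fit on all other sessions only; the held-out windows never enter metric
    fitting, SVM training, or hyperparameter search.
    """
    sess = matrix.session_ids().to_numpy()
    unique_sessions = list(dict.fromkeys(sess))
    if len(unique_sessions) < 2:
        raise ValueError("need >= 2 sessions for leave-one-session-out")
    X = matrix.values.to_numpy(dtype=float)
    y = matrix.metadata["anger"].to_numpy(dtype=int)

    acc: dict[str, float] = {}
    f1s: dict[str, float] = {}
    base_acc: dict[str, float] = {}
    base_f1: dict[str, float] = {}
    for sid in unique_sessions:
        test_mask = sess == sid
        train_mask = ~test_mask
        um = fit_supervised_metric(X[train_mask], y[train_mask], embed_config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Z_train = um.embedding_
            Z_test = um.transform(X[test_mask])
        svc = _fit_svm(Z_train, y[train_mask], clf_config)
        pred = svc.predict(Z_test)
        y_test = y[test_mask]
        acc[sid] = float(accuracy_score(y_test, pred))
        pi, bf1 = minority_baseline(y_test)
        base_acc[sid] = pi
        if y_test.sum() == 0:
            warnings.warn(f"session {sid} has no anger windows; F1 undefined", stacklevel=2)
            f1s[sid] = float("nan")
            base_f1[sid] = float("nan")
        else:
            f1s[sid] = float(f1_score(y_test, pred, pos_label=1, zero_division=0))
            base_f1[sid] = bf1

    per_participant: dict[str, dict[str, float]] = {}
    for sid in unique_sessions:
        pid = sid.rsplit("-", 1)[0]
        per_participant.setdefault(pid, {"sessions": 0, "accuracy": 0.0, "f1": 0.0,
                                         "baseline_accuracy": 0.0, "baseline_f1": 0.0})
    for pid, agg in per_participant.items():
        sids = [s for s in unique_sessions if s.rsplit("-", 1)[0] == pid]
        agg["sessions"] = len(sids)
        agg["accuracy"] = float(np.mean([acc[s] for s in sids]))
        agg["f1"] = float(np.nanmean([f1s[s] for s in sids]))
        agg["baseline_accuracy"] = float(np.mean([base_acc[s] for s in sids]))
        agg["baseline_f1"] = float(np.nanmean([base_f1[s] for s in sids]))

    summary = {
        "mean_accuracy": float(np.mean([p["accuracy"] for p in per_participant.values()])),
        "sd_accuracy": float(np.std([p["accuracy"] for p in per_participant.values()])),
        "mean_f1": float(np.nanmean([p["f1"] for p in per_participant.values()])),
        "mean_baseline_accuracy": float(
            np.mean([p["baseline_accuracy"] for p in per_participant.values()])
        ),
        "mean_baseline_f1": float(
            np.nanmean([p["baseline_f1"] for p in per_participant.values()])
        ),
    }
    return ClassificationReport(
        session_ids=unique_sessions,
        accuracy=acc,
        f1=f1s,
        baseline_accuracy=base_acc,
        baseline_f1=base_f1,
        per_participant=per_participant,
        summary=summary,
    )
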