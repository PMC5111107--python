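"""Re-trainable classification engines for the centroid-style subtypers.

Engines implemented:

- nearest centroid (distance-to-centroid, Euclidean or one-minus-Pearson),
- nearest shrunken centroid (PAM: class centroids soft-thresholded toward
  the overall centroid in standardized units, Gaussian-style posteriors),
- compound covariate predictor (t-statistic-weighted two-class score with a
  class-mean-midpoint threshold),
- meta-gene linear discriminant (member-gene means as features, pooled
  covariance with an additive ridge),
- reference engines: k-nearest-neighbour and a linear maximum-margin
  classifier.

All engines are deterministic given their inputs; prediction ties yield NA,
and class posteriors below a model's confidence floor also yield NA.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .expression import ExpressionMatrix
from .rules import SubtypeCall

logger = logging.getLogger(__name__)

_TIE_RTOL = 1e-12


@dataclass
class TrainedModel:
    """A fitted engine: kind, class labels, parameters, training metadata."""

    kind: str
    classes: list[str]
    genes: list[str]
    name: str = "trained"
    centroids: pd.DataFrame | None = None      # classes x genes
    gene_sd: pd.Series | None = None           # PAM: s_g + s0 (offset applied)
    shrinkage: float = 0.0
    metric: str = "euclidean"
    confidence_floor: float = 0.0
    extras: dict[str, Any] = field(default_factory=dict)
    training_meta: dict[str, Any] = field(default_factory=dict)
    # engines that keep training data / sklearn estimators
    _train_X: pd.DataFrame | None = None
    _train_y: np.ndarray | None = None
    _estimator: Any = None

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("a trained model needs >= 2 classes")
        if not 0.0 <= self.confidence_floor <= 1.0:
            raise ValueError("confidence floor must be in [0, 1]")


def _check_labels(matrix: ExpressionMatrix, labels: pd.Series,
                  min_per_class: int = 2) -> pd.Series:
    labels = pd.Series(labels).reindex(matrix.values.columns).dropna()
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("training needs >= 2 classes")
    small = counts[counts < min_per_class]
    if len(small):
        raise ValueError(
            f"class(es) with fewer than {min_per_class} samples: "
            f"{sorted(small.index)}")
    return labels


def train_nearest_centroid(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    metric: str = "euclidean",
    name: str = "nearest_centroid",
) -> TrainedModel:
    """Per-class centroid = per-gene mean over that class's samples."""
    if metric not in ("euclidean", "one_minus_correlation"):
        raise ValueError(f"unknown metric {metric!r}")
    labels = _check_labels(matrix, labels, min_per_class=1)
    X = matrix.values[labels.index]
    cents = {}
    for cls, members in labels.groupby(labels).groups.items():
        cents[str(cls)] = X[list(members)].mean(axis=1)
    centroids = pd.DataFrame(cents).T
    return TrainedModel("nearest_centroid", sorted(centroids.index),
                        list(X.index), name=name,
                        centroids=centroids.loc[sorted(centroids.index)],
                        metric=metric,
                        training_meta={"n": int(len(labels))})


def train_shrunken_centroid(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    shrinkage: float = 0.0,
    name: str = "pam",
    confidence_floor: float = 0.0,
) -> TrainedModel:
    """Nearest shrunken centroid (PAM).

    Standardized class-vs-overall centroid contrasts
    ``d_gk = (xbar_gk - xbar_g) / (m_k (s_g + s0))`` with
    ``m_k = sqrt(1/n_k - 1/n)`` and ``s0`` the median of the pooled
    within-class gene SDs are soft-thresholded by the shrinkage amount;
    shrunken centroids are rebuilt from the surviving contrasts. At
    shrinkage 0 prediction coincides with nearest centroid in
    standardized space.
    """
    if shrinkage < 0:
        raise ValueError("shrinkage must be >= 0")
    labels = _check_labels(matrix, labels, min_per_class=2)
    X = matrix.values[labels.index]
    n = len(labels)
    classes = sorted(labels.unique())
    overall = X.mean(axis=1)

    within_ss = pd.Series(0.0, index=X.index)
    cents = {}
    n_k = {}
    for cls in classes:
        members = labels.index[labels == cls]
        block = X[list(members)]
        cents[cls] = block.mean(axis=1)
        within_ss += ((block.sub(cents[cls], axis=0)) ** 2).sum(axis=1)
        n_k[cls] = len(members)
    s = np.sqrt(within_ss / (n - len(classes)))
    s0 = float(s.median())
    sd = s + s0

    shrunk = {}
    for cls in classes:
        m_k = np.sqrt(1.0 / n_k[cls] - 1.0 / n)
        d = (cents[cls] - overall) / (m_k * sd)
        d_shrunk = np.sign(d) * np.maximum(d.abs() - shrinkage, 0.0)
        shrunk[cls] = overall + m_k * sd * d_shrunk
    centroids = pd.DataFrame(shrunk).T.loc[classes]
    return TrainedModel(
        "shrunken_centroid", [str(c) for c in classes], list(X.index),
        name=name, centroids=centroids, gene_sd=sd, shrinkage=shrinkage,
        confidence_floor=confidence_floor,
        training_meta={"n": int(n), "s0": s0,
                       "class_sizes": {str(c): n_k[c] for c in classes}})


def train_compound_covariate(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    name: str = "compound_covariate",
) -> TrainedModel:
    """Compound covariate predictor for exactly two classes.

    Each gene's pooled-variance two-sample t-statistic is its weight; a
    sample's score is the t-weighted expression sum and the decision
    threshold is the midpoint of the two class-mean scores. A sample exactly
    at the midpoint goes to the class with the lower mean score.
    """
    labels = _check_labels(matrix, labels, min_per_class=2)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError("compound covariate predictor needs exactly 2 classes")
    X = matrix.values[labels.index]
    a_cols = list(labels.index[labels == classes[0]])
    b_cols = list(labels.index[labels == classes[1]])
    A, B = X[a_cols], X[b_cols]
    na, nb = len(a_cols), len(b_cols)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    sp2 = (((A.sub(mean_a, axis=0)) ** 2).sum(axis=1)
           + ((B.sub(mean_b, axis=0)) ** 2).sum(axis=1)) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / np.sqrt(sp2 * (1 / na + 1 / nb))
    t = t.replace([np.inf, -np.inf], np.nan).fillna(0.0)
    scores = X.mul(t, axis=0).sum(axis=0)
    mu_a = float(scores[a_cols].mean())
    mu_b = float(scores[b_cols].mean())
    threshold = 0.5 * (mu_a + mu_b)
    lower_class = classes[0] if mu_a <= mu_b else classes[1]
    upper_class = classes[1] if lower_class == classes[0] else classes[0]
    return TrainedModel(
        "compound_covariate", [str(c) for c in classes], list(X.index),
        name=name,
        extras={"weights": t.to_dict(), "threshold": threshold,
                "lower_class": str(lower_class),
                "upper_class": str(upper_class),
                "class_mean_scores": {str(classes[0]): mu_a,
                                      str(classes[1]): mu_b}},
        training_meta={"n": int(len(labels))})


def train_metagene_lda(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    metagene_map: Mapping[str, list[str]],
    ridge: float = 1e-6,
    name: str = "metagene_lda",
) -> TrainedModel:
    """Multiclass linear discriminant on meta-gene features.

    A meta-gene's value is the mean of its member genes; meta-genes with no
    covered member are dropped with a warning, as are constant features.
    The pooled within-class covariance gets an additive ridge (default 1e-6)
    so a singular covariance never aborts the fit.
    """
    labels = _check_labels(matrix, labels, min_per_class=2)
    X = matrix.values[labels.index]
    feats = {}
    for mg, members in metagene_map.items():
        present = [g for g in members if g in X.index]
        if not present:
            logger.warning("metagene %s has no covered members, dropped", mg)
            continue
        feats[mg] = X.loc[present].mean(axis=0)
    if not feats:
        raise ValueError("no metagene has covered members")
    F = pd.DataFrame(feats)  # samples x metagenes
    constant = F.columns[F.nunique() <= 1]
    if len(constant):
        logger.warning("constant metagene feature(s) excluded: %s",
                       list(constant))
        F = F.drop(columns=constant)
    classes = sorted(labels.unique())
    means = {c: F.loc[labels.index[labels == c]].mean(axis=0) for c in classes}
    pooled = np.zeros((F.shape[1], F.shape[1]))
    for c in classes:
        block = F.loc[labels.index[labels == c]]
        dev = block - means[c]
        pooled += dev.T.to_numpy() @ dev.to_numpy()
    pooled /= (len(labels) - len(classes))
    pooled += ridge * np.eye(F.shape[1])
    inv = np.linalg.inv(pooled)
    # linear discriminant: w_c = inv @ mu_c, b_c = -0.5 mu_c' inv mu_c
    W = {str(c): inv @ means[c].to_numpy() for c in classes}
    b = {str(c): float(-0.5 * means[c].to_numpy() @ inv @ means[c].to_numpy())
         for c in classes}
    return TrainedModel(
        "metagene_lda", [str(c) for c in classes], list(X.index), name=name,
        extras={"metagene_map": {m: list(v) for m, v in metagene_map.items()
                                 if m in F.columns},
                "features": list(F.columns),
                "weights": {c: list(map(float, w)) for c, w in W.items()},
                "biases": b, "ridge": ridge},
        training_meta={"n": int(len(labels))})


def train_reference_model(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    engine: str = "knn",
    k: int = 5,
    C: float = 1000.0,
    name: str | None = None,
) -> TrainedModel:
    """Reference engines: KNN majority vote or a linear maximum-margin fit.

    KNN ties (an even split) break toward the class with the smaller
    aggregate distance among the tied votes. The maximum-margin engine
    delegates to a linear-kernel SVM.
    """
    labels = _check_labels(matrix, labels, min_per_class=1)
    X = matrix.values[labels.index]
    if engine == "knn":
        if k >= len(labels):
            raise ValueError(f"k={k} must be < n={len(labels)}")
        return TrainedModel(
            "knn", sorted(map(str, labels.unique())), list(X.index),
            name=name or "knn", extras={"k": k},
            _train_X=X, _train_y=labels.to_numpy(),
            training_meta={"n": int(len(labels))})
    if engine == "max_margin":
        from sklearn.svm import SVC

        est = SVC(kernel="linear", C=C)
        est.fit(X.T.to_numpy(), labels.to_numpy())
        return TrainedModel(
            "max_margin", sorted(map(str, labels.unique())), list(X.index),
            name=name or "max_margin", _estimator=est,
            training_meta={"n": int(len(labels)), "C": C})
    raise ValueError(f"unknown reference engine {engine!r}")


# ---------------------------------------------------------------------------
# prediction


def _distances(model: TrainedModel, X: pd.DataFrame) -> pd.DataFrame:
    """Samples x classes distance table for centroid models."""
    C = model.centroids[X.index].to_numpy()  # classes x genes
    V = X.T.to_numpy()                       # samples x genes
    if model.kind == "shrunken_centroid":
        sd = model.gene_sd[X.index].to_numpy()
        D = cdist(V / sd, C / sd, metric="sqeuclidean")
    elif model.metric == "one_minus_correlation":
        D = cdist(V, C, metric="correlation")
    else:
        D = cdist(V, C, metric="euclidean")
    return pd.DataFrame(D, index=X.columns, columns=model.centroids.index)


def _confidence_from_distance(row: np.ndarray) -> np.ndarray:
    """Normalized inverse distance; an exact centroid hit gets confidence 1."""
    zero = row <= 0
    if zero.any():
        return zero.astype(float) / zero.sum()
    inv = 1.0 / row
    return inv / inv.sum()


def predict(model: TrainedModel, matrix: ExpressionMatrix,
            coverage_floor: float = 0.5) -> list[SubtypeCall]:
    """Label each sample with the nearest / most probable class.

    Confidence is the class posterior (PAM, LDA) or the normalized inverse
    distance (plain centroids). Calls whose confidence falls below the
    model's floor, and exact prediction ties, come back NA.
    """
    shared = [g for g in model.genes if g in matrix.values.index]
    if not shared:
        raise KeyError(f"{model.name}: no model gene present in matrix")
    if len(shared) < coverage_floor * len(model.genes):
        raise KeyError(
            f"{model.name}: only {len(shared)}/{len(model.genes)} model "
            f"genes present (< coverage floor {coverage_floor})")
    X = matrix.values.loc[shared]
    calls: list[SubtypeCall] = []

    if model.kind in ("nearest_centroid", "shrunken_centroid"):
        D = _distances(model, X)
        for s in X.columns:
            row = D.loc[s].to_numpy(dtype=float)
            if not np.all(np.isfinite(row)):
                calls.append(SubtypeCall(s, None, model.name))
                continue
            if model.kind == "shrunken_centroid":
                # Gaussian discriminant posteriors from squared distances
                z = -0.5 * row
                z -= z.max()
                conf_vec = np.exp(z) / np.exp(z).sum()
            else:
                conf_vec = _confidence_from_distance(row)
            calls.append(_argmax_call(s, model, conf_vec,
                                      score=-float(row.min())))
        return calls

    if model.kind == "compound_covariate":
        w = pd.Series(model.extras["weights"]).reindex(shared).fillna(0.0)
        scores = X.mul(w, axis=0).sum(axis=0)
        thr = model.extras["threshold"]
        lower, upper = model.extras["lower_class"], model.extras["upper_class"]
        for s in X.columns:
            v = float(scores[s])
            label = lower if v <= thr else upper
            calls.append(SubtypeCall(s, label, model.name, score=v))
        return calls

    if model.kind == "metagene_lda":
        feats = {}
        for mg, members in model.extras["metagene_map"].items():
            present = [g for g in members if g in X.index]
            feats[mg] = (X.loc[present].mean(axis=0) if present
                         else pd.Series(0.0, index=X.columns))
        F = pd.DataFrame(feats)[model.extras["features"]]
        for s in F.index:
            x = F.loc[s].to_numpy()
            disc = np.array([x @ np.asarray(model.extras["weights"][c])
                             + model.extras["biases"][c]
                             for c in model.classes])
            z = disc - disc.max()
            conf_vec = np.exp(z) / np.exp(z).sum()
            calls.append(_argmax_call(s, model, conf_vec,
                                      score=float(disc.max())))
        return calls

    if model.kind == "knn":
        k = model.extras["k"]
        train = model._train_X.loc[shared]
        D = cdist(X.T.to_numpy(), train.T.to_numpy())
        y = np.asarray(model._train_y)
        for i, s in enumerate(X.columns):
            order = np.argsort(D[i], kind="stable")[:k]
            votes = pd.Series(y[order]).value_counts()
            top = votes[votes == votes.max()].index
            if len(top) == 1:
                label = top[0]
            else:  # split vote: smaller aggregate distance wins
                agg = {c: D[i][order][y[order] == c].sum() for c in top}
                ranked = sorted(agg.items(), key=lambda kv: (kv[1], kv[0]))
                if len(ranked) > 1 and np.isclose(ranked[0][1], ranked[1][1],
                                                  rtol=_TIE_RTOL):
                    label = None
                else:
                    label = ranked[0][0]
            conf = float(votes.max() / k)
            calls.append(SubtypeCall(
                s, None if label is None or conf < model.confidence_floor
                else str(label), model.name, confidence=conf))
        return calls

    if model.kind == "max_margin":
        pred = model._estimator.predict(X.T.to_numpy())
        for s, label in zip(X.columns, pred):
            calls.append(SubtypeCall(s, str(label), model.name))
        return calls

    raise ValueError(f"unknown model kind {model.kind!r}")


def _argmax_call(sample: str, model: TrainedModel, conf_vec: np.ndarray,
                 score: float | None = None) -> SubtypeCall:
    order = np.argsort(conf_vec)
    best, second = conf_vec[order[-1]], conf_vec[order[-2]]
    tied = np.isclose(best, second, rtol=1e-9, atol=1e-12)
    label = None if tied else str(model.centroids.index[order[-1]]
                                  if model.centroids is not None
                                  else model.classes[order[-1]])
    conf = float(best)
    if label is not None and conf < model.confidence_floor:
        label = None
    return SubtypeCall(sample, label, model.name, score=score,
                       confidence=conf)


# ---------------------------------------------------------------------------
# serialization (centroid-style models round-trip through structured text)


def save_model(model: TrainedModel, path: str | Path) -> None:
    if model.kind in ("knn", "max_margin"):
        raise ValueError(f"{model.kind} reference models are not serialized; "
                         f"retrain from the labeled matrix")
    doc = {
        "kind": model.kind, "name": model.name, "classes": model.classes,
        "genes": model.genes, "shrinkage": model.shrinkage,
        "metric": model.metric, "confidence_floor": model.confidence_floor,
        "extras": model.extras, "training_meta": model.training_meta,
        "centroids": (None if model.centroids is None
                      else model.centroids.to_dict(orient="index")),
        "gene_sd": None if model.gene_sd is None else model.gene_sd.to_dict(),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_model(path: str | Path) -> TrainedModel:
    doc = json.loads(Path(path).read_text())
    centroids = doc["centroids"]
    if centroids is not None:
        centroids = pd.DataFrame.from_dict(centroids, orient="index")
        centroids = centroids.loc[doc["classes"], doc["genes"]]
    gene_sd = doc["gene_sd"]
    if gene_sd is not None:
        gene_sd = pd.Series(gene_sd).reindex(doc["genes"])
    return TrainedModel(
        doc["kind"], doc["classes"], doc["genes"], name=doc["name"],
        centroids=centroids, gene_sd=gene_sd, shrinkage=doc["shrinkage"],
        metric=doc["metric"], confidence_floor=doc["confidence_floor"],
        extras=doc["extras"], training_meta=doc["training_meta"])
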