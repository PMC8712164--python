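"""Feature assembly and classifiers.

The per-image feature vector holds eight scalars in a fixed order —
entropy, energy, Hough-Gini, skewness, contrast, correlation,
homogeneity, and the entropy product E(X)*D(X) — optionally followed by
the 384-entry HOG block (total length 392).

Two classifiers are supported: a soft-margin linear SVM (C = 1) and a
100-tree random forest with sqrt-d feature subsampling and majority
voting (ties go to the cancerous class). Both are trained on z-scored
features, with the scaler fit on training data only. Evaluation is by
stratified k-fold cross-validation with a pooled out-of-fold confusion
matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import glcm, hog as hog_mod, hough, intensity, preprocessing, segmentation
from .config import PipelineConfig
from .evaluation import ConfusionMatrix, confusion
from .image import RadiographImage

__all__ = [
    "SCALAR_FEATURES",
    "FeatureVector",
    "TrainedClassifier",
    "CVResult",
    "extract_features",
    "features_to_matrix",
    "features_to_dataframe",
    "features_from_dataframe",
    "train_svm",
    "train_random_forest",
    "predict",
    "kfold_cv",
]

logger = logging.getLogger(__name__)

# Fixed scalar order of every feature vector.
SCALAR_FEATURES = (
    "entropy",
    "energy",
    "gini",
    "skewness",
    "contrast",
    "correlation",
    "homogeneity",
    "entropy_product",
)

LABEL_CODES = {"cancerous": +1, "healthy": -1}


@dataclass(frozen=True)
class FeatureVector:
    """Named scalar features plus an optional HOG block and label (+1/-1)."""

    scalars: dict[str, float]
    hog: Optional[np.ndarray] = None
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if tuple(self.scalars.keys()) != SCALAR_FEATURES:
            raise ValueError(
                f"scalar features must be exactly {SCALAR_FEATURES} in order, "
                f"got {tuple(self.scalars.keys())}"
            )
        if self.label is not None and self.label not in (+1, -1):
            raise ValueError(f"label must be +1 or -1, got {self.label}")

    def as_array(self, with_hog: bool = True) -> np.ndarray:
        x = np.array([self.scalars[k] for k in SCALAR_FEATURES], dtype=np.float64)
        if with_hog and self.hog is not None:
            x = np.concatenate([x, self.hog])
        return x


def extract_features(
    img: RadiographImage,
    with_hog: bool = True,
    config: PipelineConfig | None = None,
) -> FeatureVector:
    """Run the full pipeline on one image: preprocess, detect edges,
    crop to the ROI, then compute all texture features.

    Degenerate inputs are handled explicitly: with no edge pixels the
    features are computed on the full image and the Hough-Gini feature
    falls back to 0 (both logged).
    """
    cfg = config or PipelineConfig()
    pre = preprocessing.preprocess(img, cfg.preprocess)
    edges = segmentation.detect_edges(pre, method=cfg.edges.method, config=cfg.edges)

    roi_img = pre
    roi_mask = edges.mask
    if cfg.use_roi:
        try:
            box = segmentation.extract_roi(edges)
            if min(box.shape) < 8:  # sliver ROI: texture stats degenerate
                logger.warning(
                    "ROI %s of %s is thinner than 8 px; using the full image",
                    box, img.source_id or "<image>",
                )
            else:
                roi_img = segmentation.crop(pre, box)
                roi_mask = edges.mask[box.row_min : box.row_max,
                                      box.col_min : box.col_max]
        except segmentation.NoROIError:
            logger.warning(
                "no edges found in %s; computing features on the full image",
                img.source_id or "<image>",
            )

    def _run(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"feature {name!r} failed: {exc}") from exc

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate-case conventions warn
        haralick = _run("glcm", glcm.glcm_features, roi_img, cfg.glcm)
        first_order = _run(
            "intensity",
            intensity.intensity_features,
            roi_img,
            cfg.entropy,
            cfg.skewness_denominator,
        )

    if roi_mask.any():
        edge_crop = segmentation.EdgeMap(
            mask=roi_mask, detector=edges.detector, params=edges.params
        )
        gini = _run("gini", hough.hough_gini_feature, edge_crop, cfg.hough)
    else:
        logger.warning("empty edge map: Hough-Gini feature falls back to 0")
        gini = 0.0

    scalars = {
        "entropy": first_order["entropy"],
        "energy": haralick["energy"],
        "gini": gini,
        "skewness": first_order["skewness"],
        "contrast": haralick["contrast"],
        "correlation": haralick["correlation"],
        "homogeneity": haralick["homogeneity"],
        "entropy_product": first_order["entropy_product"],
    }
    hog_block = None
    if with_hog:
        hog_block = _run("hog", hog_mod.compute_hog, roi_img, cfg.hog).vector
    label = LABEL_CODES.get(img.label) if img.label else None
    return FeatureVector(scalars=scalars, hog=hog_block, label=label)


def features_to_matrix(
    data: Sequence[FeatureVector], with_hog: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Stack feature vectors into (X, y); raises if any label is missing."""
    if not data:
        raise ValueError("empty feature set")
    X = np.stack([fv.as_array(with_hog=with_hog) for fv in data])
    labels = [fv.label for fv in data]
    if any(lab is None for lab in labels):
        raise ValueError("all feature vectors need labels for training")
    return X, np.array(labels, dtype=int)


def features_to_dataframe(data: Sequence[FeatureVector]) -> "pd.DataFrame":
    """One row per image: id-free scalar columns, optional hog_0..hog_N,
    and a label column (+1/-1 or empty)."""
    import pandas as pd

    records = []
    for fv in data:
        rec = dict(fv.scalars)
        if fv.hog is not None:
            rec.update({f"hog_{i}": v for i, v in enumerate(fv.hog)})
        rec["label"] = fv.label
        records.append(rec)
    return pd.DataFrame.from_records(records)


def features_from_dataframe(df: "pd.DataFrame") -> list[FeatureVector]:
    """Inverse of :func:`features_to_dataframe`."""
    hog_cols = sorted(
        (c for c in df.columns if c.startswith("hog_")),
        key=lambda c: int(c.split("_")[1]),
    )
    out = []
    for _, row in df.iterrows():
        scalars = {k: float(row[k]) for k in SCALAR_FEATURES}
        hog = np.array([row[c] for c in hog_cols], float) if hog_cols else None
        label = None if "label" not in df.columns or pd.isna(row["label"]) \
            else int(row["label"])
        out.append(FeatureVector(scalars=scalars, hog=hog, label=label))
    return out


@dataclass
class TrainedClassifier:
    """Fitted model plus its feature scaler (z-score, train-data only)."""

    kind: str  # linear_svm | random_forest
    model: object
    scaler: StandardScaler
    n_features: int
    seed: int
    support_vector_count: Optional[int] = None


def train_svm(
    data: Sequence[FeatureVector],
    with_hog: bool = True,
    seed: int = 42,
    solver: str = "batch",
) -> TrainedClassifier:
    """Soft-margin linear SVM, C = 1, optimizer tolerance 1e-3.

    ``solver="sgd"`` swaps in a stochastic hinge-loss trainer with a
    constant step size of 0.001 for comparison; the batch solver is the
    default and is deterministic.
    """
    X, y = features_to_matrix(data, with_hog=with_hog)
    _check_two_classes(y)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    if solver == "batch":
        model = SVC(kernel="linear", C=1.0, tol=1e-3, random_state=seed)
        model.fit(Xs, y)
        sv_count = int(model.n_support_.sum())
    elif solver == "sgd":
        model = SGDClassifier(
            loss="hinge",
            learning_rate="constant",
            eta0=0.001,
            alpha=1.0 / len(y),
            random_state=seed,
        )
        model.fit(Xs, y)
        sv_count = None
    else:
        raise ValueError(f"unknown SVM solver {solver!r}")
    logger.info("linear SVM trained; support vectors: %s", sv_count)
    return TrainedClassifier(
        kind="linear_svm",
        model=model,
        scaler=scaler,
        n_features=X.shape[1],
        seed=seed,
        support_vector_count=sv_count,
    )


def train_random_forest(
    data: Sequence[FeatureVector],
    with_hog: bool = True,
    n_trees: int = 100,
    seed: int = 42,
) -> TrainedClassifier:
    """Bootstrap forest of ``n_trees`` trees, sqrt-d features per split,
    unlimited depth; prediction is by majority vote with ties resolved
    to the cancerous class (+1)."""
    X, y = features_to_matrix(data, with_hog=with_hog)
    _check_two_classes(y)
    scaler = StandardScaler().fit(X)
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
    )
    model.fit(scaler.transform(X), y)
    return TrainedClassifier(
        kind="random_forest",
        model=model,
        scaler=scaler,
        n_features=X.shape[1],
        seed=seed,
    )


def _check_two_classes(y: np.ndarray) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError(
            "training requires at least 2 examples per class; "
            f"got counts {dict(zip(classes.tolist(), counts.tolist()))}"
        )


def predict(
    clf: TrainedClassifier, data: Sequence[FeatureVector] | np.ndarray
) -> np.ndarray:
    """Apply the stored scaler and decision rule; returns labels in {+1, -1}.

    Points exactly on the SVM hyperplane, and random-forest vote ties,
    resolve to +1 (cancerous) by convention.
    """
    if isinstance(data, np.ndarray):
        X = np.atleast_2d(data)
    else:
        X = np.stack(
            [fv.as_array(with_hog=clf.n_features > len(SCALAR_FEATURES))
             for fv in data]
        )
    if X.shape[1] != clf.n_features:
        raise ValueError(
            f"feature length mismatch: model expects {clf.n_features}, "
            f"got {X.shape[1]}"
        )
    Xs = clf.scaler.transform(X)
    if clf.kind == "linear_svm" and hasattr(clf.model, "decision_function"):
        scores = clf.model.decision_function(Xs)
        if clf.model.classes_[1] != 1:  # orient score towards +1
            scores = -scores
        return np.where(scores >= 0, 1, -1)
    if clf.kind == "random_forest":
        proba = clf.model.predict_proba(Xs)
        pos = list(clf.model.classes_).index(1)
        return np.where(proba[:, pos] >= 0.5, 1, -1)
    return clf.model.predict(Xs)


@dataclass
class CVResult:
    """Pooled out-of-fold predictions of a stratified k-fold run."""

    confusion: ConfusionMatrix
    fold_accuracies: list[float]
    y_true: np.ndarray
    y_pred: np.ndarray

    @property
    def pooled_accuracy(self) -> float:
        return 100.0 * float((self.y_true == self.y_pred).mean())


def kfold_cv(
    data: Sequence[FeatureVector],
    k: int = 5,
    model_kind: str = "svm",
    with_hog: bool = True,
    seed: int = 42,
) -> CVResult:
    """Stratified k-fold cross-validation.

    The scaler and model are refit inside each training fold — no test
    example ever touches its fold's scaler statistics. Every example is
    predicted exactly once out-of-fold; the pooled confusion matrix is
    returned along with per-fold accuracies.
    """
    X, y = features_to_matrix(data, with_hog=with_hog)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"each class needs at least k={k} members for stratified CV; "
            f"got {dict(zip(classes.tolist(), counts.tolist()))}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.zeros_like(y)
    fold_acc: list[float] = []
    trainers = {"svm": train_svm, "rf": train_random_forest}
    if model_kind not in trainers:
        raise ValueError(f"unknown model kind {model_kind!r}")
    for train_idx, test_idx in skf.split(X, y):
        fold_data = [data[i] for i in train_idx]
        clf = trainers[model_kind](fold_data, with_hog=with_hog, seed=seed)
        pred = predict(clf, X[test_idx])
        y_pred[test_idx] = pred
        fold_acc.append(float((pred == y[test_idx]).mean()))
    return CVResult(
        confusion=confusion(y, y_pred),
        fold_accuracies=fold_acc,
        y_true=y,
        y_pred=y_pred,
    )
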