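"""Per-pixel spectral classification into tumor / non-tumor tissue / background.

Seven method configurations are supported, mirroring the standard toolbox of
spectral classifiers:

* ``PCA-LDA``, ``PCA-KNN``, ``PCA-NN`` — principal-component projection of the
  F-element spectra (loadings fitted on training data only, optionally
  truncated to the first 4/5/6 PCs) followed by linear discriminant analysis,
  k-nearest-neighbor voting (k = 5) or a small feed-forward network.
* ``SAM-min``, ``SAM-LDA``, ``SAM-KNN`` — spectral angle mapping: the angle
  between each spectrum and the per-class mean training spectra yields a
  3-element feature vector; classification is the minimum angle, or LDA/KNN
  on the angle features.
* ``NN`` — the network applied to the raw F-element spectra.

Evaluation follows a leave-three-out cube protocol: train on one image cube,
test pooled over the remaining cubes (four permutations with four cubes); the
network additionally holds out one cube for validation-based early stopping.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.neural_network import MLPClassifier

from .preprocess import CLASS_LABELS, CLASS_BACKGROUND, LabeledSpectra, normalize_spectra

logger = logging.getLogger(__name__)

__all__ = [
    "METHODS",
    "ClassifierConfig",
    "PcaModel",
    "SamReference",
    "SamFeatures",
    "TrainedClassifier",
    "EvalResult",
    "PermutationResult",
    "fit_pca",
    "project_pca",
    "fit_sam_reference",
    "spectral_angles",
    "fit",
    "predict",
    "predict_cube",
    "cross_validate",
    "method_grid",
    "save_classifier",
    "load_classifier",
]

METHODS = ("PCA-LDA", "PCA-KNN", "SAM-min", "SAM-LDA", "SAM-KNN", "NN", "PCA-NN")
_PCA_METHODS = ("PCA-LDA", "PCA-KNN", "PCA-NN")
_NN_METHODS = ("NN", "PCA-NN")


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable parameters shared by the seven methods."""

    n_retained: int = 4          # PCs kept by the PCA- methods (studied: 4, 5, 6)
    k: int = 5                   # KNN neighbors
    hidden_units: int = 10       # sigmoid hidden neurons of the network
    seed: int = 0
    nn_iter_per_round: int = 40  # lbfgs iterations between validation checks
    nn_max_rounds: int = 40
    nn_patience: int = 6         # validation checks without improvement before stopping


# ---------------------------------------------------------------------------
# PCA with a deterministic sign convention
# ---------------------------------------------------------------------------

@dataclass
class PcaModel:
    """Principal components of the training spectra.

    ``loadings`` columns are orthonormal eigenvectors of the covariance,
    ordered by descending explained variance, with the largest-magnitude
    element of each column made positive so cross-run comparisons are stable.
    """

    mean: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    n_retained: int
    rank_deficient: bool = False


def fit_pca(X, n_retained: int | None = None) -> PcaModel:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be N x F")
    N, F = X.shape
    if N <= F:
        raise ValueError("PCA requires more samples than features")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    n_retained = F if n_retained is None else int(n_retained)
    if not 1 <= n_retained <= F:
        raise ValueError(f"n_retained must be in 1..{F}")

    mean = X.mean(axis=0)
    cov = np.cov(X - mean, rowvar=False, ddof=1).reshape(F, F)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention: largest-|loading| element positive
    for j in range(F):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    rank_deficient = bool(evals[-1] <= 1e-12 * max(evals[0], 1e-300))
    if rank_deficient:
        logger.warning("rank-deficient training data: zero-variance PCs present")
    return PcaModel(mean, evecs, evals, n_retained, rank_deficient)


def project_pca(model: PcaModel, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError("column count does not match the fitted PCA model")
    return (X - model.mean) @ model.loadings[:, :model.n_retained]


# ---------------------------------------------------------------------------
# Spectral angle mapping
# ---------------------------------------------------------------------------

@dataclass
class SamReference:
    """Per-class mean training spectra, rows ordered (tumor, non-tumor, background)."""

    reference_spectra: np.ndarray          # 3 x F
    class_labels: tuple = CLASS_LABELS


@dataclass
class SamFeatures:
    """Angles (radians, in [0, pi]) to each class reference; one row per spectrum."""

    angles: np.ndarray                     # N x 3
    zero_rows: np.ndarray                  # flagged degenerate target rows


def fit_sam_reference(X, y) -> SamReference:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    refs = []
    for c in CLASS_LABELS:
        rows = X[y == c]
        if rows.shape[0] == 0:
            raise ValueError(f"no training spectra for class {c}")
        refs.append(rows.mean(axis=0))
    refs = np.asarray(refs)
    norms = np.linalg.norm(refs, axis=1)
    if np.any(norms <= 0):
        bad = [int(c) for c, n in zip(CLASS_LABELS, norms) if n <= 0]
        raise ValueError(f"zero reference spectrum for classes {bad}")
    return SamReference(refs)


def spectral_angles(X, ref: SamReference) -> SamFeatures:
    """theta = arccos(<x, r> / (|x| |r|)), clipped into [-1, 1] before arccos.

    All-zero target rows get theta = pi/2 for every class and are flagged.
    """
    X = np.asarray(X, dtype=float)
    R = ref.reference_spectra
    if X.shape[1] != R.shape[1]:
        raise ValueError("spectrum length does not match the SAM references")
    xn = np.linalg.norm(X, axis=1)
    rn = np.linalg.norm(R, axis=1)
    zero = xn <= 0
    safe = np.where(zero, 1.0, xn)
    cosang = (X @ R.T) / (safe[:, None] * rn[None, :])
    angles = np.arccos(np.clip(cosang, -1.0, 1.0))
    angles[zero] = np.pi / 2
    return SamFeatures(angles, zero)


# ---------------------------------------------------------------------------
# Deterministic KNN (vote -> nearer mean distance -> fixed class order)
# ---------------------------------------------------------------------------

class _KNNClassifier:
    """Euclidean k-nearest-neighbor voting with a fully specified tie-break.

    Class vote ties are broken toward the class with the nearer mean distance
    among its voting neighbors, then toward the lower class label.  Neighbor
    distance ties resolve toward the earlier training row (stable sort).
    """

    def __init__(self, k: int = 5):
        self.k = int(k)

    def fit(self, F, y):
        self.F_ = np.asarray(F, dtype=float)
        self.y_ = np.asarray(y, dtype=int)
        self.classes_ = np.array(sorted(set(self.y_.tolist())))
        if self.k > len(self.y_):
            raise ValueError("k exceeds the number of training points")
        self._yidx = np.searchsorted(self.classes_, self.y_)
        return self

    def predict(self, F) -> np.ndarray:
        F = np.asarray(F, dtype=float)
        n = F.shape[0]
        C = len(self.classes_)
        out = np.empty(n, dtype=int)
        for start in range(0, n, 4096):
            chunk = F[start:start + 4096]
            D = cdist(chunk, self.F_)
            order = np.argsort(D, axis=1, kind="stable")[:, :self.k]
            nb_cls = self._yidx[order]                       # m x k
            nb_d = np.take_along_axis(D, order, axis=1)      # m x k
            onehot = nb_cls[:, :, None] == np.arange(C)[None, None, :]
            counts = onehot.sum(axis=1)                      # m x C
            dsum = (nb_d[:, :, None] * onehot).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                dmean = np.where(counts > 0, dsum / np.maximum(counts, 1), np.inf)
            best = counts.max(axis=1, keepdims=True)
            cand_mean = np.where(counts == best, dmean, np.inf)
            winner = cand_mean.argmin(axis=1)                # first min -> lower label
            out[start:start + 4096] = self.classes_[winner]
        return out


# ---------------------------------------------------------------------------
# Neural network (sklearn MLP behind validation-cube early stopping)
# ---------------------------------------------------------------------------

class _MinMaxScaler:
    """Train-set min-max scaling to [-1, 1]; frozen at fit time."""

    def fit(self, F):
        F = np.asarray(F, dtype=float)
        self.lo_ = F.min(axis=0)
        self.hi_ = F.max(axis=0)
        self.span_ = np.where(self.hi_ > self.lo_, self.hi_ - self.lo_, 1.0)
        return self

    def transform(self, F):
        return 2.0 * (np.asarray(F, dtype=float) - self.lo_) / self.span_ - 1.0


def _fit_nn(Ftr, ytr, Fval, yval, config: ClassifierConfig):
    """Quasi-Newton (lbfgs) training with early stopping on a validation set.

    The optimizer runs in short rounds; after each round the validation
    accuracy is evaluated and the best-so-far weights are kept.  Training
    stops once ``nn_patience`` rounds pass without improvement.
    """
    net = MLPClassifier(hidden_layer_sizes=(config.hidden_units,),
                        activation="logistic", solver="lbfgs",
                        alpha=1e-4, max_iter=config.nn_iter_per_round,
                        warm_start=True, random_state=config.seed)
    best_acc, best_net, stale = -np.inf, None, 0
    converged = False
    for _ in range(config.nn_max_rounds):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            net.fit(Ftr, ytr)
        acc = float(np.mean(net.predict(Fval) == yval))
        if acc > best_acc + 1e-12:
            best_acc, best_net, stale = acc, copy.deepcopy(net), 0
        else:
            stale += 1
            if stale >= config.nn_patience:
                converged = True
                break
    if not converged:
        logger.warning("network training stopped at the round limit; "
                       "returning the best-validation snapshot")
    return best_net


# ---------------------------------------------------------------------------
# The seven method configurations
# ---------------------------------------------------------------------------

@dataclass
class TrainedClassifier:
    """A frozen method configuration fitted on one cube's labeled spectra.

    The feature pipeline (PCA mean/loadings, SAM references, NN input
    scaling) is determined by the training data only and applied identically
    at prediction time.
    """

    method: str
    normalization: str
    pca: PcaModel | None = None
    sam: SamReference | None = None
    model: object | None = None
    scaler: _MinMaxScaler | None = None
    k: int = 5
    hidden_units: int = 10
    seed: int = 0
    training_cube_id: str | None = None

    def describe(self) -> dict:
        return {"method": self.method, "normalization": self.normalization,
                "k": self.k, "hidden_units": self.hidden_units, "seed": self.seed,
                "n_retained": None if self.pca is None else self.pca.n_retained,
                "training_cube_id": self.training_cube_id}


def _features(method: str, X, pca: PcaModel | None, sam: SamReference | None) -> np.ndarray:
    if method in _PCA_METHODS:
        return project_pca(pca, X)
    if method in ("SAM-min", "SAM-LDA", "SAM-KNN"):
        return spectral_angles(X, sam).angles
    return np.asarray(X, dtype=float)      # NN on raw spectra


def fit(method: str, train: LabeledSpectra, config: ClassifierConfig | None = None,
        validation: LabeledSpectra | None = None) -> TrainedClassifier:
    """Fit one of the seven method configurations on labeled training spectra.

    ``validation`` is required by the network methods for early stopping
    (the evaluation protocol supplies a held-out cube); if omitted, a seeded
    stratified 80/20 split of the training rows is used instead.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    config = config or ClassifierConfig()
    X, y = train.X, train.y
    present = set(np.unique(y).tolist())
    if present != set(CLASS_LABELS):
        raise ValueError(f"training data must contain all three classes, got {sorted(present)}")
    min_class = min(train.class_counts().values())
    if method.endswith("KNN") and config.k > min_class:
        raise ValueError(f"k={config.k} exceeds the smallest class size ({min_class})")

    pca = sam = model = scaler = None
    if method in _PCA_METHODS:
        n_ret = min(config.n_retained, X.shape[1])
        pca = fit_pca(X, n_retained=n_ret)
    if method.startswith("SAM"):
        sam = fit_sam_reference(X, y)
    F = _features(method, X, pca, sam)

    if method.endswith("LDA"):
        model = LinearDiscriminantAnalysis().fit(F, y)
    elif method.endswith("KNN"):
        model = _KNNClassifier(config.k).fit(F, y)
    elif method in _NN_METHODS:
        scaler = _MinMaxScaler().fit(F)
        if validation is not None:
            if validation.normalization != train.normalization:
                raise ValueError("validation normalization does not match training")
            Fval = _features(method, validation.X, pca, sam)
            yval = validation.y
            Ftr, ytr = F, y
        else:
            rng = np.random.default_rng(config.seed)
            val_idx = np.zeros(len(y), bool)
            for c in CLASS_LABELS:
                idx = np.flatnonzero(y == c)
                val_idx[rng.choice(idx, size=max(1, len(idx) // 5), replace=False)] = True
            Ftr, ytr = F[~val_idx], y[~val_idx]
            Fval, yval = F[val_idx], y[val_idx]
        model = _fit_nn(scaler.transform(Ftr), ytr, scaler.transform(Fval), yval, config)
    # SAM-min needs no inner model

    return TrainedClassifier(method=method, normalization=train.normalization,
                             pca=pca, sam=sam, model=model, scaler=scaler,
                             k=config.k, hidden_units=config.hidden_units,
                             seed=config.seed, training_cube_id=train.source_cube_id)


def predict(clf: TrainedClassifier, data) -> np.ndarray:
    """Predict class labels for spectra.

    ``data`` may be a :class:`LabeledSpectra` (its normalization tag must
    match the classifier's — a mismatch is the silent failure mode of
    exposure-sensitive pipelines and is refused) or a bare N x F matrix
    already normalized as the classifier expects.
    """
    if isinstance(data, LabeledSpectra):
        if data.normalization != clf.normalization:
            raise ValueError(
                f"normalization mismatch: classifier expects {clf.normalization!r}, "
                f"input is {data.normalization!r}")
        X = data.X
    else:
        X = np.asarray(data, dtype=float)
    if clf.method == "SAM-min":
        feats = spectral_angles(X, clf.sam)
        labels = np.asarray(clf.sam.class_labels)[np.argmin(feats.angles, axis=1)]
        # an all-zero spectrum is a dark pixel: assign background
        labels = np.where(feats.zero_rows, CLASS_BACKGROUND, labels)
        return labels.astype(int)
    F = _features(clf.method, X, clf.pca, clf.sam)
    if clf.scaler is not None:
        F = clf.scaler.transform(F)
    return np.asarray(clf.model.predict(F), dtype=int)


def predict_cube(clf: TrainedClassifier, cube) -> np.ndarray:
    """Classify every pixel of a cube into an H x W label map.

    The classifier's own normalization mode is applied to the pixel spectra.
    """
    X = cube.pixel_spectra()
    Xn = normalize_spectra(X, clf.normalization)
    labels = predict(clf, Xn)
    return labels.reshape(cube.data.shape[:2])


# ---------------------------------------------------------------------------
# Evaluation protocol
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    train_cube: str | None
    validation_cube: str | None
    accuracy: float
    per_class_accuracy: np.ndarray
    confusion: np.ndarray
    n_test: int


@dataclass
class EvalResult:
    """Cross-validated accuracy: overall, per class, confusion and breakdown.

    ``overall_accuracy`` and ``per_class_accuracy`` are averages over the
    permutations; ``confusion`` (rows = true, cols = predicted, class order
    tumor/non-tumor/background) is summed over them.
    """

    overall_accuracy: float
    per_class_accuracy: np.ndarray
    confusion: np.ndarray
    per_permutation: list


def _evaluate(y_true, y_pred) -> tuple[float, np.ndarray, np.ndarray]:
    conf = _sk_confusion(y_true, y_pred, labels=list(CLASS_LABELS))
    total = conf.sum()
    acc = float(np.trace(conf)) / total if total else np.nan
    row = conf.sum(axis=1)
    with np.errstate(invalid="ignore"):
        per_class = np.where(row > 0, np.diag(conf) / np.maximum(row, 1), np.nan)
    return acc, per_class, conf


def cross_validate(cubes, method: str, config: ClassifierConfig | None = None) -> EvalResult:
    """Leave-three-out cube protocol.

    For non-network methods each cube in turn is the training set and the
    remaining cubes form the pooled test set (four permutations with four
    cubes).  For the network methods one cube trains, the next cube in cyclic
    order validates, and the rest test.
    """
    cubes = list(cubes)
    n = len(cubes)
    is_nn = method in _NN_METHODS
    if n < (3 if is_nn else 2):
        raise ValueError(f"{method} needs at least {'3' if is_nn else '2'} cubes")
    norms = {c.normalization for c in cubes}
    if len(norms) > 1:
        raise ValueError("all cubes must share a normalization mode")

    perms = []
    total_conf = np.zeros((3, 3), dtype=int)
    for i in range(n):
        train = cubes[i]
        if is_nn:
            val = cubes[(i + 1) % n]
            test = [cubes[j] for j in range(n) if j not in (i, (i + 1) % n)]
            clf = fit(method, train, config, validation=val)
            val_id = val.source_cube_id
        else:
            test = [cubes[j] for j in range(n) if j != i]
            clf = fit(method, train, config)
            val_id = None
        y_true = np.concatenate([t.y for t in test])
        y_pred = np.concatenate([predict(clf, t) for t in test])
        acc, per_class, conf = _evaluate(y_true, y_pred)
        total_conf += conf
        perms.append(PermutationResult(train.source_cube_id, val_id, acc,
                                       per_class, conf, len(y_true)))
    overall = float(np.mean([p.accuracy for p in perms]))
    per_class = np.nanmean(np.stack([p.per_class_accuracy for p in perms]), axis=0)
    return EvalResult(overall, per_class, total_conf, perms)


def method_grid(datasets, methods=METHODS, normalizations=("max", "auc", "snv"),
                n_retained_list=(4, 5, 6),
                config: ClassifierConfig | None = None) -> pd.DataFrame:
    """Full factorial comparison: methods x normalizations (x PC counts).

    ``datasets`` is a sequence of ``(ImageCube, RoiSet)`` pairs; labeled
    spectra are re-extracted per normalization.  PC truncation applies to the
    PCA- methods only; the other methods get a single row each (``n_pcs`` is
    NA there).  Returns a tidy DataFrame sorted by overall accuracy.
    """
    from .preprocess import extract_labeled_spectra

    config = config or ClassifierConfig()
    rows = []
    for norm in normalizations:
        labeled = [extract_labeled_spectra(cube, rois, norm) for cube, rois in datasets]
        for method in methods:
            pc_list = n_retained_list if method in _PCA_METHODS else (None,)
            for n_pcs in pc_list:
                cfg = config if n_pcs is None else replace(config, n_retained=n_pcs)
                res = cross_validate(labeled, method, cfg)
                rows.append({"method": method, "normalization": norm,
                             "n_pcs": np.nan if n_pcs is None else n_pcs,
                             "overall_accuracy": res.overall_accuracy,
                             "accuracy_tumor": res.per_class_accuracy[0],
                             "accuracy_non_tumor": res.per_class_accuracy[1],
                             "accuracy_background": res.per_class_accuracy[2]})
    df = pd.DataFrame(rows).sort_values("overall_accuracy", ascending=False,
                                        kind="stable").reset_index(drop=True)
    return df


def save_classifier(clf: TrainedClassifier, path) -> None:
    """Serialize a trained classifier (method/config/seed travel with it)."""
    joblib.dump({"format": "swirclass-classifier-v1",
                 "header": clf.describe(), "classifier": clf}, path)


def load_classifier(path) -> TrainedClassifier:
    payload = joblib.load(path)
    if payload.get("format") != "swirclass-classifier-v1":
        raise ValueError("not a swirclass classifier archive")
    return payload["classifier"]
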