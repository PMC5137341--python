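"""Tree species recognition from hyperspectral pixels.

Pipeline: per-pixel brightness normalization (each spectrum divided by its
band sum), sunlit-pixel extraction inside every crown polygon, feature
selection by sequential forward floating selection (SFFS) under the
Jeffries-Matusita (JM) separability criterion, a pixel-level RBF support
vector machine, crown labels by majority vote over pixel predictions, and
confusion-matrix accuracy summaries (overall, kappa, producer's / user's
accuracies, average accuracy).

The JM distance between two classes modelled as Gaussians is
``JM = 2 (1 - exp(-B))`` with ``B`` the Bhattacharyya distance

    B = 1/8 (mu1-mu2)^T [(S1+S2)/2]^{-1} (mu1-mu2)
        + 1/2 ln( |(S1+S2)/2| / sqrt(|S1| |S2|) )

bounded in [0, 2]; 2 means asymptotically perfect separability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from shapely.geometry import Point
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io_formats import HyperCube

logger = logging.getLogger(__name__)

_COV_LOAD = 1e-6  # diagonal loading relative to mean variance


@dataclass
class PixelSample:
    """One crown pixel: normalized spectrum (+ optional ALS height feature)."""

    feature_vector: np.ndarray
    itc_id: int
    class_label: str | None = None


@dataclass
class ClassifierSpec:
    """SVM configuration and, after fitting, the trained model."""

    kernel: str = "rbf"
    c_grid: tuple = (0.1, 1.0, 10.0, 100.0, 1000.0)
    gamma_grid: tuple = (1e-3, 1e-2, 1e-1, 1.0, 10.0)
    cv_folds: int = 5
    seed: int = 0
    selected_features: list[int] | None = None
    model: Pipeline | None = field(default=None, repr=False)
    classes_: list[str] | None = None
    train_counts: dict[str, int] | None = None


def normalize_pixels(cube: HyperCube) -> HyperCube:
    """Divide each pixel spectrum by its band sum (sums to 1 afterwards).

    Zero-sum pixels are flagged nodata with a warning.
    """
    sums = cube.band_values.sum(axis=0)
    zero = sums <= 0
    if zero.any():
        logger.warning("%d zero-sum pixels flagged nodata", int(zero.sum()))
    safe = np.where(zero, 1.0, sums)
    vals = cube.band_values / safe
    vals[:, zero] = cube.nodata
    return HyperCube(cube.origin_x, cube.origin_y, cube.resolution,
                     vals, cube.wavelengths, cube.nodata)


def extract_sunlit_pixels(cube: HyperCube, itcs, normalized: HyperCube | None = None,
                          quantile: float = 0.5) -> list[PixelSample]:
    """Select the sunlit (brighter) pixels of each crown.

    A pixel belongs to an ITC when its centre is inside the polygon; within
    each ITC, pixels whose pre-normalization mean brightness is at or above
    the ITC's brightness quantile (default the median) are kept.  ITCs with
    fewer than 2 pixels keep all their pixels.  Feature vectors come from
    ``normalized`` when given, else from ``cube``.
    """
    src = normalized if normalized is not None else cube
    geom = cube.geometry()
    brightness = cube.band_values.mean(axis=0)
    samples: list[PixelSample] = []
    for itc in itcs:
        minx, miny, maxx, maxy = itc.polygon.bounds
        r0, c0 = geom.world_to_pixel(minx, maxy)
        r1, c1 = geom.world_to_pixel(maxx, miny)
        cand = []
        for r in range(max(int(r0), 0), min(int(r1) + 1, cube.n_rows)):
            for c in range(max(int(c0), 0), min(int(c1) + 1, cube.n_cols)):
                x, y = geom.pixel_center(r, c)
                p = Point(float(x), float(y))
                if itc.polygon.contains(p) or itc.polygon.touches(p):
                    cand.append((r, c))
        if not cand:
            logger.warning("ITC %d covers no pixel centre; skipped", itc.id)
            continue
        if len(cand) >= 2:
            bvals = np.array([brightness[r, c] for r, c in cand])
            cut = np.quantile(bvals, quantile)
            cand = [rc for rc, b in zip(cand, bvals) if b >= cut]
        for r, c in cand:
            samples.append(PixelSample(src.band_values[:, r, c].copy(), itc.id))
    return samples


# ---------------------------------------------------------------------------
# Jeffries-Matusita separability and SFFS feature selection
# ---------------------------------------------------------------------------


def _gauss_stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    if x.shape[0] > 1:
        cov = np.cov(x, rowvar=False)
    else:
        cov = np.zeros((x.shape[1], x.shape[1]))
    cov = np.atleast_2d(cov)
    load = _COV_LOAD * max(np.mean(np.diag(cov)), 1.0)
    cov = cov + load * np.eye(cov.shape[0])
    return mu, cov


def bhattacharyya(a: np.ndarray, b: np.ndarray) -> float:
    """Gaussian Bhattacharyya distance between two sample sets (n x d)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    mu1, s1 = _gauss_stats(a)
    mu2, s2 = _gauss_stats(b)
    sm = (s1 + s2) / 2.0
    diff = mu1 - mu2
    sign, logdet_m = np.linalg.slogdet(sm)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular pooled covariance")
    _, logdet_1 = np.linalg.slogdet(s1)
    _, logdet_2 = np.linalg.slogdet(s2)
    maha = float(diff @ np.linalg.solve(sm, diff))
    return 0.125 * maha + 0.5 * (logdet_m - 0.5 * (logdet_1 + logdet_2))


def jm_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Jeffries-Matusita distance, 2(1 - exp(-B)), in [0, 2]."""
    return float(2.0 * (1.0 - np.exp(-bhattacharyya(a, b))))


def _criterion(X: np.ndarray, y: np.ndarray, feats: list[int],
               mode: str = "mean") -> float:
    classes = np.unique(y)
    vals = [jm_distance(X[y == ca][:, feats], X[y == cb][:, feats])
            for ca, cb in combinations(classes, 2)]
    return float(np.mean(vals) if mode == "mean" else np.min(vals))


def sffs_select(X: np.ndarray, y: np.ndarray, n_features_target: int,
                criterion: str = "mean") -> list[int]:
    """Sequential forward floating selection under the JM criterion.

    Greedy forward additions of the feature maximizing the mean (or minimum)
    pairwise JM distance, each followed by conditional backward removals
    that are kept only while they improve the criterion.  Deterministic:
    ties resolve to the lowest feature index.  Returns sorted indices.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_avail = X.shape[1]
    if n_features_target > n_avail:
        raise ValueError("n_features_target exceeds available features")
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    if n_features_target == n_avail:
        return list(range(n_avail))

    selected: list[int] = []
    best_sets: dict[int, tuple[float, list[int]]] = {}

    def score(feats: list[int]) -> float:
        try:
            return _criterion(X, y, feats, criterion)
        except np.linalg.LinAlgError:
            return -np.inf

    max_steps = 20 * n_avail * n_features_target  # oscillation guard
    steps = 0
    while len(selected) < n_features_target:
        steps += 1
        if steps > max_steps:
            break
        # forward step
        cand = [f for f in range(n_avail) if f not in selected]
        scores = [(score(selected + [f]), -f) for f in cand]
        best = max(range(len(cand)), key=lambda i: scores[i])
        selected = sorted(selected + [cand[best]])
        k = len(selected)
        cur = score(selected)
        if k not in best_sets or cur > best_sets[k][0]:
            best_sets[k] = (cur, list(selected))
        # conditional backward steps
        while len(selected) > 2:
            k = len(selected)
            sub_scores = [(score([f for f in selected if f != r]), -r)
                          for r in selected]
            i_best = max(range(len(selected)), key=lambda i: sub_scores[i])
            reduced = [f for f in selected if f != selected[i_best]]
            red_score = sub_scores[i_best][0]
            prev = best_sets.get(k - 1, (-np.inf, None))[0]
            if red_score > prev:
                selected = reduced
                best_sets[k - 1] = (red_score, list(selected))
            else:
                break
    return sorted(best_sets[n_features_target][1])


# ---------------------------------------------------------------------------
# SVM training, crown labeling, accuracy metrics
# ---------------------------------------------------------------------------


def train_classifier(samples: list[PixelSample],
                     spec: ClassifierSpec | None = None) -> ClassifierSpec:
    """Fit the pixel-level SVM (RBF kernel, one-vs-one, CV-tuned C/gamma).

    Classes represented by fewer than 5 pixels are excluded with a warning.
    Feature selection (``spec.selected_features``) is applied to the stored
    vectors before fitting.
    """
    spec = spec or ClassifierSpec()
    labelled = [s for s in samples if s.class_label is not None]
    if not labelled:
        raise ValueError("no labelled samples")
    counts = pd.Series([s.class_label for s in labelled]).value_counts()
    keep_classes = set(counts[counts >= 5].index)
    dropped = set(counts.index) - keep_classes
    if dropped:
        logger.warning("classes with <5 pixels excluded: %s", sorted(dropped))
    labelled = [s for s in labelled if s.class_label in keep_classes]
    if len(keep_classes) < 2:
        raise ValueError("need at least 2 classes with >=5 pixels each")

    X = np.vstack([s.feature_vector for s in labelled])
    if spec.selected_features is not None:
        X = X[:, spec.selected_features]
    y = np.array([s.class_label for s in labelled])

    folds = min(spec.cv_folds, int(counts[counts >= 5].min()))
    cv = StratifiedKFold(n_splits=max(folds, 2), shuffle=True, random_state=spec.seed)
    pipe = Pipeline([("scale", StandardScaler()),
                     ("svm", SVC(kernel=spec.kernel, decision_function_shape="ovo"))])
    search = GridSearchCV(pipe, {"svm__C": list(spec.c_grid),
                                 "svm__gamma": list(spec.gamma_grid)}, cv=cv)
    search.fit(X, y)
    spec.model = search.best_estimator_
    spec.classes_ = list(search.best_estimator_.named_steps["svm"].classes_)
    spec.train_counts = counts.to_dict()
    return spec


def classify_itcs(fitted: ClassifierSpec,
                  samples: list[PixelSample]) -> dict[int, str]:
    """Majority-rule crown labels from pixel predictions.

    Ties go to the label with the greater mean decision confidence, then to
    lexicographic label order.  Crowns with no pixels get ``"unknown"``.
    """
    if fitted.model is None:
        raise ValueError("classifier not fitted")
    if not samples:
        return {}
    X = np.vstack([s.feature_vector for s in samples])
    if fitted.selected_features is not None:
        X = X[:, fitted.selected_features]
    pred = fitted.model.predict(X)
    # per-class confidence from one-vs-rest view of the decision function
    svm = fitted.model.named_steps["svm"]
    classes = list(svm.classes_)
    if len(classes) == 2:
        dec = fitted.model.decision_function(X)
        conf = np.column_stack([-dec, dec])
    else:
        ovo = fitted.model.decision_function(X)
        conf = np.zeros((X.shape[0], len(classes)))
        k = 0
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                conf[:, i] += ovo[:, k]
                conf[:, j] -= ovo[:, k]
                k += 1
    out: dict[int, str] = {}
    df = pd.DataFrame({"itc": [s.itc_id for s in samples], "pred": pred})
    for itc_id, grp in df.groupby("itc"):
        votes = grp["pred"].value_counts()
        top = votes[votes == votes.max()].index.tolist()
        if len(top) == 1:
            out[int(itc_id)] = top[0]
        else:
            rows = grp.index.to_numpy()
            mean_conf = {
                lab: float(conf[rows][df.loc[rows, "pred"].to_numpy() == lab,
                                      classes.index(lab)].mean())
                for lab in top}
            out[int(itc_id)] = min(top, key=lambda l: (-mean_conf[l], l))
    return out


@dataclass
class ConfusionMatrix:
    """k x k counts; rows = predicted class, columns = reference class."""

    counts: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be k x k with one label per class")
        if (self.counts < 0).any() or self.counts.sum() == 0:
            raise ValueError("counts must be non-negative with positive total")

    @classmethod
    def from_predictions(cls, predicted, reference, labels=None) -> "ConfusionMatrix":
        labels = list(labels) if labels is not None else \
            sorted(set(predicted) | set(reference))
        idx = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for p, r in zip(predicted, reference):
            counts[idx[p], idx[r]] += 1
        return cls(counts, labels)


@dataclass
class AccuracySummary:
    overall_acc_pct: float
    kappa: float
    producers_acc_pct: dict[str, float]
    users_acc_pct: dict[str, float]
    average_acc_pct: float


def load_packaged_confusion() -> ConfusionMatrix:
    """ITC-level species confusion matrix of a 7-class Alpine conifer test set."""
    from importlib import resources

    with resources.files("canopycarbon.data").joinpath(
            "species_confusion_testset.csv").open() as fh:
        df = pd.read_csv(fh, index_col=0)
    return ConfusionMatrix(df.to_numpy(), list(df.columns))


def confusion_metrics(cm: ConfusionMatrix) -> AccuracySummary:
    """Overall %, kappa, producer's/user's accuracies and their class mean.

    Producer's accuracy of class j = 100 * cm[j,j] / column_sum(j) (reference
    recall); user's = row-based precision; average = unweighted mean of the
    producer's accuracies; kappa = (p_o - p_e) / (1 - p_e) with
    p_e = sum_j row_sum(j) col_sum(j) / total^2.
    """
    c = cm.counts.astype(float)
    total = c.sum()
    overall = 100.0 * np.trace(c) / total
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    pe = float(np.sum(row * col)) / total ** 2
    kappa = (overall / 100.0 - pe) / (1.0 - pe) if pe < 1 else 1.0
    producers: dict[str, float] = {}
    users: dict[str, float] = {}
    for j, lab in enumerate(cm.labels):
        if col[j] > 0:
            producers[lab] = 100.0 * c[j, j] / col[j]
        else:
            logger.warning("class %s has no reference samples; producer's "
                           "accuracy undefined", lab)
        if row[j] > 0:
            users[lab] = 100.0 * c[j, j] / row[j]
    average = float(np.mean(list(producers.values())))
    return AccuracySummary(float(overall), float(kappa), producers, users, average)
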