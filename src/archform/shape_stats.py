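"""Classifier-based shape comparison, k-means clustering and associations.

Three analyses operate on fixed-length shape vectors of normalized arch
forms:

* the *difference* experiment trains binary classifiers (KNN, naive Bayes,
  RBF-SVM) to separate two subject subsets; accuracy near 0.5 means the two
  data types are indistinguishable (random guessing on a balanced set),
  accuracy near 1 a discernible difference;
* *clustering* partitions shapes with k-means, choosing k by the Elbow
  method: the within-cluster sum of squares (WSS) is computed over candidate
  k and the k where the marginal WSS improvement collapses is located by a
  cumulative-sum (CuSum) change detector;
* the *association* matrix cross-tabulates each subject's dental and
  dentoalveolar cluster memberships as proportions of the cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "ShapeStatsError",
    "ConfusionMatrix",
    "MetricsResult",
    "ExperimentResult",
    "ArchClusterModel",
    "AssociationMatrix",
    "compute_metrics",
    "run_difference_experiment",
    "compute_wss_curve",
    "choose_k_elbow_cusum",
    "cluster_arch_forms",
    "build_association_matrix",
    "DATASETS",
    "CLASSIFIERS",
]


class ShapeStatsError(ValueError):
    pass


DATASETS = ("ND-ND", "NA-NA", "ND-NA")

#: classifier factories; hyperparameters are fixed here and logged in output
CLASSIFIERS = {
    "KNN": lambda: KNeighborsClassifier(n_neighbors=5, metric="euclidean"),
    "NB": lambda: GaussianNB(),
    "SVM": lambda: SVC(kernel="rbf"),
}


# ---------------------------------------------------------------------------
# confusion matrix and metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ShapeStatsError("confusion-matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_labels(cls, y_true, y_pred, positive=1) -> "ConfusionMatrix":
        yt = np.asarray(y_true) == positive
        yp = np.asarray(y_pred) == positive
        return cls(
            tp=int(np.sum(yt & yp)),
            fn=int(np.sum(yt & ~yp)),
            fp=int(np.sum(~yt & yp)),
            tn=int(np.sum(~yt & ~yp)),
        )


@dataclass(frozen=True)
class MetricsResult:
    accuracy: float
    sensitivity: float | None
    f1: float


def compute_metrics(cm: ConfusionMatrix) -> MetricsResult:
    """Accuracy, sensitivity and F1 score from a binary confusion matrix.

    accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN),
    F1 = 2 TP / (2 TP + FP + FN).  Sensitivity is undefined (None, with a
    warning) when there are no positive samples; F1 is 0 when TP = 0.
    """
    if cm.total <= 0:
        raise ShapeStatsError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    if cm.tp + cm.fn == 0:
        warnings.warn("no positive samples; sensitivity undefined", stacklevel=2)
        sensitivity = None
    else:
        sensitivity = cm.tp / (cm.tp + cm.fn)
    denom = 2 * cm.tp + cm.fp + cm.fn
    f1 = (2 * cm.tp / denom) if denom > 0 else 0.0
    return MetricsResult(accuracy=accuracy, sensitivity=sensitivity, f1=f1)


# ---------------------------------------------------------------------------
# difference experiment
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    """Per (dataset, classifier) summary over repeats."""

    table: pd.DataFrame
    n_repeats: int

    def mean_accuracy(self, dataset: str, classifier: str | None = None) -> float:
        t = self.table[self.table["dataset"] == dataset]
        if classifier is not None:
            t = t[t["classifier"] == classifier]
        return float(t["mean_accuracy"].mean())


def run_difference_experiment(
    forms_nd: np.ndarray,
    forms_na: np.ndarray,
    repeats: int = 100,
    seed: int | None = None,
    ci_method: str = "normal",
) -> ExperimentResult:
    """Repeated ND/NA comparison with three classifiers.

    Per repeat the subject indices are split 50/50 into S1 and S2
    (floor/ceil for odd cohorts); the control datasets ND-ND and NA-NA give
    S1 and S2 the same data type with labels 0/1, the experimental dataset
    ND-NA gives S1 the dental and S2 the dentoalveolar shapes.  Rows are
    shuffled, the first 80% train and the last 20% test each classifier.
    The positive class is label 1 (S2's type).  Means and 95% confidence
    intervals of accuracy over repeats are reported.
    """
    nd = np.atleast_2d(np.asarray(forms_nd, float))
    na = np.atleast_2d(np.asarray(forms_na, float))
    if nd.shape != na.shape:
        raise ShapeStatsError("ND and NA must be paired arrays of equal shape")
    n = len(nd)
    if n < 10:
        raise ShapeStatsError("need at least 10 subjects for an 80/20 split")
    if repeats < 1:
        raise ShapeStatsError("repeats must be >= 1")
    if ci_method not in ("normal", "percentile"):
        raise ShapeStatsError("ci_method must be 'normal' or 'percentile'")
    rng = np.random.default_rng(seed)
    acc: dict = {(d, c): [] for d in DATASETS for c in CLASSIFIERS}
    sens: dict = {(d, c): [] for d in DATASETS for c in CLASSIFIERS}
    f1s: dict = {(d, c): [] for d in DATASETS for c in CLASSIFIERS}
    n1 = n // 2
    n_train = int(n * 0.8)
    for _ in range(repeats):
        perm = rng.permutation(n)
        s1, s2 = perm[:n1], perm[n1:]
        sources = {
            "ND-ND": (nd[s1], nd[s2]),
            "NA-NA": (na[s1], na[s2]),
            "ND-NA": (nd[s1], na[s2]),
        }
        for ds, (x1, x2) in sources.items():
            X = np.vstack([x1, x2])
            y = np.concatenate([np.zeros(len(x1)), np.ones(len(x2))])
            order = rng.permutation(n)
            X, y = X[order], y[order]
            Xtr, ytr = X[:n_train], y[:n_train]
            Xte, yte = X[n_train:], y[n_train:]
            for name, factory in CLASSIFIERS.items():
                clf = factory()
                clf.fit(Xtr, ytr)
                cm = ConfusionMatrix.from_labels(yte, clf.predict(Xte), positive=1)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m = compute_metrics(cm)
                acc[(ds, name)].append(m.accuracy)
                sens[(ds, name)].append(np.nan if m.sensitivity is None else m.sensitivity)
                f1s[(ds, name)].append(m.f1)
    rows = []
    for ds in DATASETS:
        for name in CLASSIFIERS:
            a = np.asarray(acc[(ds, name)])
            mean = a.mean()
            if ci_method == "percentile" and repeats > 1:
                lo, hi = np.percentile(a, [2.5, 97.5])
            elif repeats > 1:
                half = 1.96 * a.std(ddof=1) / np.sqrt(repeats)
                lo, hi = mean - half, mean + half
            else:
                lo = hi = mean
            rows.append(
                {
                    "dataset": ds,
                    "classifier": name,
                    "mean_accuracy": mean,
                    "ci_low": lo,
                    "ci_high": hi,
                    "mean_sensitivity": float(np.nanmean(sens[(ds, name)])),
                    "mean_f1": float(np.mean(f1s[(ds, name)])),
                }
            )
    return ExperimentResult(table=pd.DataFrame(rows), n_repeats=repeats)


# ---------------------------------------------------------------------------
# k-means with Elbow + CuSum model selection
# ---------------------------------------------------------------------------


@dataclass
class ArchClusterModel:
    k: int
    centers: np.ndarray             # (k, m)
    labels: np.ndarray              # per-subject cluster id in 1..k
    member_distances: np.ndarray    # Euclidean distance to own center
    mu: np.ndarray                  # per-cluster mean member distance
    sigma: np.ndarray               # per-cluster member-distance sd
    wss_curve: dict = field(default_factory=dict)  # k -> WSS

    @property
    def wss(self) -> float:
        return float(np.sum(self.member_distances**2))


def compute_wss_curve(
    vectors: np.ndarray, k_max: int = 10, n_init: int = 10, seed: int | None = None
) -> np.ndarray:
    """WSS of best-of-n_init k-means for k = 1..k_max."""
    X = np.atleast_2d(np.asarray(vectors, float))
    k_max = min(k_max, len(X))
    out = np.empty(k_max)
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=_seed32(seed, k)).fit(X)
        out[k - 1] = km.inertia_
    return out


def choose_k_elbow_cusum(wss_curve: np.ndarray) -> int:
    """Elbow of a WSS curve located by CuSum change detection.

    The relative per-k drop d_k = (WSS(k-1) - WSS(k)) / WSS(k-1) collapses
    by an order of magnitude once k exceeds the true cluster count, so the
    change detection runs on log d_k: the cumulative sum of mean-adjusted
    log-drops peaks at the last k of the high-drop regime, which is
    returned.  An (almost) flat curve returns 1.  Non-monotone segments are
    tolerated (non-positive drops count as negligible improvement).
    """
    wss = np.asarray(wss_curve, float)
    if len(wss) < 3:
        raise ShapeStatsError("need WSS over at least k = 1..3")
    scale = max(abs(wss[0]), 1e-300)
    if (wss[0] - wss.min()) <= 1e-9 * scale:
        return 1
    prev = np.where(np.abs(wss[:-1]) > 0, wss[:-1], 1e-300)
    drops = np.clip((wss[:-1] - wss[1:]) / prev, 1e-12, None)
    log_drops = np.log(drops)
    cusum = np.cumsum(log_drops - log_drops.mean())
    return int(np.argmax(cusum)) + 2  # drop index i corresponds to k = i + 2


def _seed32(seed: int | None, salt: int) -> int | None:
    if seed is None:
        return None
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31))


def cluster_arch_forms(
    vectors: np.ndarray,
    k: int | str = "auto",
    n_init: int = 10,
    seed: int | None = None,
    k_max: int = 10,
) -> ArchClusterModel:
    """Best-of-n_init k-means (k-means++ seeding) with per-cluster distance stats.

    With ``k="auto"`` the WSS curve over k = 1..k_max is computed and the
    Elbow+CuSum rule picks k.  Cluster labels are 1..k; mu and sigma are the
    mean and sd of member distances to the own center, the reference used by
    the outlier rule.
    """
    X = np.atleast_2d(np.asarray(vectors, float))
    wss_curve: dict = {}
    if k == "auto":
        curve = compute_wss_curve(X, k_max=k_max, n_init=n_init, seed=seed)
        wss_curve = {i + 1: float(w) for i, w in enumerate(curve)}
        k = choose_k_elbow_cusum(curve)
    k = int(k)
    if k > len(X):
        raise ShapeStatsError(f"k={k} exceeds the number of vectors ({len(X)})")
    if k < 1:
        raise ShapeStatsError("k must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=_seed32(seed, 0)).fit(X)
    labels = km.labels_ + 1
    dists = np.linalg.norm(X - km.cluster_centers_[km.labels_], axis=1)
    mu = np.zeros(k)
    sigma = np.zeros(k)
    for j in range(k):
        d = dists[km.labels_ == j]
        mu[j] = d.mean() if len(d) else 0.0
        sigma[j] = d.std(ddof=1) if len(d) > 1 else 0.0
    wss_curve.setdefault(k, float(km.inertia_))
    return ArchClusterModel(
        k=k,
        centers=km.cluster_centers_,
        labels=labels,
        member_distances=dists,
        mu=mu,
        sigma=sigma,
        wss_curve=wss_curve,
    )


# ---------------------------------------------------------------------------
# association matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationMatrix:
    """cells[i-1, j-1] = fraction of subjects in dental cluster i and
    dentoalveolar cluster j; cells sum to 1."""

    cells: np.ndarray
    n_subjects: int

    def cell(self, dental: int, alveolar: int) -> float:
        if not (1 <= dental <= self.cells.shape[0] and 1 <= alveolar <= self.cells.shape[1]):
            raise ShapeStatsError("cluster id out of range")
        return float(self.cells[dental - 1, alveolar - 1])


def build_association_matrix(
    dental_labels: np.ndarray,
    alveolar_labels: np.ndarray,
    k_d: int | None = None,
    k_a: int | None = None,
) -> AssociationMatrix:
    """Cross-tabulate dental vs dentoalveolar cluster memberships."""
    d = np.asarray(dental_labels, dtype=int)
    a = np.asarray(alveolar_labels, dtype=int)
    if len(d) != len(a):
        raise ShapeStatsError("label sequences differ in length")
    if len(d) == 0:
        raise ShapeStatsError("empty label sequences")
    if d.min() < 1 or a.min() < 1:
        raise ShapeStatsError("cluster labels must be 1-based")
    k_d = int(d.max()) if k_d is None else k_d
    k_a = int(a.max()) if k_a is None else k_a
    cells = np.zeros((k_d, k_a))
    np.add.at(cells, (d - 1, a - 1), 1.0)
    return AssociationMatrix(cells=cells / len(d), n_subjects=len(d))
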