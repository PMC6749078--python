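"""Two-stage k-means++ metastate extraction under correlation distance.

Windowed, z-normalized centrality vectors are the samples; a metastate is a
cluster center (the arithmetic mean of its members). The group stage pools
all subjects' windows and clusters with k-means++ initialization; the
individual stage re-runs Lloyd iterations per subject starting from the
group centers. Correlation distance d(u, v) = 1 - Pearson(u, v).

For row-standardized samples this is spherical k-means after centering, so
Lloyd iterations with plain-mean centroid updates descend monotonically;
the descent is asserted at every iteration.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)


def _center_unit(X: np.ndarray, what: str = "vector") -> np.ndarray:
    """Rows centered and scaled to unit norm; errors on constant rows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    bad = np.flatnonzero(norms.ravel() == 0)
    if bad.size:
        raise ValueError(f"constant {what} (row {bad[0]}): correlation undefined")
    return Xc / norms


def correlation_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - Pearson correlation; in [0, 2]."""
    uh = _center_unit(u)[0]
    vh = _center_unit(v)[0]
    return float(1.0 - uh @ vh)


def _distance_matrix(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Pairwise correlation distance between sample rows and center rows."""
    return 1.0 - _center_unit(X, "sample") @ _center_unit(C, "center").T


@dataclasses.dataclass
class MetastateModel:
    """A fitted set of metastates: centers, labels, and fit metadata."""

    centers: np.ndarray  # k x regions, z-units
    labels: np.ndarray  # per-window state index
    k: int
    inertia: float
    seed: int | None
    distance: str = "correlation"
    validity_curve: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "k": self.k,
            "distance": self.distance,
            "seed": self.seed,
            "inertia": self.inertia,
            "centers": self.centers.tolist(),
            "labels": self.labels.tolist(),
        }
        if self.validity_curve is not None:
            d["validity_curve"] = self.validity_curve
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MetastateModel":
        return cls(
            centers=np.asarray(d["centers"], dtype=float),
            labels=np.asarray(d["labels"], dtype=int),
            k=int(d["k"]),
            inertia=float(d["inertia"]),
            seed=d.get("seed"),
            distance=d.get("distance", "correlation"),
            validity_curve=d.get("validity_curve"),
        )


class MetastateKMeans(BaseEstimator, ClusterMixin):
    """k-means++ clustering under correlation distance.

    Parameters
    ----------
    n_clusters : number of metastates k.
    n_init : random restarts; the run with the lowest inertia wins.
    max_iter : Lloyd iteration cap per run.
    random_state : seed for the k-means++ initialization.
    init : optional explicit (k x p) initial centers; overrides seeding and
        forces a single run (the individual-stage refinement path).
    on_empty : what to do when a cluster loses all members: "reseed" moves
        its center to the sample farthest from its assigned center (group
        stage); "keep" leaves the center where it is (refinement stage, so
        a state absent from one subject keeps its group-level identity).

    Attributes
    ----------
    cluster_centers_ : (k, p) arithmetic means of member vectors.
    labels_ : per-sample state indices, ties broken toward the lowest index.
    inertia_ : summed correlation distance of samples to their centers.
    n_iter_ : Lloyd iterations of the winning run.
    """

    def __init__(
        self,
        n_clusters: int = 5,
        n_init: int = 10,
        max_iter: int = 300,
        random_state: int | None = None,
        init: np.ndarray | None = None,
        on_empty: str = "reseed",
    ):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state
        self.init = init
        self.on_empty = on_empty

    # -- internals ---------------------------------------------------------

    def _seed_centers(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """k-means++ seeding with correlation distance playing the role of
        the squared Euclidean distance (to which it is proportional for
        centered unit-norm vectors)."""
        n = X.shape[0]
        idx = [int(rng.integers(n))]
        for _ in range(1, self.n_clusters):
            d = _distance_matrix(X, X[idx]).min(axis=1)
            d = np.clip(d, 0.0, None)
            total = d.sum()
            if total <= 0:
                remaining = np.setdiff1d(np.arange(n), idx)
                idx.append(int(rng.choice(remaining)))
            else:
                idx.append(int(rng.choice(n, p=d / total)))
        return X[idx].copy()

    def _lloyd(self, X: np.ndarray, centers: np.ndarray) -> tuple:
        k = self.n_clusters
        prev_labels = None
        prev_inertia = np.inf
        labels = None
        n_iter = 0
        reseeded = False
        for n_iter in range(1, self.max_iter + 1):
            D = _distance_matrix(X, centers)
            labels = D.argmin(axis=1)  # argmin takes the lowest index on ties
            inertia = float(D[np.arange(X.shape[0]), labels].sum())
            # descent is exact for row-standardized samples; a forced
            # empty-cluster reseed is exempt from the check
            if not reseeded and inertia > prev_inertia + 1e-9:
                raise RuntimeError(
                    f"Lloyd inertia increased ({prev_inertia} -> {inertia})"
                )
            prev_inertia = inertia
            reseeded = False
            # empty clusters: re-seed at the sample farthest from its center,
            # or (refinement stage) keep the initialized center in place
            if self.on_empty == "reseed":
                for c in range(k):
                    if not (labels == c).any():
                        far = int(D[np.arange(X.shape[0]), labels].argmax())
                        labels[far] = c
                        reseeded = True
                        logger.info("re-seeded empty cluster %d at sample %d", c, far)
            if prev_labels is not None and np.array_equal(labels, prev_labels):
                break
            centers = np.stack([
                X[labels == c].mean(axis=0) if (labels == c).any() else centers[c]
                for c in range(k)
            ])
            prev_labels = labels
        D = _distance_matrix(X, centers)
        inertia = float(D[np.arange(X.shape[0]), labels].sum())
        return centers, labels, inertia, n_iter

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x regions)")
        if X.shape[0] < self.n_clusters:
            raise ValueError(
                f"{X.shape[0]} samples for k={self.n_clusters} clusters"
            )
        _center_unit(X, "sample")  # validates nonconstant rows up front
        if self.init is not None:
            init = np.asarray(self.init, dtype=float)
            if init.shape != (self.n_clusters, X.shape[1]):
                raise ValueError("init centers have the wrong shape")
            runs = [self._lloyd(X, init.copy())]
        else:
            ss = np.random.SeedSequence(self.random_state)
            runs = [
                self._lloyd(X, self._seed_centers(X, np.random.default_rng(child)))
                for child in ss.spawn(self.n_init)
            ]
        best = min(runs, key=lambda r: r[2])
        self.cluster_centers_, self.labels_, self.inertia_, self.n_iter_ = best
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X, dtype=float)
        return _distance_matrix(X, self.cluster_centers_).argmin(axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def to_model(self, validity_curve: dict | None = None) -> MetastateModel:
        check_is_fitted(self, "cluster_centers_")
        return MetastateModel(
            centers=self.cluster_centers_,
            labels=self.labels_,
            k=self.n_clusters,
            inertia=self.inertia_,
            seed=self.random_state,
            validity_curve=validity_curve,
        )


def kmeans_pp(
    samples: np.ndarray,
    k: int,
    seed: int | None = None,
    n_init: int = 10,
) -> MetastateModel:
    """Functional wrapper: fit ``MetastateKMeans`` and return the model."""
    est = MetastateKMeans(n_clusters=k, n_init=n_init, random_state=seed)
    est.fit(samples)
    return est.to_model()


def metastate_centers(samples: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-state arithmetic mean centrality pattern."""
    samples = np.asarray(samples, dtype=float)
    labels = np.asarray(labels, dtype=int)
    k = labels.max() + 1
    out = []
    for c in range(k):
        members = samples[labels == c]
        if members.shape[0] == 0:
            raise ValueError(f"state {c} has no member windows")
        out.append(members.mean(axis=0))
    return np.stack(out)


def elbow_select_k(
    samples: np.ndarray,
    k_range: tuple[int, int] = (2, 10),
    seed: int | None = None,
    n_init: int = 10,
) -> tuple[int, dict]:
    """Choose k by the elbow of the best-inertia curve.

    Fits every k in the inclusive range (``n_init`` restarts each, best
    inertia kept) and returns the k maximizing the second-order difference
    of the inertia curve, i.e. the sharpest kink. The mean-silhouette curve
    (correlation metric) is reported alongside as a secondary diagnostic.
    """
    lo, hi = int(k_range[0]), int(k_range[1])
    if hi - lo < 2:
        raise ValueError("k_range must span at least 3 values for an elbow")
    samples = np.asarray(samples, dtype=float)
    ks = list(range(lo, hi + 1))
    ss = np.random.SeedSequence(seed)
    inertias = []
    silhouettes = []
    for k, child in zip(ks, ss.spawn(len(ks))):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        model = kmeans_pp(samples, k, seed=sub_seed, n_init=n_init)
        inertias.append(model.inertia)
        if len(np.unique(model.labels)) > 1:
            sil = float(
                silhouette_score(samples, model.labels, metric="correlation")
            )
        else:
            sil = float("nan")
        silhouettes.append(sil)
    curve = np.asarray(inertias)
    second_diff = curve[:-2] - 2 * curve[1:-1] + curve[2:]
    k_star = ks[1 + int(second_diff.argmax())]
    validity = {
        "k": ks,
        "inertia": [float(v) for v in inertias],
        "silhouette": silhouettes,
        "second_diff": [float(v) for v in second_diff],
    }
    return k_star, validity


@dataclasses.dataclass
class StateMatching:
    """Optimal bijection between two models' state indices."""

    permutation: np.ndarray  # permutation[a] = matched index in B
    matched_distances: np.ndarray
    total_distance: float


def match_states(centers_a: np.ndarray, centers_b: np.ndarray) -> StateMatching:
    """Hungarian matching of state centers by correlation distance."""
    A = np.asarray(centers_a, dtype=float)
    B = np.asarray(centers_b, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError(f"unequal state counts: {A.shape[0]} vs {B.shape[0]}")
    cost = _distance_matrix(A, B)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(A.shape[0], dtype=int)
    perm[rows] = cols
    dists = cost[rows, cols]
    return StateMatching(
        permutation=perm,
        matched_distances=dists,
        total_distance=float(dists.sum()),
    )


@dataclasses.dataclass
class TwoStageResult:
    group_model: MetastateModel
    subject_labels: list[np.ndarray]
    subject_models: list[MetastateModel | None]


def two_stage_fit(
    group_samples: list[np.ndarray],
    k: int,
    seed: int | None = None,
    n_init: int = 10,
) -> TwoStageResult:
    """Group-level k-means++ on pooled windows, then per-subject Lloyd
    refinement initialized at the group centers.

    Subject labels are reported against the group state indices: each
    subject's refined centers are matched back to the group centers and the
    labels relabeled through that bijection. A subject with fewer windows
    than k is assigned by nearest group center without refinement.
    """
    mats = [np.asarray(m, dtype=float) for m in group_samples]
    p = mats[0].shape[1]
    if any(m.shape[1] != p for m in mats):
        raise ValueError("subjects disagree on region dimension")
    pooled = np.vstack(mats)
    group_model = kmeans_pp(pooled, k, seed=seed, n_init=n_init)
    subject_labels: list[np.ndarray] = []
    subject_models: list[MetastateModel | None] = []
    for s, m in enumerate(mats):
        if m.shape[0] < k:
            logger.info("subject %d has fewer windows than k; nearest-center labels", s)
            labels = _distance_matrix(m, group_model.centers).argmin(axis=1)
            subject_labels.append(labels)
            subject_models.append(None)
            continue
        est = MetastateKMeans(
            n_clusters=k, init=group_model.centers, max_iter=300, on_empty="keep"
        )
        est.fit(m)
        matching = match_states(est.cluster_centers_, group_model.centers)
        subject_labels.append(matching.permutation[est.labels_])
        subject_models.append(est.to_model())
    return TwoStageResult(group_model, subject_labels, subject_models)
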