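"""Biotype extraction: consensus clustering plus discriminant validation.

The procedure operates on a six-variable network feature table per subject
(prestimulus and modulation values of path length, connectivity strength
and small-world index):

1. z-score each feature;
2. choose the number of clusters by majority vote of a validity-index
   ensemble (ties broken toward the smallest k);
3. partition with k-means, keeping the best of 50 random-centroid
   restarts by mean silhouette width;
4. check stability with a CLARA-style k-medoids run on random subsets
   (agreement with the k-means partition after optimal label matching);
5. characterise the subgroups with a linear discriminant function,
   validated by leave-one-out (jackknife) reclassification; and
6. project held-out samples (replication set, controls) through the
   stored z-scoring and discriminant function.

The two estimators (:class:`BiotypeClustering`,
:class:`BiotypeDiscriminant`) follow scikit-learn conventions
(``fit`` / ``predict``, ``get_params``, fitted attributes with trailing
underscores) and compose with sklearn model selection; the module-level
functions are thin wrappers over them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import silhouette_score

from .validity import DEFAULT_INDICES, index_votes, majority_k

FEATURE_COLUMNS = (
    "pl_prestim",
    "cs_prestim",
    "sw_prestim",
    "pl_modulation",
    "cs_modulation",
    "sw_modulation",
)

#: Feature whose coefficient anchors the rescaled discriminant vector.
_SCALE_ANCHOR = "pl_modulation"


def _as_array(table) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), list(table.columns)
    x = np.asarray(table, dtype=float)
    return x, [f"f{i}" for i in range(x.shape[1])]


@dataclass
class ZScoreParams:
    """Column means/SDs stored at fit time for projecting new samples."""

    mean: np.ndarray
    sd: np.ndarray
    columns: list[str] = field(default_factory=list)

    def transform(self, table) -> np.ndarray:
        x, cols = _as_array(table)
        if isinstance(table, pd.DataFrame) and self.columns:
            missing = [c for c in self.columns if c not in table.columns]
            if missing:
                raise ValueError(f"feature mismatch: missing columns {missing}")
            x = table[self.columns].to_numpy(dtype=float)
        elif x.shape[1] != len(self.mean):
            raise ValueError(
                f"feature mismatch: expected {len(self.mean)} columns, "
                f"got {x.shape[1]}"
            )
        return (x - self.mean) / self.sd


def zscore(table) -> tuple[pd.DataFrame, ZScoreParams]:
    """Column-wise z-scoring; returns the table and reusable parameters."""
    x, cols = _as_array(table)
    if len(x) < 2:
        raise ValueError("z-scoring needs >= 2 subjects")
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [cols[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance column(s): {bad}")
    params = ZScoreParams(mean=x.mean(axis=0), sd=sd, columns=cols)
    z = pd.DataFrame(params.transform(table), columns=cols)
    return z, params


def select_k(
    table,
    k_range: tuple[int, int] = (2, 8),
    indices: tuple[str, ...] = DEFAULT_INDICES,
    seed: int = 0,
) -> tuple[int, dict[str, int]]:
    """Consensus cluster count: each validity index votes, the modal k
    wins, ties go to the smallest k."""
    x, _ = _as_array(table)
    votes = index_votes(x, k_range=k_range, seed=seed, indices=indices)
    return majority_k(votes), votes


def match_labels(
    reference: np.ndarray, other: np.ndarray
) -> tuple[np.ndarray, float]:
    """Optimally relabel ``other`` onto ``reference`` (Hungarian matching
    on the confusion matrix); returns (relabelled, agreement fraction)."""
    reference = np.asarray(reference)
    other = np.asarray(other)
    ref_ids = np.unique(reference)
    oth_ids = np.unique(other)
    confusion = np.zeros((len(oth_ids), len(ref_ids)))
    for i, a in enumerate(oth_ids):
        for j, b in enumerate(ref_ids):
            confusion[i, j] = np.sum((other == a) & (reference == b))
    rows, cols = linear_sum_assignment(-confusion)
    mapping = {oth_ids[r]: ref_ids[c] for r, c in zip(rows, cols)}
    fallback = ref_ids[0]
    relabelled = np.array([mapping.get(v, fallback) for v in other])
    return relabelled, float(np.mean(relabelled == reference))


@dataclass
class ClusterSolution:
    """Outcome of the two-stage clustering on one feature table."""

    k: int
    labels: np.ndarray
    index_votes: dict[str, int]
    silhouette: float
    restart_seeds: list[int]
    stability_agreement: float
    zscore_params: ZScoreParams | None = None


def kmeans_best_silhouette(
    table, k: int, n_init: int = 50, seed: int = 0
) -> ClusterSolution:
    """k-means from ``n_init`` random centroid draws; the restart with the
    best mean silhouette width wins.  Input should already be z-scored."""
    x, _ = _as_array(table)
    rng = np.random.default_rng(seed)
    restart_seeds = [int(s) for s in rng.integers(2**31, size=n_init)]
    best = None
    for s in restart_seeds:
        km = KMeans(n_clusters=k, n_init=1, init="random", random_state=s).fit(x)
        if len(np.unique(km.labels_)) < k:
            continue
        sil = silhouette_score(x, km.labels_)
        if best is None or sil > best[0]:
            best = (sil, km)
    if best is None:
        raise ValueError(f"every restart produced an empty cluster at k={k}")
    sil, km = best
    solution = ClusterSolution(
        k=k,
        labels=km.labels_.copy(),
        index_votes={},
        silhouette=float(sil),
        restart_seeds=restart_seeds,
        stability_agreement=float("nan"),
    )
    solution.cluster_centers_ = km.cluster_centers_  # type: ignore[attr-defined]
    return solution


def _pam_medoids(dist: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-medoids on a precomputed distance matrix: greedy build then
    Voronoi iteration until the medoid set is stable."""
    n = len(dist)
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.array(
            [
                np.maximum(current - dist[:, j], 0.0).sum()
                if j not in medoids
                else -np.inf
                for j in range(n)
            ]
        )
        medoids.append(int(np.argmax(gains)))
    medoids = np.array(sorted(medoids))
    for _ in range(100):
        labels = np.argmin(dist[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if len(members) == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new[c] = members[np.argmin(within)]
        new = np.array(sorted(new))
        if np.array_equal(new, medoids):
            break
        medoids = new
    return medoids


def clara_consistency(
    table,
    k: int,
    kmeans_labels: np.ndarray,
    n_subsets: int = 50,
    subset_size: int | None = None,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """CLARA stability check on the k-means partition.

    k-medoids is fitted on ``n_subsets`` random subsets (Euclidean
    distance); the subset whose medoids give the lowest total dissimilarity
    over the whole sample is kept and every subject is assigned to its
    nearest medoid.  Returns the fraction of subjects assigned to the same
    cluster as k-means after Hungarian label matching, plus the CLARA
    labels themselves.
    """
    if k < 2:
        raise ValueError("consistency check undefined for k < 2")
    x, _ = _as_array(table)
    n = len(x)
    if subset_size is None:
        subset_size = min(40 + 2 * k, n)
    if subset_size < k:
        raise ValueError(f"subset size {subset_size} < k={k}")
    rng = np.random.default_rng(seed)
    best_cost, best_medoid_points = np.inf, None
    for _ in range(n_subsets):
        idx = rng.choice(n, size=subset_size, replace=False)
        sub = x[idx]
        dist = cdist(sub, sub)
        medoids = _pam_medoids(dist, k, rng)
        medoid_points = sub[medoids]
        cost = cdist(x, medoid_points).min(axis=1).sum()
        if cost < best_cost:
            best_cost, best_medoid_points = cost, medoid_points
    clara_labels = np.argmin(cdist(x, best_medoid_points), axis=1)
    matched, agreement = match_labels(np.asarray(kmeans_labels), clara_labels)
    return agreement, matched


class BiotypeClustering(ClusterMixin, BaseEstimator):
    """Two-stage biotype clustering with consensus k selection.

    Parameters
    ----------
    k : int or None
        Fixed cluster count; when None it is chosen by the validity-index
        majority rule over ``k_range``.
    k_range : (int, int)
        Candidate cluster counts for the consensus vote.
    n_init : int
        Random-centroid k-means restarts; best silhouette wins.
    n_subsets : int
        Random subsets for the CLARA stability check.
    subset_size : int or None
        CLARA subset size; default ``min(40 + 2k, n)``.
    indices : tuple of str
        Validity-index ensemble for the consensus vote.
    random_state : int
        Seed for every stochastic stage.

    Attributes
    ----------
    k_, labels_, index_votes_, silhouette_, restart_seeds_,
    stability_agreement_, clara_labels_, cluster_centers_, scaler_
    """

    def __init__(
        self,
        k: int | None = None,
        k_range: tuple[int, int] = (2, 8),
        n_init: int = 50,
        n_subsets: int = 50,
        subset_size: int | None = None,
        indices: tuple[str, ...] = DEFAULT_INDICES,
        random_state: int = 0,
    ):
        self.k = k
        self.k_range = k_range
        self.n_init = n_init
        self.n_subsets = n_subsets
        self.subset_size = subset_size
        self.indices = indices
        self.random_state = random_state

    def fit(self, X, y=None) -> "BiotypeClustering":
        z, params = zscore(X)
        self.scaler_ = params
        self.feature_names_in_ = np.asarray(params.columns)
        if self.k is None:
            self.k_, self.index_votes_ = select_k(
                z, k_range=self.k_range, indices=self.indices,
                seed=self.random_state,
            )
        else:
            self.k_, self.index_votes_ = int(self.k), {}
        solution = kmeans_best_silhouette(
            z, self.k_, n_init=self.n_init, seed=self.random_state
        )
        self.labels_ = solution.labels
        self.silhouette_ = solution.silhouette
        self.restart_seeds_ = solution.restart_seeds
        self.cluster_centers_ = solution.cluster_centers_  # type: ignore[attr-defined]
        self.stability_agreement_, self.clara_labels_ = clara_consistency(
            z,
            self.k_,
            self.labels_,
            n_subsets=self.n_subsets,
            subset_size=self.subset_size,
            seed=self.random_state,
        )
        return self

    def predict(self, X) -> np.ndarray:
        z = self.scaler_.transform(X)
        return np.argmin(cdist(z, self.cluster_centers_), axis=1)

    def solution(self) -> ClusterSolution:
        return ClusterSolution(
            k=self.k_,
            labels=self.labels_.copy(),
            index_votes=dict(self.index_votes_),
            silhouette=self.silhouette_,
            restart_seeds=list(self.restart_seeds_),
            stability_agreement=self.stability_agreement_,
            zscore_params=self.scaler_,
        )


class BiotypeDiscriminant(ClassifierMixin, BaseEstimator):
    """Linear discriminant function characterising two biotypes.

    Homoscedastic (pooled-covariance) linear discriminant over the six
    network features.  Coefficients are exposed raw
    (``coefficients_``) and rescaled so the modulation-PL coefficient
    equals 1 (``coefficients_scaled_``) — the conventional presentation
    for this feature set.  ``shrinkage`` enables ridge-style covariance
    regularisation for near-singular inputs.
    """

    def __init__(self, shrinkage: float | None = None):
        self.shrinkage = shrinkage

    def fit(self, X, y) -> "BiotypeDiscriminant":
        x, cols = _as_array(X)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("discriminant needs exactly two classes")
        if counts.min() < 2:
            raise ValueError("each class needs >= 2 members")
        self.feature_names_in_ = np.asarray(cols)
        pooled = sum(
            np.cov(x[y == c], rowvar=False) * (np.sum(y == c) - 1)
            for c in classes
        ) / (len(x) - 2)
        if self.shrinkage is None:
            cond = np.linalg.cond(pooled)
            if not np.isfinite(cond) or cond > 1e12:
                raise ValueError(
                    "pooled within-class covariance is (near-)singular; "
                    "set shrinkage (e.g. shrinkage=0.1) to regularise"
                )
            lda = LinearDiscriminantAnalysis(solver="lsqr")
        else:
            lda = LinearDiscriminantAnalysis(
                solver="lsqr", shrinkage=self.shrinkage
            )
        self.lda_ = lda.fit(x, y)
        self.classes_ = self.lda_.classes_
        self.coefficients_ = pd.Series(self.lda_.coef_[0], index=cols)
        anchor = (
            _SCALE_ANCHOR
            if _SCALE_ANCHOR in cols
            else cols[min(3, len(cols) - 1)]
        )
        anchor_coef = self.coefficients_[anchor]
        self.coefficients_scaled_ = (
            self.coefficients_ / anchor_coef
            if anchor_coef != 0
            else self.coefficients_ * np.nan
        )
        self.class_means_ = pd.DataFrame(
            self.lda_.means_, index=self.classes_, columns=cols
        )
        self.scores_ = self.lda_.decision_function(x)
        return self

    def decision_function(self, X) -> np.ndarray:
        x, _ = _as_array(X)
        return self.lda_.decision_function(x)

    def predict(self, X) -> np.ndarray:
        x, _ = _as_array(X)
        return self.lda_.predict(x)


def fit_discriminant(table, labels, shrinkage: float | None = None):
    """Fit the two-class linear discriminant; returns the estimator."""
    return BiotypeDiscriminant(shrinkage=shrinkage).fit(table, labels)


def jackknife_accuracy(
    table, labels, shrinkage: float | None = None
) -> float:
    """Leave-one-out reclassification accuracy of the discriminant.

    Each subject is classified by a discriminant fitted without it;
    accuracy is the fraction matching the supplied (clustering) labels.
    Folds in which a class would vanish are skipped with a warning.
    """
    x, _ = _as_array(table)
    y = np.asarray(labels)
    hits, evaluated = 0, 0
    for i in range(len(x)):
        mask = np.ones(len(x), dtype=bool)
        mask[i] = False
        rest_classes, rest_counts = np.unique(y[mask], return_counts=True)
        if len(rest_classes) < 2 or rest_counts.min() < 2:
            warnings.warn(
                f"jackknife fold {i}: a class vanished; fold skipped",
                stacklevel=2,
            )
            continue
        model = BiotypeDiscriminant(shrinkage=shrinkage).fit(x[mask], y[mask])
        hits += int(model.predict(x[i : i + 1])[0] == y[i])
        evaluated += 1
    if evaluated == 0:
        raise ValueError("no evaluable jackknife folds")
    return hits / evaluated


def project(
    model: BiotypeDiscriminant,
    new_table,
    zscore_params: ZScoreParams,
    reference_labels: np.ndarray | None = None,
) -> dict:
    """Apply a fitted discriminant to new subjects.

    New samples are standardised with the training z-score parameters and
    pushed through the discriminant; returns scores and hard labels, plus
    agreement with ``reference_labels`` (e.g. the new table's own
    clustering) after optimal label matching when those are given.
    """
    z = zscore_params.transform(new_table)
    scores = model.decision_function(z)
    labels = model.predict(z)
    out = {"scores": scores, "labels": labels}
    if reference_labels is not None:
        _, agreement = match_labels(labels, np.asarray(reference_labels))
        out["agreement"] = agreement
    return out


def rerun_excluding(
    table,
    exclude_mask: np.ndarray,
    base_labels: np.ndarray | None = None,
    **clustering_params,
) -> tuple[ClusterSolution, pd.DataFrame | None]:
    """Repeat the full clustering on the subjects not excluded.

    Returns the new solution and, when ``base_labels`` are supplied, the
    cross-tabulation of old vs new labels over the retained subjects.
    """
    exclude_mask = np.asarray(exclude_mask, dtype=bool)
    x, cols = _as_array(table)
    if len(exclude_mask) != len(x):
        raise ValueError("mask length must match the table")
    keep = ~exclude_mask
    retained = pd.DataFrame(x[keep], columns=cols)
    model = BiotypeClustering(**clustering_params)
    k_for_check = model.k or model.k_range[0]
    if keep.sum() < 2 * k_for_check:
        raise ValueError(
            f"only {keep.sum()} subjects retained; need >= {2 * k_for_check}"
        )
    model.fit(retained)
    crosstab = None
    if base_labels is not None:
        base = np.asarray(base_labels)[keep]
        crosstab = pd.crosstab(
            pd.Series(base, name="original"),
            pd.Series(model.labels_, name="rerun"),
        )
    return model.solution(), crosstab
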