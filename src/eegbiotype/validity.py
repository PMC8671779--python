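"""Cluster-validity index ensemble for consensus selection of k.

Each index inspects k-means partitions over a range of cluster counts and
votes for its preferred k; the consensus (majority) vote with a lowest-k
tie-break is taken by :func:`eegbiotype.biotype.select_k`.  The ensemble
covers the classic families: silhouette-style separation (silhouette,
Dunn, Davies-Bouldin, Xie-Beni), variance ratios (Calinski-Harabasz, PBM,
Ratkowsky-Lance), within-dispersion elbows (Ball-Hall, Hartigan,
Krzanowski-Lai, gap statistic) and pairwise-distance consistency
(C-index, McClain-Rao).  Vote rules follow each index's published
optimum (max, min, largest drop, or the gap criterion).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

DEFAULT_INDICES = (
    "silhouette",
    "calinski_harabasz",
    "davies_bouldin",
    "dunn",
    "c_index",
    "mcclain_rao",
    "pbm",
    "ratkowsky_lance",
    "ball_hall",
    "hartigan",
    "krzanowski_lai",
    "gap",
    "xie_beni",
)


def _kmeans_labels(X: np.ndarray, k: int, seed: int, n_init: int = 10):
    if k == 1:
        labels = np.zeros(len(X), dtype=int)
        centers = X.mean(axis=0, keepdims=True)
        return labels, centers
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    return km.labels_, km.cluster_centers_


def _wss(X: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    return float(((X - centers[labels]) ** 2).sum())


class _Partitions:
    """k-means partitions and shared geometry for all indices."""

    def __init__(self, X: np.ndarray, k_values: list[int], seed: int,
                 n_init: int = 10):
        self.X = X
        self.n, self.p = X.shape
        self.labels: dict[int, np.ndarray] = {}
        self.centers: dict[int, np.ndarray] = {}
        self.wss: dict[int, float] = {}
        for k in k_values:
            lab, cen = _kmeans_labels(X, k, seed, n_init)
            self.labels[k], self.centers[k] = lab, cen
            self.wss[k] = _wss(X, lab, cen)
        self.dist = squareform(pdist(X))


def _dunn(parts: _Partitions, k: int) -> float:
    lab = parts.labels[k]
    d = parts.dist
    inter = np.inf
    diam = 0.0
    for a in range(k):
        ia = lab == a
        if ia.sum() > 1:
            diam = max(diam, d[np.ix_(ia, ia)].max())
        for b in range(a + 1, k):
            ib = lab == b
            inter = min(inter, d[np.ix_(ia, ib)].min())
    return inter / diam if diam > 0 else np.inf


def _within_between(parts: _Partitions, k: int):
    lab = parts.labels[k]
    same = lab[:, None] == lab[None, :]
    iu = np.triu_indices(parts.n, k=1)
    within = parts.dist[iu][same[iu]]
    between = parts.dist[iu][~same[iu]]
    return within, between


def _c_index(parts: _Partitions, k: int) -> float:
    within, _ = _within_between(parts, k)
    nw = len(within)
    if nw == 0:
        return np.inf
    iu = np.triu_indices(parts.n, k=1)
    all_d = np.sort(parts.dist[iu])
    s = within.sum()
    s_min = all_d[:nw].sum()
    s_max = all_d[-nw:].sum()
    return (s - s_min) / (s_max - s_min) if s_max > s_min else 0.0


def _mcclain_rao(parts: _Partitions, k: int) -> float:
    within, between = _within_between(parts, k)
    if len(within) == 0 or len(between) == 0 or between.mean() == 0:
        return np.inf
    return within.mean() / between.mean()


def _pbm(parts: _Partitions, k: int) -> float:
    X = parts.X
    global_c = X.mean(axis=0)
    e1 = np.linalg.norm(X - global_c, axis=1).sum()
    lab, cen = parts.labels[k], parts.centers[k]
    ek = np.linalg.norm(X - cen[lab], axis=1).sum()
    if ek == 0:
        return np.inf
    dk = pdist(cen).max() if k > 1 else 0.0
    return ((e1 / ek) * dk / k) ** 2


def _ratkowsky_lance(parts: _Partitions, k: int) -> float:
    X = parts.X
    lab = parts.labels[k]
    grand = X.mean(axis=0)
    tss = ((X - grand) ** 2).sum(axis=0)
    bgss = np.zeros(parts.p)
    for g in range(k):
        ig = lab == g
        bgss += ig.sum() * (X[ig].mean(axis=0) - grand) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(tss > 0, bgss / tss, 0.0)
    return float(np.mean(np.sqrt(ratio)) / np.sqrt(k))


def _xie_beni(parts: _Partitions, k: int) -> float:
    if k < 2:
        return np.inf
    sep = (pdist(parts.centers[k]) ** 2).min()
    if sep == 0:
        return np.inf
    return parts.wss[k] / (parts.n * sep)


def _gap_votes(parts: _Partitions, k_range: list[int], seed: int,
               n_refs: int = 10) -> int:
    X = parts.X
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    ks = k_range + [k_range[-1] + 1]
    log_w = {k: np.log(max(parts.wss[k], 1e-300)) for k in ks}
    log_wb = {k: [] for k in ks}
    for _ in range(n_refs):
        ref = rng.uniform(lo, hi, size=X.shape)
        for k in ks:
            lab, cen = _kmeans_labels(ref, k, seed, n_init=2)
            log_wb[k].append(np.log(max(_wss(ref, lab, cen), 1e-300)))
    gap = {k: float(np.mean(log_wb[k]) - log_w[k]) for k in ks}
    s = {
        k: float(np.std(log_wb[k], ddof=0) * np.sqrt(1.0 + 1.0 / n_refs))
        for k in ks
    }
    for k in k_range:
        if gap[k] >= gap[k + 1] - s[k + 1]:
            return k
    return max(k_range, key=lambda k: gap[k])


def index_votes(
    X: np.ndarray,
    k_range: tuple[int, int] = (2, 8),
    seed: int = 0,
    indices: tuple[str, ...] = DEFAULT_INDICES,
    n_init: int = 10,
) -> dict[str, int]:
    """Preferred k per validity index on k-means partitions of ``X``."""
    X = np.asarray(X, dtype=float)
    k_min, k_max = k_range
    if k_min < 2:
        raise ValueError("k_range must start at >= 2")
    ks = list(range(k_min, k_max + 1))
    if len(X) < k_max + 1:
        raise ValueError(
            f"need more subjects ({len(X)}) than max(k_range)={k_max}"
        )
    parts = _Partitions(X, list(range(1, k_max + 2)), seed, n_init)

    votes: dict[str, int] = {}

    def argbest(fn, best):
        vals = {k: fn(k) for k in ks}
        return best(ks, key=lambda k: vals[k])

    for name in indices:
        if name == "silhouette":
            votes[name] = argbest(
                lambda k: silhouette_score(X, parts.labels[k]), max
            )
        elif name == "calinski_harabasz":
            votes[name] = argbest(
                lambda k: calinski_harabasz_score(X, parts.labels[k]), max
            )
        elif name == "davies_bouldin":
            votes[name] = argbest(
                lambda k: davies_bouldin_score(X, parts.labels[k]), min
            )
        elif name == "dunn":
            votes[name] = argbest(lambda k: _dunn(parts, k), max)
        elif name == "c_index":
            votes[name] = argbest(lambda k: _c_index(parts, k), min)
        elif name == "mcclain_rao":
            votes[name] = argbest(lambda k: _mcclain_rao(parts, k), min)
        elif name == "pbm":
            votes[name] = argbest(lambda k: _pbm(parts, k), max)
        elif name == "ratkowsky_lance":
            votes[name] = argbest(lambda k: _ratkowsky_lance(parts, k), max)
        elif name == "xie_beni":
            votes[name] = argbest(lambda k: _xie_beni(parts, k), min)
        elif name == "ball_hall":
            # Largest drop of the mean within-cluster dispersion W_k / k.
            bh = {k: parts.wss[k] / k for k in range(1, parts_max(ks) + 1)}
            votes[name] = max(ks, key=lambda k: bh[k - 1] - bh[k])
        elif name == "hartigan":
            n = parts.n
            h = {
                k: (parts.wss[k] / parts.wss[k + 1] - 1.0) * (n - k - 1)
                if parts.wss[k + 1] > 0
                else 0.0
                for k in range(1, parts_max(ks) + 1)
            }
            small = [k for k in ks if h[k] <= 10.0]
            votes[name] = (
                small[0] if small else max(ks, key=lambda k: h[k - 1] - h[k])
            )
        elif name == "krzanowski_lai":
            p = parts.p
            diff = {
                k: (k - 1) ** (2.0 / p) * parts.wss[k - 1]
                - k ** (2.0 / p) * parts.wss[k]
                for k in range(2, parts_max(ks) + 2)
            }
            kl = {
                k: abs(diff[k]) / abs(diff[k + 1]) if diff[k + 1] != 0 else np.inf
                for k in ks
            }
            votes[name] = max(ks, key=lambda k: kl[k])
        elif name == "gap":
            votes[name] = _gap_votes(parts, ks, seed)
        else:
            raise ValueError(f"unknown validity index {name!r}")
    return votes


def parts_max(ks: list[int]) -> int:
    return max(ks)


def majority_k(votes: dict[str, int]) -> int:
    """Modal voted k; ties broken toward the smallest k."""
    if not votes:
        raise ValueError("no index votes")
    counts: dict[int, int] = {}
    for k in votes.values():
        counts[k] = counts.get(k, 0) + 1
    best = max(counts.values())
    return min(k for k, c in counts.items() if c == best)
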