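"""Weighted-graph summary metrics for dense connectivity matrices.

Four global parameters characterise each network: connectivity strength
(CS, the mean off-diagonal weight), the averaged weighted clustering
coefficient (CLC, geometric-mean-of-triangles formulation on max-scaled
weights), the characteristic path length (PL, mean shortest-path length
with inverse-weight edge distances), and the small-world index
(SW = CLC / PL).  CLC and PL can be normalised by the mean of a surrogate
ensemble that permutes the weight multiset while preserving symmetry —
values then sit near 1 and measure structure beyond the weight
distribution itself.  The response-minus-prestimulus difference of each
metric is its task modulation ("chronnectomics"); negative modulation
means the metric decreases during the response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path

FEATURE_COLUMNS = (
    "pl_prestim",
    "cs_prestim",
    "sw_prestim",
    "pl_modulation",
    "cs_modulation",
    "sw_modulation",
)


def _check_square_symmetric(matrix: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T, atol=atol):
        raise ValueError("matrix must be symmetric")
    return m


@dataclass
class SurrogateEnsemble:
    """Weight-permutation surrogate scheme for metric normalisation.

    Each surrogate redistributes the original off-diagonal weight multiset
    uniformly at random over the edges (upper triangle permuted, then
    mirrored), preserving symmetry and the weight distribution while
    destroying topology.
    """

    n_surrogates: int = 50
    seed: int = 0
    method: str = "weight_permutation"

    def draws(self, matrix: np.ndarray):
        m = _check_square_symmetric(matrix)
        rng = np.random.default_rng(self.seed)
        iu = np.triu_indices(m.shape[0], k=1)
        weights = m[iu]
        for _ in range(self.n_surrogates):
            s = np.zeros_like(m)
            s[iu] = rng.permutation(weights)
            s = s + s.T
            np.fill_diagonal(s, np.diag(m))
            yield s

    def mean_metric(self, matrix: np.ndarray, metric) -> float:
        return float(np.mean([metric(s) for s in self.draws(matrix)]))


def connectivity_strength(matrix: np.ndarray) -> float:
    """Mean off-diagonal weight (average pairwise coupling)."""
    m = _check_square_symmetric(matrix)
    if np.any(m < 0):
        raise ValueError("weights must be >= 0")
    n = m.shape[0]
    off = ~np.eye(n, dtype=bool)
    return float(m[off].mean())


def _clc_unnormalized(matrix: np.ndarray) -> float:
    m = matrix.copy()
    np.fill_diagonal(m, 0.0)
    w_max = m.max()
    if w_max <= 0:
        return 0.0
    w = np.cbrt(m / w_max)
    triangles = np.diagonal(w @ w @ w)  # 2 * sum of triangle intensities
    degree = np.count_nonzero(m > 0, axis=1)
    denom = degree * (degree - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        node_clc = np.where(denom > 0, triangles / denom, 0.0)
    return float(node_clc.mean())


def clustering_coefficient(
    matrix: np.ndarray,
    normalize: bool = False,
    ensemble: SurrogateEnsemble | None = None,
) -> float:
    """Averaged weighted clustering coefficient.

    Weights are scaled by the matrix maximum, node clustering is the
    geometric mean of triangle weights around each node divided by the
    number of possible triangles, and nodes are averaged.  With
    ``normalize`` the value is divided by the surrogate-ensemble mean.
    """
    m = _check_square_symmetric(matrix)
    if m.shape[0] < 3:
        raise ValueError("clustering coefficient needs >= 3 nodes")
    if np.any(m < 0):
        raise ValueError("weights must be >= 0")
    value = _clc_unnormalized(m)
    if normalize:
        ensemble = ensemble or SurrogateEnsemble()
        ref = ensemble.mean_metric(m, _clc_unnormalized)
        value = value / ref
    return value


def _pl_unnormalized(matrix: np.ndarray) -> float:
    m = matrix.copy()
    np.fill_diagonal(m, 0.0)
    n = m.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        dist = np.where(m > 0, 1.0 / np.where(m > 0, m, 1.0), np.inf)
    np.fill_diagonal(dist, 0.0)
    sp = shortest_path(dist, method="D", directed=False)
    if np.any(np.isinf(sp[off])):
        raise ValueError("graph is disconnected; path length undefined")
    return float(sp[off].mean())


def path_length(
    matrix: np.ndarray,
    normalize: bool = False,
    ensemble: SurrogateEnsemble | None = None,
) -> float:
    """Characteristic path length with edge distances 1/weight.

    All-pairs shortest-path lengths averaged over ordered node pairs;
    optionally normalised by the surrogate-ensemble mean.
    """
    m = _check_square_symmetric(matrix)
    if np.any(m < 0):
        raise ValueError("weights must be >= 0")
    value = _pl_unnormalized(m)
    if normalize:
        ensemble = ensemble or SurrogateEnsemble()
        ref = ensemble.mean_metric(m, _pl_unnormalized)
        value = value / ref
    return value


def small_world(clc: float, pl: float) -> float:
    """Small-world index: CLC divided by PL."""
    if pl == 0:
        raise ValueError("path length must be nonzero")
    return clc / pl


@dataclass
class GraphMetrics:
    """CS / CLC / PL / SW of one matrix (one band, one window)."""

    cs: float
    clc: float
    pl: float
    sw: float
    band: str = ""
    window: str = ""
    subject_id: str = ""

    @classmethod
    def from_matrix(
        cls,
        matrix: np.ndarray,
        band: str = "",
        window: str = "",
        subject_id: str = "",
        normalize: bool = True,
        ensemble: SurrogateEnsemble | None = None,
    ) -> "GraphMetrics":
        ensemble = ensemble or SurrogateEnsemble()
        clc = clustering_coefficient(matrix, normalize=normalize, ensemble=ensemble)
        pl = path_length(matrix, normalize=normalize, ensemble=ensemble)
        return cls(
            cs=connectivity_strength(matrix),
            clc=clc,
            pl=pl,
            sw=small_world(clc, pl),
            band=band,
            window=window,
            subject_id=subject_id,
        )


def modulation(response: GraphMetrics, prestimulus: GraphMetrics) -> GraphMetrics:
    """Response minus prestimulus for each metric.

    Negative values mean the metric decreased during the response window.
    """
    if response.band != prestimulus.band:
        raise ValueError(
            f"band mismatch: {response.band!r} vs {prestimulus.band!r}"
        )
    return GraphMetrics(
        cs=response.cs - prestimulus.cs,
        clc=response.clc - prestimulus.clc,
        pl=response.pl - prestimulus.pl,
        sw=response.sw - prestimulus.sw,
        band=response.band,
        window="modulation",
        subject_id=response.subject_id,
    )


@dataclass
class NetworkFeatures:
    """Per-subject window metrics plus modulation; yields the 6-variable
    clustering feature vector (PL, CS and SW, prestimulus and modulation —
    CLC is computed and reported but excluded from the feature set)."""

    prestimulus: GraphMetrics
    response: GraphMetrics
    modulation: GraphMetrics = field(init=False)
    band: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.modulation = modulation(self.response, self.prestimulus)

    @classmethod
    def from_matrices(
        cls,
        prestim_matrix: np.ndarray,
        response_matrix: np.ndarray,
        band: str = "",
        subject_id: str = "",
        normalize: bool = True,
        ensemble: SurrogateEnsemble | None = None,
    ) -> "NetworkFeatures":
        pre = GraphMetrics.from_matrix(
            prestim_matrix, band, "prestimulus", subject_id, normalize, ensemble
        )
        resp = GraphMetrics.from_matrix(
            response_matrix, band, "response", subject_id, normalize, ensemble
        )
        return cls(prestimulus=pre, response=resp, band=band, subject_id=subject_id)

    def feature_row(self) -> dict[str, float]:
        return {
            "pl_prestim": self.prestimulus.pl,
            "cs_prestim": self.prestimulus.cs,
            "sw_prestim": self.prestimulus.sw,
            "pl_modulation": self.modulation.pl,
            "cs_modulation": self.modulation.cs,
            "sw_modulation": self.modulation.sw,
        }


def structural_metrics(
    matrix: np.ndarray,
    subject_id: str = "",
    normalize: bool = True,
    ensemble: SurrogateEnsemble | None = None,
) -> GraphMetrics:
    """Apply the CS/CLC/PL/SW engine to a structural (e.g. FA-weighted)
    matrix; single window, no modulation.  Zero diagonal is allowed."""
    m = _check_square_symmetric(matrix)
    if np.any(m < 0):
        raise ValueError("structural weights must be >= 0")
    return GraphMetrics.from_matrix(
        m, band="structural", window="", subject_id=subject_id,
        normalize=normalize, ensemble=ensemble,
    )
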