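"""Quantitative analysis of latent representations: multimodality via
kNN-rate-guided dimensionality reduction plus full-covariance X-means, and
local smoothness via directional-derivative norms and Tanimoto neighbor
profiles.

The multimodality scheme is two-step: (1) project the latent means to a
low-dimensional space with UMAP, choosing the target dimension by the knee
of the k-nearest-neighbor preservation curve; (2) count clusters with an
X-means variant whose BIC uses full-covariance Gaussian components, and
exclude clusters smaller than the kNN neighborhood size k = ceil(0.005 N).
The cluster count is the multimodality proxy; more clusters mean a more
multimodal latent distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import multivariate_normal

__all__ = [
    "knn_rate", "kneedle", "select_embedding_dim", "xmeans_count",
    "ClusteringResult", "MultimodalityConfig", "multimodality_pipeline",
    "SmoothnessReport", "directional_smoothness", "tanimoto_smoothness",
    "ecfp4_fingerprints", "tanimoto",
]


def default_k(n: int) -> int:
    """Neighborhood size: 0.5% of the sample size, at least 1."""
    return max(1, int(np.ceil(0.005 * n)))


def _knn_sets(Z: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest Euclidean neighbors of each row, self
    excluded; distance ties broken by index for determinism."""
    n = len(Z)
    if k >= n:
        raise ValueError(f"k={k} must be < N={n}")
    D = cdist(Z, Z)
    np.fill_diagonal(D, np.inf)
    idx = np.arange(n)
    out = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        order = np.lexsort((idx, D[i]))
        out[i] = order[:k]
    return out


def knn_rate(Z_high: np.ndarray, Z_low: np.ndarray, k: int) -> float:
    """Average fractional overlap of k-nearest-neighbor sets between the
    high- and low-dimensional embeddings (row correspondence assumed)."""
    if len(Z_high) != len(Z_low):
        raise ValueError("embeddings must have the same number of rows")
    hi = _knn_sets(np.atleast_2d(Z_high), k)
    lo = _knn_sets(np.atleast_2d(Z_low), k)
    overlap = [len(np.intersect1d(hi[i], lo[i], assume_unique=True))
               for i in range(len(hi))]
    return float(np.sum(overlap)) / (len(hi) * k)


def kneedle(x: np.ndarray, y: np.ndarray) -> int | None:
    """Knee of a concave increasing curve: the point of maximum vertical
    distance above the chord after normalizing both axes to [0, 1].
    Returns the index of the knee, or None when no point rises above the
    chord (flat or convex curve)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 3:
        return None
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    xn = (x - x.min()) / np.ptp(x)
    yn = (y - y.min()) / np.ptp(y)
    diff = yn - xn
    best = int(np.argmax(diff))
    return best if diff[best] > 0 else None


def _umap_project(Z: np.ndarray, n_components: int, n_neighbors: int,
                  min_dist: float, seed: int) -> np.ndarray:
    import warnings

    from umap import UMAP

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = UMAP(n_components=n_components,
                       n_neighbors=min(n_neighbors, len(Z) - 1),
                       min_dist=min_dist, random_state=seed, verbose=False)
        return np.asarray(reducer.fit_transform(Z), dtype=np.float64)


def select_embedding_dim(Z_high: np.ndarray, l_range, k: int | None = None,
                         seed: int = 0, n_neighbors: int = 250,
                         min_dist: float = 0.1):
    """Pick the UMAP target dimension by the knee of the kNN-rate curve.

    Returns ``(curve, l_hat)`` where curve is an array of (l, rate) rows
    (empty when l_range has a single candidate).  If the curve has no
    knee, falls back to the smallest l within 95% of the maximum rate and
    records that in the curve's companion attribute.
    """
    l_range = sorted(set(int(l) for l in l_range))
    d = Z_high.shape[1]
    if any(l < 1 or l > d for l in l_range):
        raise ValueError("l_range must lie within [1, d]")
    if len(l_range) == 1:
        return np.empty((0, 2)), l_range[0]
    if k is None:
        k = default_k(len(Z_high))
    rates = []
    for l in l_range:
        Z_low = _umap_project(Z_high, l, n_neighbors, min_dist, seed)
        rates.append(knn_rate(Z_high, Z_low, k))
    curve = np.column_stack([l_range, rates])
    knee = kneedle(curve[:, 0], curve[:, 1])
    if knee is not None:
        return curve, int(curve[knee, 0])
    # fallback: smallest l reaching 95% of the best preservation
    good = curve[:, 1] >= 0.95 * curve[:, 1].max()
    return curve, int(curve[np.argmax(good), 0])


@dataclass
class ClusteringResult:
    """X-means output over a low-dimensional embedding."""

    n_clusters: int
    assignments: np.ndarray              # -1 for points in dissolved clusters
    means: list[np.ndarray]
    covariances: list[np.ndarray]
    excluded_small: int
    ridge_applied: bool = False


def _gauss_loglik(X: np.ndarray, ridge: float = 1e-6) -> tuple[float, bool]:
    """Log-likelihood of points under a single Gaussian with the sample
    mean and unbiased covariance; adds a diagonal ridge when singular."""
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    ridged = False
    try:
        ll = multivariate_normal.logpdf(X, mean, cov).sum()
    except (np.linalg.LinAlgError, ValueError):
        cov = cov + ridge * np.eye(cov.shape[0])
        ll = multivariate_normal.logpdf(X, mean, cov).sum()
        ridged = True
    return float(ll), ridged


def _n_free_params(l: int) -> int:
    # mean + symmetric covariance per component
    return l + l * (l + 1) // 2


def xmeans_count(Z_low: np.ndarray, min_size: int | None = None,
                 k_max: int = 50, seed: int = 0,
                 ridge: float = 1e-6) -> ClusteringResult:
    """Estimate the number of modes by recursive 2-means splitting.

    A split of a cluster is accepted when the two-component BIC (full-
    covariance Gaussian log-likelihood plus hard-assignment mixing weights,
    penalized by half the free-parameter count times log n) exceeds the
    single-Gaussian BIC of the parent.  Clusters smaller than ``min_size``
    (default ceil(0.005 N)) are dissolved after splitting terminates.
    """
    from sklearn.cluster import KMeans

    Z = np.atleast_2d(np.asarray(Z_low, dtype=np.float64))
    n, l = Z.shape
    if min_size is None:
        min_size = default_k(n)
    if n <= 2 * min_size:
        raise ValueError("need N > 2 * min_size")
    p1 = _n_free_params(l)
    p2 = 2 * p1 + 1
    ridged_any = False
    final: list[np.ndarray] = []
    stack: list[np.ndarray] = [np.arange(n)]
    rng_counter = 0
    while stack:
        idx = stack.pop()
        X = Z[idx]
        m = len(idx)
        # too small to estimate two full-covariance children
        if len(final) + len(stack) + 1 >= k_max or m < 2 * (l + 2):
            final.append(idx)
            continue
        ll1, r1 = _gauss_loglik(X, ridge)
        bic_parent = ll1 - 0.5 * p1 * np.log(m)
        km = KMeans(n_clusters=2, n_init=4, random_state=seed + rng_counter)
        rng_counter += 1
        labels = km.fit_predict(X)
        sizes = np.bincount(labels, minlength=2)
        if sizes.min() < l + 2:
            final.append(idx)
            continue
        ll2 = 0.0
        r2 = False
        for c in (0, 1):
            llc, rc = _gauss_loglik(X[labels == c], ridge)
            ll2 += llc + sizes[c] * np.log(sizes[c] / m)
            r2 = r2 or rc
        bic_children = ll2 - 0.5 * p2 * np.log(m)
        if bic_children > bic_parent:
            ridged_any = ridged_any or r1 or r2
            stack.append(idx[labels == 0])
            stack.append(idx[labels == 1])
        else:
            final.append(idx)
    retained = [idx for idx in final if len(idx) >= min_size]
    excluded = len(final) - len(retained)
    assignments = np.full(n, -1, dtype=np.int64)
    means, covs = [], []
    for c, idx in enumerate(retained):
        assignments[idx] = c
        means.append(Z[idx].mean(axis=0))
        covs.append(np.atleast_2d(np.cov(Z[idx], rowvar=False, ddof=1)))
    return ClusteringResult(len(retained), assignments, means, covs,
                            excluded, ridged_any)


@dataclass(frozen=True)
class MultimodalityConfig:
    l_range: tuple[int, ...] = (1, 2, 3, 4, 5)
    k: int | None = None
    n_neighbors: int = 250
    min_dist: float = 0.1
    k_max: int = 50
    seed: int = 0


def multimodality_pipeline(Z_high: np.ndarray,
                           config: MultimodalityConfig = MultimodalityConfig(),
                           ) -> dict:
    """Step 1 (dimension selection + UMAP) then Step 2 (X-means count)."""
    k = config.k if config.k is not None else default_k(len(Z_high))
    curve, l_hat = select_embedding_dim(
        Z_high, config.l_range, k=k, seed=config.seed,
        n_neighbors=config.n_neighbors, min_dist=config.min_dist)
    Z_low = _umap_project(Z_high, l_hat, config.n_neighbors,
                          config.min_dist, config.seed)
    result = xmeans_count(Z_low, min_size=k, k_max=config.k_max,
                          seed=config.seed)
    return {
        "l_hat": l_hat,
        "n_clusters": result.n_clusters,
        "knn_curve": curve,
        "excluded_small": result.excluded_small,
        "clustering": result,
        "embedding": Z_low,
    }


# ----------------------------------------------------------------- smoothness

@dataclass
class SmoothnessReport:
    per_anchor: np.ndarray
    grand_mean: float
    eps: float
    M: int
    anchors: np.ndarray


def directional_smoothness(Z: np.ndarray, f_values: np.ndarray,
                           anchors: np.ndarray | None = None,
                           eps: float = 1.0, M: int = 5,
                           seed: int = 0) -> SmoothnessReport:
    """Mean finite-difference directional-derivative norm of a property f
    over latent space: for each anchor a, average |f(u_i) - f(a)| / eps over
    its M nearest dataset neighbors u_i (Euclidean, self excluded)."""
    Z = np.atleast_2d(Z)
    f_values = np.asarray(f_values, dtype=np.float64)
    n = len(Z)
    if M >= n:
        raise ValueError(f"M={M} must be < N={n}")
    if anchors is None:
        rng = np.random.default_rng(seed)
        anchors = rng.choice(n, size=min(1000, n), replace=False)
    anchors = np.asarray(anchors, dtype=np.int64)
    D = cdist(Z[anchors], Z)
    D[np.arange(len(anchors)), anchors] = np.inf
    idx = np.arange(n)
    per_anchor = np.empty(len(anchors))
    for i, a in enumerate(anchors):
        order = np.lexsort((idx, D[i]))[:M]
        per_anchor[i] = np.mean(np.abs(f_values[order] - f_values[a])) / eps
    return SmoothnessReport(per_anchor, float(per_anchor.mean()),
                            eps, M, anchors)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity of two bit vectors; defined as 0 when both are
    empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def ecfp4_fingerprints(smiles_list: list[str],
                       n_bits: int = 2048) -> np.ndarray:
    """Morgan fingerprints of radius 2 (ECFP4) as a boolean matrix."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    out = np.zeros((len(smiles_list), n_bits), dtype=bool)
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        fp = gen.GetFingerprint(mol)
        out[i, list(fp.GetOnBits())] = True
    return out


def tanimoto_smoothness(Z: np.ndarray, fingerprints: np.ndarray,
                        anchors: np.ndarray | None = None,
                        n_neighbors: int = 50, seed: int = 0) -> dict:
    """Mean Tanimoto similarity to each anchor by latent neighbor rank.

    Returns a profile of length ``n_neighbors``: entry r-1 is the average
    similarity between anchors and their rank-r latent-space neighbor.
    Higher profiles indicate chemically smoother latent neighborhoods.
    """
    Z = np.atleast_2d(Z)
    fingerprints = np.asarray(fingerprints, dtype=bool)
    n = len(Z)
    if n_neighbors >= n:
        raise ValueError("n_neighbors must be < N")
    if anchors is None:
        rng = np.random.default_rng(seed)
        anchors = rng.choice(n, size=min(5000, n), replace=False)
    anchors = np.asarray(anchors, dtype=np.int64)
    D = cdist(Z[anchors], Z)
    D[np.arange(len(anchors)), anchors] = np.inf
    idx = np.arange(n)
    sims = np.empty((len(anchors), n_neighbors))
    empty_flagged = 0
    for i, a in enumerate(anchors):
        order = np.lexsort((idx, D[i]))[:n_neighbors]
        fa = fingerprints[a]
        if not fa.any():
            empty_flagged += 1
        for r, j in enumerate(order):
            sims[i, r] = tanimoto(fa, fingerprints[j])
    return {
        "profile": sims.mean(axis=0),
        "n_anchors": len(anchors),
        "empty_fingerprints": empty_flagged,
    }
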