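"""Population structure: LD pruning, PCA, DAPC, IBS distances and NJ trees.

PCA centers dosages by twice the allele frequency and (optionally) scales by
sqrt(2*p*q); DAPC runs k-means over retained PC scores for a range of k,
selects k by the adegenet-style BIC  n*log(WSS/n) + k*log(n), and fits linear
discriminant axes on the selected clustering.  Neighbor joining is delegated
to scikit-bio on a 1 - mean-IBS-share distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, natural_sort_key
from .popgen_stats import allele_stats

__all__ = [
    "PCAResult", "DAPCResult", "ld_prune", "pca", "dapc_find_clusters",
    "ibs_distance", "nj_tree",
]


@dataclass
class PCAResult:
    scores: np.ndarray                      # n_samples x n_pcs
    loadings: np.ndarray                    # n_variants x n_pcs
    explained_variance_fraction: np.ndarray
    sample_ids: list[str] = field(default_factory=list)


@dataclass
class DAPCResult:
    k_selected: int
    bic_by_k: dict[int, float]
    assignments: np.ndarray                 # int label per sample
    discriminant_scores: np.ndarray | None  # n_samples x (k-1), None for k=1
    sample_ids: list[str] = field(default_factory=list)
    n_pcs_used: int = 0


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_prune(G: GenotypeMatrix, r2_threshold: float = 0.5,
             window_bp: int = 50_000, step_bp: int | None = None
             ) -> GenotypeMatrix:
    """Greedy windowed LD pruning.

    Within each sliding window, any pair with r^2 > threshold loses its
    later-position member (the earlier variant is kept).  Windows slide by
    ``step_bp`` (default half the window).
    """
    if step_bp is None:
        step_bp = window_bp // 2
    chroms, pos = G.chromosomes, G.positions
    keep = np.ones(G.n_variants, dtype=bool)
    d = G.dosages

    for c in sorted(set(chroms), key=natural_sort_key):
        sel = np.flatnonzero(chroms == c)
        p = pos[sel]
        last = int(p.max())
        for start in range(0, last + 1, step_bp):
            in_w = sel[(p > start) & (p <= start + window_bp)]
            in_w = in_w[keep[in_w]]
            if in_w.size < 2:
                continue
            R2 = _r2_matrix(d[:, in_w])
            for a in range(in_w.size):
                if not keep[in_w[a]]:
                    continue
                for b in range(a + 1, in_w.size):
                    if keep[in_w[b]] and R2[a, b] > r2_threshold:
                        keep[in_w[b]] = False
    return G.take_variants(keep)


def _r2_matrix(d: np.ndarray) -> np.ndarray:
    """Pairwise-complete r^2 among columns of a dosage block."""
    obs = (d != MISSING).astype(float)
    x = np.where(d != MISSING, d, 0).astype(float)
    n = obs.T @ obs
    sx = x.T @ obs
    sxx = (x * x).T @ obs
    sxy = x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        vx = sxx - sx ** 2 / n
        r2 = cov * cov / (vx * vx.T)
        r2 = np.where((vx > 0) & (vx.T > 0) & (n > 1), r2, 0.0)
    return r2


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(G: GenotypeMatrix, min_maf: float = 0.05, scaling: str = "patterson",
        n_pcs: int | None = None) -> PCAResult:
    """Principal components of the dosage matrix.

    Columns are centered by 2*p-hat and, with ``scaling='patterson'``, scaled
    by sqrt(2*p*q).  Missing dosages are mean-imputed (zero after centering).
    Sign convention: within each PC the largest-|loading| element is positive.
    """
    if G.n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    st = allele_stats(G)
    with np.errstate(invalid="ignore"):
        keep = st["maf"] >= min_maf
    keep &= np.nan_to_num(st["maf"]) > 0
    G2 = G.take_variants(keep)
    p = allele_stats(G2)["alt_freq"]
    d = G2.dosages
    X = np.where(d != MISSING, d, 2 * p[None, :]).astype(float) - 2 * p[None, :]
    if scaling == "patterson":
        X /= np.sqrt(2 * p * (1 - p))[None, :]
    elif scaling not in (None, "none"):
        raise ValueError(f"unknown scaling {scaling!r}")
    if not np.any(X):
        raise ValueError("zero-variance matrix after filtering")

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total_var = float((s ** 2).sum())
    k = n_pcs or min(X.shape) - 1 or 1
    k = min(k, len(s))
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    frac = (s[:k] ** 2) / total_var
    return PCAResult(scores, loadings, frac, list(G.sample_ids))


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------

def dapc_find_clusters(G: GenotypeMatrix, k_max: int = 6,
                       n_pcs_retained: int | None = None,
                       n_starts: int = 10, seed: int = 0,
                       min_maf: float = 0.0) -> DAPCResult:
    """DAPC group discovery: k-means on PC scores with BIC model selection.

    ``n_pcs_retained`` defaults to the smallest number of PCs reaching 80%
    of the variance.  BIC(k) = n*log(WSS(k)/n) + k*log(n); the minimizing k
    wins (ties to the smallest k).  Discriminant axes are then fit on the
    selected clustering.
    """
    from sklearn.cluster import KMeans
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    n = G.n_samples
    if k_max >= n:
        raise ValueError("k_max must be < n_samples")
    pcs = pca(G, min_maf=min_maf, scaling="patterson")
    if n_pcs_retained is None:
        cum = np.cumsum(pcs.explained_variance_fraction)
        n_pcs_retained = int(np.searchsorted(cum, 0.8)) + 1
    n_pcs_retained = min(n_pcs_retained, n - 1, pcs.scores.shape[1])
    X = pcs.scores[:, :n_pcs_retained]

    rng = np.random.default_rng(seed)
    bic: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(1, k_max + 1):
        if k == 1:
            wss = float(((X - X.mean(axis=0)) ** 2).sum())
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_starts,
                        random_state=int(rng.integers(2 ** 31 - 1)))
            labels = km.fit_predict(X)
            wss = float(km.inertia_)
        bic[k] = n * np.log(wss / n) + k * np.log(n)
        labels_by_k[k] = labels

    k_sel = min(bic, key=lambda k: (round(bic[k], 12), k))
    labels = labels_by_k[k_sel]
    disc = None
    if k_sel > 1:
        lda = LinearDiscriminantAnalysis(n_components=k_sel - 1)
        disc = lda.fit_transform(X, labels)
    return DAPCResult(k_sel, bic, labels, disc, list(G.sample_ids),
                      n_pcs_retained)


# ---------------------------------------------------------------------------
# Distances and NJ
# ---------------------------------------------------------------------------

def ibs_distance(G: GenotypeMatrix) -> np.ndarray:
    """1 - mean identity-by-state share over pairwise non-missing sites.

    IBS share per site is 1 - |g_i - g_j| / 2, so identical samples are at
    distance 0 and opposite homozygotes at distance 1.
    """
    d = G.dosages
    obs = d != MISSING
    x = np.where(obs, d, 0).astype(float)
    o = obs.astype(float)
    # sum |gi-gj| over shared sites, via (gi-gj)^2 decomposition on 0/1/2:
    # |a-b| in {0,1,2}; |a-b| = (a-b)^2 - 2*[both het? no]; do it blockwise
    n = G.n_samples
    D = np.zeros((n, n))
    shared = o @ o.T
    for i in range(n):
        diff = np.abs(x[i][None, :] - x)            # n x m
        both = obs[i][None, :] & obs
        s = np.where(both, diff, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            D[i] = np.where(shared[i] > 0, s / (2.0 * shared[i]), 0.0)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def nj_tree(D: np.ndarray, ids: list[str] | None = None):
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Returns an skbio TreeNode (unrooted, trifurcating root).  Negative branch
    lengths are clamped to zero.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    D = np.asarray(D, dtype=float)
    if D.shape[0] < 3:
        raise ValueError("NJ needs at least 3 taxa")
    if not np.allclose(D, D.T, atol=1e-10) or np.abs(np.diag(D)).max() > 1e-10:
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if ids is None:
        ids = [f"t{i}" for i in range(D.shape[0])]
    return nj(DistanceMatrix(D, ids), neg_as_zero=True)
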