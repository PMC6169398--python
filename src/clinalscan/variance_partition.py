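"""RDA variance partitioning of a genotype matrix on climate and space.

Redundancy analysis here is multivariate least squares of the (centered)
genotype matrix Y on a standardized predictor block X; explained variance is
R^2 = tr(SS_fitted)/tr(SS_total) and is adjusted with Ezekiel's formula
adjR2 = 1 - (1 - R2)(n - 1)/(n - p - 1).  Two-set partitioning follows the
classical identity:

    [a] = adjR2(C+S) - adjR2(S)        climate unique
    [c] = adjR2(C+S) - adjR2(C)        space unique
    [b] = adjR2(C) + adjR2(S) - adjR2(C+S)   collinear overlap
    residual = 1 - adjR2(C+S)

All fits work through n x n projection matrices, so the number of SNPs only
enters through the n x n cross-product S = Y Y', making permutation tests
cheap: permuting rows of Y is a symmetric re-indexing of S.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("clinalscan")

__all__ = ["VarPartResult", "rda_r2", "varpart2", "permute_collinear_test",
           "prepare_response"]


@dataclass
class VarPartResult:
    frac_climate_unique: float
    frac_collinear: float
    frac_space_unique: float
    frac_residual: float
    adj_r2_climate: float
    adj_r2_space: float
    adj_r2_both: float
    n_samples: int
    n_permutations: int = 0
    perm_p_collinear: float | None = None
    perm_null_values: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Core fits
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d constant predictor columns",
                       int((~keep).sum()))
    return X[:, keep] / sd[keep]


def _projection(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Hat matrix of the centered, standardized predictor block and its rank.

    Rank-deficient blocks lose collinear columns via QR pivoting.
    """
    Xs = _standardize(X)
    n = Xs.shape[0]
    if Xs.shape[1] == 0:
        return np.zeros((n, n)), 0
    Q, R = np.linalg.qr(Xs)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xs.shape) * np.finfo(float).eps if diag.size else 0
    rank = int((diag > tol).sum())
    if rank < Xs.shape[1]:
        logger.warning("predictor block rank %d < %d columns; dropping "
                       "collinear directions", rank, Xs.shape[1])
        Q = Q[:, diag > tol]
    if rank >= n - 1:
        raise ValueError("predictors must have rank < n - 1")
    return Q @ Q.T, rank


def prepare_response(dosages: np.ndarray, missing: int = -1) -> np.ndarray:
    """Column mean-impute missing dosages and center columns."""
    d = np.asarray(dosages, dtype=float)
    mask = dosages == missing
    if mask.any():
        col_mean = np.where(mask, np.nan, d).mean(axis=0, where=~mask)
        d = np.where(mask, col_mean[None, :], d)
    return d - d.mean(axis=0)


def _adj(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        raise ValueError("too few samples for the predictor count")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def rda_r2(Y: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """RDA explained variance of centered Y on predictor block X.

    Returns (R2, adjusted R2).  X is standardized internally; an intercept is
    implicit through centering.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    P, p = _projection(X)
    tot = float((Y * Y).sum())
    if tot == 0:
        raise ValueError("response matrix has zero variance")
    r2 = float((P @ Y * Y).sum()) / tot  # tr(P S) with S = Y Y'
    return r2, _adj(r2, n, p)


def _fractions_from_S(S: np.ndarray, P_c: np.ndarray, P_s: np.ndarray,
                      P_b: np.ndarray, p_c: int, p_s: int, p_b: int
                      ) -> tuple[float, float, float, float, float, float]:
    n = S.shape[0]
    tot = float(np.trace(S))
    r2c = float((P_c * S).sum()) / tot
    r2s = float((P_s * S).sum()) / tot
    r2b = float((P_b * S).sum()) / tot
    ac, as_, ab = _adj(r2c, n, p_c), _adj(r2s, n, p_s), _adj(r2b, n, p_b)
    return ac, as_, ab, ab - as_, ac + as_ - ab, ab - ac


def varpart2(Y: np.ndarray, X_climate: np.ndarray, X_space: np.ndarray
             ) -> VarPartResult:
    """Two-set adjusted-R^2 variance partition of Y on climate and space."""
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    S = Y @ Y.T
    P_c, p_c = _projection(X_climate)
    P_s, p_s = _projection(X_space)
    P_b, p_b = _projection(np.column_stack([X_climate, X_space]))
    ac, as_, ab, fa, fb, fc = _fractions_from_S(S, P_c, P_s, P_b,
                                                p_c, p_s, p_b)
    return VarPartResult(
        frac_climate_unique=fa, frac_collinear=fb, frac_space_unique=fc,
        frac_residual=1.0 - ab, adj_r2_climate=ac, adj_r2_space=as_,
        adj_r2_both=ab, n_samples=n)


def permute_collinear_test(Y: np.ndarray, X_climate: np.ndarray,
                           X_space: np.ndarray, n_perm: int = 1000,
                           seed: int = 0,
                           permute: str = "rows") -> VarPartResult:
    """Permutation test of the climate-space collinear fraction [b].

    Each permutation shuffles the rows of Y (sample identities) against both
    predictor sets jointly and recomputes [b]; the one-sided upper-tail
    p-value uses the add-one rule p = (1 + #{perm >= obs})/(n_perm + 1).
    ``permute='climate'`` instead permutes the climate block only (testing
    climate conditional on space); the default matches randomizing
    individuals.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if permute not in ("rows", "climate"):
        raise ValueError(f"unknown permute mode {permute!r}")
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    S = Y @ Y.T
    P_c, p_c = _projection(X_climate)
    P_s, p_s = _projection(X_space)
    P_b, p_b = _projection(np.column_stack([X_climate, X_space]))
    ac, as_, ab, fa, fb, fc = _fractions_from_S(S, P_c, P_s, P_b,
                                                p_c, p_s, p_b)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for t in range(n_perm):
        idx = rng.permutation(n)
        if permute == "rows":
            Sp = S[np.ix_(idx, idx)]
            _, _, _, _, b_t, _ = _fractions_from_S(Sp, P_c, P_s, P_b,
                                                   p_c, p_s, p_b)
        else:
            Pc_t, pc_t = _projection(np.asarray(X_climate)[idx])
            Pb_t, pb_t = _projection(np.column_stack(
                [np.asarray(X_climate)[idx], X_space]))
            _, _, _, _, b_t, _ = _fractions_from_S(S, Pc_t, P_s, Pb_t,
                                                   pc_t, p_s, pb_t)
        null[t] = b_t
    p = (1.0 + int((null >= fb).sum())) / (n_perm + 1.0)
    return VarPartResult(
        frac_climate_unique=fa, frac_collinear=fb, frac_space_unique=fc,
        frac_residual=1.0 - ab, adj_r2_climate=ac, adj_r2_space=as_,
        adj_r2_both=ab, n_samples=n, n_permutations=n_perm,
        perm_p_collinear=p, perm_null_values=null)
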