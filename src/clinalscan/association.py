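"""Common-garden BLUPs, kinship, mixed-model GWAS (MLM/MLMM) and GLM scans.

The trait model is y = mu + garden (random) + accession (random) + residual,
fit by REML; accession predictions are shrinkage (BLUP) estimates.  GWAS uses
the one-eigendecomposition mixed model: kinship K is spectrally decomposed
once, the variance ratio delta = sigma_e^2/sigma_g^2 is REML-estimated under
the null by a log-delta grid plus golden-section refinement, and every SNP is
tested by generalized least squares with fixed covariates (intercept + PCs +
SNP).  The multi-locus scan (MLMM) adds the most significant SNP as a fixed
cofactor, re-estimates variance components, and repeats.  The environmental
scan is a deliberately structure-naive per-SNP simple linear regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger("clinalscan")

__all__ = [
    "BLUPTable", "ScanResult", "estimate_blups", "kinship", "mlm_scan",
    "mlmm_scan", "glm_scan", "select_outliers", "genomic_inflation",
    "bonferroni_threshold",
]


@dataclass
class BLUPTable:
    """Per-accession BLUPs (mu + accession effect) with variance components."""

    table: pd.DataFrame            # accession_id, trait, blup, n_records
    var_garden: float
    var_accession: float
    var_residual: float
    mu: float

    def series(self) -> pd.Series:
        return self.table.set_index("accession_id")["blup"]


@dataclass
class ScanResult:
    """Per-variant association statistics for one trait or climate variable."""

    table: pd.DataFrame            # id chrom pos maf effect stderr p_value [outlier]
    model: str
    target: str
    covariates: list[str] = field(default_factory=list)
    threshold: float | None = None
    cofactor_path: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    @property
    def p_values(self) -> np.ndarray:
        return self.table["p_value"].to_numpy()


def bonferroni_threshold(n_markers: int, alpha: float = 0.05) -> float:
    return alpha / n_markers


# ---------------------------------------------------------------------------
# BLUPs
# ---------------------------------------------------------------------------

def estimate_blups(records: pd.DataFrame, trait: str | None = None
                   ) -> BLUPTable:
    """REML fit of y = mu + garden(random) + accession(random) + residual.

    ``records`` needs columns (accession, garden, value); rows with missing
    values are dropped.  Returns mu + BLUP per accession.
    """
    df = records.dropna(subset=["value"]).copy()
    if trait is None:
        trait = str(df["trait"].iloc[0]) if "trait" in df else "trait"
    acc = pd.Categorical(df["accession"])
    gar = pd.Categorical(df["garden"])
    y = df["value"].to_numpy(dtype=float)
    n = len(y)
    n_acc, n_gar = len(acc.categories), len(gar.categories)
    if n_acc < 2:
        raise ValueError("need >= 2 accessions")
    Za = np.zeros((n, n_acc))
    Za[np.arange(n), acc.codes] = 1.0
    Zg = np.zeros((n, n_gar))
    Zg[np.arange(n), gar.codes] = 1.0
    if n_gar == 1:
        logger.warning("single common garden: garden variance fixed at 0")

    Ga = Za @ Za.T
    Gg = Zg @ Zg.T
    X = np.ones((n, 1))

    def reml_nll(params: np.ndarray) -> float:
        la, lg = params
        V = np.exp(la) * Ga + (np.exp(lg) * Gg if n_gar > 1 else 0.0) \
            + np.eye(n)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e30
        logdetV = 2.0 * np.log(np.diag(L)).sum()
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = y - X @ beta
        quad = float(r @ np.linalg.solve(V, r))
        # profiled sigma_e^2
        s2 = quad / (n - 1)
        return 0.5 * ((n - 1) * np.log(s2) + logdetV
                      + float(np.linalg.slogdet(XtViX)[1]) + (n - 1))

    x0 = np.array([0.0, 0.0])
    res = optimize.minimize(reml_nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8,
                                     "maxiter": 400})
    la, lg = res.x
    ratio_a = float(np.exp(la))
    ratio_g = float(np.exp(lg)) if n_gar > 1 else 0.0
    V = ratio_a * Ga + ratio_g * Gg + np.eye(n)
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    mu = float(np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)[0])
    r = y - mu
    s2e = float(r @ np.linalg.solve(V, r)) / (n - 1)
    s2a, s2g = ratio_a * s2e, ratio_g * s2e
    # BLUP: u_a = sigma_a^2 Za' V^-1 (y - mu), on the ratio scale
    u = ratio_a * (Za.T @ np.linalg.solve(V, r))

    counts = pd.Series(acc.codes).value_counts().sort_index()
    tab = pd.DataFrame({
        "accession_id": list(acc.categories),
        "trait": trait,
        "blup": mu + u,
        "n_records": counts.reindex(range(n_acc), fill_value=0).to_numpy(),
    })
    return BLUPTable(tab, var_garden=s2g, var_accession=s2a,
                     var_residual=s2e, mu=mu)


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def kinship(G: GenotypeMatrix) -> tuple[np.ndarray, list[str]]:
    """Centered (VanRaden) kinship K = Z Z' / (2 sum p q).

    Missing dosages are mean-imputed before centering.  Returns (K, sample
    order).
    """
    d = G.dosages
    obs = d != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, d, 0).sum(axis=0) / (2.0 * n_obs)
    poly = np.nan_to_num(p * (1 - p)) > 0
    if not poly.any():
        raise ValueError("kinship needs polymorphic variants")
    p = p[poly]
    Z = np.where(obs[:, poly], d[:, poly], 2 * p[None, :]).astype(float) \
        - 2 * p[None, :]
    denom = 2.0 * float((p * (1 - p)).sum())
    K = Z @ Z.T / denom
    return (K + K.T) / 2.0, list(G.sample_ids)


# ---------------------------------------------------------------------------
# EMMA-style mixed model machinery
# ---------------------------------------------------------------------------

def _reml_delta(yr: np.ndarray, Xr: np.ndarray, lam: np.ndarray,
                n_grid: int = 100) -> float:
    """REML estimate of delta = sigma_e^2/sigma_g^2 on eigen-rotated data.

    Profiled restricted likelihood evaluated on a log-delta grid, refined by
    golden-section search around the best grid point.
    """
    n, p = Xr.shape
    XtX = Xr.T @ Xr

    def nll(logd: float) -> float:
        d = np.exp(logd)
        w = 1.0 / (lam + d)
        Xw = Xr * w[:, None]
        A = Xr.T @ Xw
        try:
            beta = np.linalg.solve(A, Xw.T @ yr)
        except np.linalg.LinAlgError:
            return 1e30
        r = yr - Xr @ beta
        quad = float((r * r * w).sum())
        if quad <= 0:
            return 1e30
        _, ldA = np.linalg.slogdet(A)
        _, ldX = np.linalg.slogdet(XtX)
        return 0.5 * ((n - p) * np.log(quad) + np.log(lam + d).sum()
                      + ldA - ldX)

    grid = np.linspace(-10, 10, n_grid)
    vals = np.array([nll(g) for g in grid])
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(nll, bracket=None, bounds=(lo, hi),
                                   method="bounded",
                                   options={"xatol": 1e-6})
    best = res.x if res.fun <= vals[i] else grid[i]
    return float(np.exp(best))


def _prep_mlm(G: GenotypeMatrix, y: np.ndarray, Q: np.ndarray | None,
              K: np.ndarray, min_maf: float):
    from .popgen_stats import allele_stats

    st = allele_stats(G)
    with np.errstate(invalid="ignore"):
        keep = np.nan_to_num(st["maf"]) >= max(min_maf, 1e-12)
    Gk = G.take_variants(keep)
    maf = st["maf"][keep]
    p = st["alt_freq"][keep]
    d = Gk.dosages
    M = np.where(d != MISSING, d, 2 * p[None, :]).astype(float)

    K = np.asarray(K, dtype=float)
    lam, U = np.linalg.eigh((K + K.T) / 2.0)
    if lam.min() < -1e-8:
        logger.warning("kinship not PSD; flooring eigenvalues at 0")
    lam = np.clip(lam, 0.0, None)
    X = np.ones((len(y), 1))
    if Q is not None and np.size(Q):
        X = np.column_stack([X, np.asarray(Q, dtype=float)])
    return Gk, maf, M, lam, U, X


def _gls_scan(yr, Xr, Mr, w) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-SNP GLS with weights w = 1/(lam+delta).

    Partials the covariate block out of y and each SNP in the W metric, then
    tests the SNP slope with a t-test on n - p - 1 df.
    """
    n, p = Xr.shape
    Xw = Xr * w[:, None]
    A = Xr.T @ Xw
    Ai = np.linalg.inv(A)
    # residualize y and SNP columns: v - X (A^-1 X'W v)
    ytil = yr - Xr @ (Ai @ (Xw.T @ yr))
    Mtil = Mr - Xr @ (Ai @ (Xw.T @ Mr))
    sxx = (Mtil * Mtil * w[:, None]).sum(axis=0)
    sxy = (Mtil * (ytil * w)[:, None]).sum(axis=0)
    syy = float((ytil * ytil * w).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(sxx > 0, sxy / sxx, np.nan)
        rss = syy - np.where(sxx > 0, sxy * sxy / sxx, 0.0)
        df = n - p - 1
        s2 = rss / df
        se = np.sqrt(np.where(sxx > 0, s2 / sxx, np.nan))
        tstat = beta / se
    pv = 2.0 * stats.t.sf(np.abs(tstat), df)
    return beta, se, pv


def mlm_scan(G: GenotypeMatrix, y: np.ndarray, Q_covariates, K,
             min_maf: float = 0.0, cofactor_ids: list[str] | None = None
             ) -> ScanResult:
    """Single-locus mixed-model GWAS (Q + K model).

    Fixed effects: intercept + Q covariates (+ cofactor SNPs); random
    polygenic term with covariance sigma_g^2 K.  delta is REML-estimated once
    under the null model; each SNP is then tested by GLS Wald t-test.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != G.n_samples:
        raise ValueError("phenotype length != n_samples")
    Gk, maf, M, lam, U, X = _prep_mlm(G, y, Q_covariates, K, min_maf)
    cof_idx: list[int] = []
    if cofactor_ids:
        lookup = {v: i for i, v in enumerate(Gk.variant_ids)}
        cof_idx = [lookup[c] for c in cofactor_ids]
        X = np.column_stack([X, M[:, cof_idx]])

    yr, Xr, Mr = U.T @ y, U.T @ X, U.T @ M
    delta = _reml_delta(yr, Xr, lam)
    w = 1.0 / (lam + delta)
    beta, se, pv = _gls_scan(yr, Xr, Mr, w)
    if cof_idx:
        for i in cof_idx:  # a cofactor regressed on itself is meaningless
            beta[i], se[i], pv[i] = np.nan, np.nan, 1.0

    tab = pd.DataFrame({
        "id": Gk.variant_ids, "chrom": Gk.chromosomes,
        "pos": Gk.positions, "maf": maf,
        "effect": beta, "stderr": se,
        "p_value": np.clip(np.nan_to_num(pv, nan=1.0), np.nextafter(0, 1), 1.0),
    })
    return ScanResult(tab, model="mlm", target="trait",
                      covariates=[f"Q{i+1}" for i in
                                  range(Xr.shape[1] - 1 - len(cof_idx))],
                      cofactor_path=list(cofactor_ids or []),
                      extra={"delta": delta})


def mlmm_scan(G: GenotypeMatrix, y: np.ndarray, Q, K,
              max_cofactors: int = 10, threshold: float | None = None,
              min_maf: float = 0.0) -> ScanResult:
    """Multi-locus mixed model: forward SNP-cofactor inclusion + backward check.

    Forward: run mlm_scan, add the most significant SNP as a fixed cofactor
    when its p-value passes ``threshold`` (default: Bonferroni 0.05/m),
    re-estimate variance components, repeat.  Backward: cofactors whose
    p-value in the final model rises above the threshold are dropped from the
    reported cofactor list.  The reported scan is the last forward step.
    """
    scan = mlm_scan(G, y, Q, K, min_maf=min_maf)
    m = len(scan.table)
    if threshold is None:
        threshold = bonferroni_threshold(m)
    cofactors: list[str] = []
    path: list[str] = []
    for _ in range(max_cofactors):
        t = scan.table
        open_rows = ~t["id"].isin(cofactors)
        if not open_rows.any():
            break
        i = t.loc[open_rows, "p_value"].idxmin()
        if t.loc[i, "p_value"] > threshold:
            break
        cofactors.append(str(t.loc[i, "id"]))
        path.append(str(t.loc[i, "id"]))
        scan = mlm_scan(G, y, Q, K, min_maf=min_maf,
                        cofactor_ids=cofactors)

    # backward: test each cofactor in a model with the others fixed
    confirmed = list(cofactors)
    for c in list(cofactors):
        others = [x for x in confirmed if x != c]
        s = mlm_scan(G, y, Q, K, min_maf=min_maf,
                     cofactor_ids=others) if others or True else scan
        pc = float(s.table.set_index("id").loc[c, "p_value"])
        if pc > threshold:
            confirmed.remove(c)

    scan.model = "mlmm"
    scan.threshold = threshold
    scan.cofactor_path = path
    scan.extra["cofactors_confirmed"] = confirmed
    return scan


# ---------------------------------------------------------------------------
# Environmental GLM scan
# ---------------------------------------------------------------------------

def glm_scan(G: GenotypeMatrix, env_values, min_maf: float = 0.03,
             target: str = "env") -> ScanResult:
    """Structure-naive per-SNP regression env ~ intercept + dosage.

    Masked dosages drop pairwise; zero-variance SNPs are skipped.  The
    direction of regression does not change the t-test p-value.
    """
    env = np.asarray(env_values, dtype=float)
    if len(env) != G.n_samples:
        raise ValueError("env length != n_samples")
    if not np.isfinite(env).all():
        raise ValueError("env values must be finite")
    from .popgen_stats import allele_stats

    st = allele_stats(G)
    with np.errstate(invalid="ignore"):
        keep = np.nan_to_num(st["maf"]) >= max(min_maf, 1e-12)
    Gk = G.take_variants(keep)
    maf = st["maf"][keep]
    d = Gk.dosages
    obs = d != MISSING
    x = np.where(obs, d, 0).astype(float)
    e = np.where(obs, env[:, None], 0.0)

    n = obs.sum(axis=0).astype(float)
    sx, sy = x.sum(axis=0), e.sum(axis=0)
    sxx, syy = (x * x).sum(axis=0), (e * e).sum(axis=0)
    sxy = (x * e).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        cov = sxy - sx * sy / n
        beta = np.where(vx > 0, cov / vx, np.nan)
        rss = vy - np.where(vx > 0, cov * cov / vx, 0.0)
        df = n - 2
        se = np.sqrt(np.where((vx > 0) & (df > 0), rss / df / vx, np.nan))
        tstat = beta / se
    pv = 2.0 * stats.t.sf(np.abs(tstat), np.maximum(df, 1))
    ok = np.isfinite(pv)
    tab = pd.DataFrame({
        "id": np.asarray(Gk.variant_ids)[ok],
        "chrom": Gk.chromosomes[ok], "pos": Gk.positions[ok],
        "maf": maf[ok], "effect": beta[ok], "stderr": se[ok],
        "p_value": np.clip(pv[ok], np.nextafter(0, 1), 1.0),
    })
    return ScanResult(tab, model="glm", target=target)


def select_outliers(scan: ScanResult, quantile: float = 0.01) -> ScanResult:
    """Flag the top ``quantile`` of the scan by empirical p-value quantile.

    Ties at the cutoff are all included (with a warning when that makes the
    flagged set larger than the nominal count).
    """
    p = scan.p_values
    if p.size == 0:
        scan.table["outlier"] = []
        return scan
    cut = np.quantile(p, quantile, method="lower")
    flags = p <= cut
    nominal = max(1, int(np.floor(quantile * p.size)))
    if flags.sum() > nominal:
        logger.warning("select_outliers: %d flagged (> nominal %d) due to "
                       "ties at the cutoff", int(flags.sum()), nominal)
    scan.table = scan.table.copy()
    scan.table["outlier"] = flags
    scan.extra["n_outliers"] = int(flags.sum())
    scan.extra["outlier_quantile"] = quantile
    return scan


def genomic_inflation(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median chi2(1df) over its null median."""
    chi2 = stats.chi2.isf(np.asarray(p_values, dtype=float), df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
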