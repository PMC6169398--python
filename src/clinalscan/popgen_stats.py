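"""Genotype QC, filtering and windowed population-genetic statistics.

Implements the classical single-population and multi-population summaries on
dosage matrices with explicit missing-data masking: allele frequencies and
the MAF spectrum, variant filtering (missingness / MAF / minor-allele count /
monomorphic), per-bp nucleotide diversity (pi) in windows, Weir & Cockerham
(1984) F_ST with the ratio-of-sums windowed estimator, Tajima's (1989) D in
windows, LD decay (r^2 vs distance with a smoothing spline), and per-sample
heterozygosity / inbreeding coefficients.

Windows tile each chromosome from position 0, half-open, the last partial
window kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline

from .genotype_io import MISSING, GenotypeMatrix, natural_sort_key

logger = logging.getLogger("clinalscan")

__all__ = [
    "WindowStat", "LDDecayCurve", "SampleQC", "FilterReport",
    "filter_variants", "allele_stats", "nucleotide_diversity_windows",
    "weir_cockerham_fst", "tajima_d_windows", "ld_decay", "sample_qc",
    "tajima_constants",
]


@dataclass(frozen=True)
class WindowStat:
    """One genomic window (0-based half-open) with a statistic value.

    ``value`` is None when the window has too few usable sites.
    """

    chromosome: str
    start: int
    end: int
    value: float | None
    n_sites: int


@dataclass
class LDDecayCurve:
    """Binned mean r^2 against physical distance plus a smoothed curve."""

    bin_edges: np.ndarray          # bp, len = n_bins + 1
    mean_r2: np.ndarray            # len = n_bins, nan where empty
    smoothed_r2: np.ndarray        # len = n_bins
    n_pairs: np.ndarray            # len = n_bins
    crossings: dict[float, float | None] = field(default_factory=dict)
    half_decay_bp: float | None = None

    @property
    def midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


@dataclass(frozen=True)
class SampleQC:
    sample_id: str
    observed_het: float
    inbreeding_f: float | None
    n_sites: int


@dataclass
class FilterReport:
    n_input: int = 0
    n_missingness: int = 0
    n_maf: int = 0
    n_mac: int = 0
    n_monomorphic: int = 0
    n_kept: int = 0


# ---------------------------------------------------------------------------
# Allele statistics and filtering
# ---------------------------------------------------------------------------

def allele_stats(G: GenotypeMatrix) -> dict[str, np.ndarray]:
    """Per-variant ALT frequency, MAF, missing rate and minor-allele count.

    Frequencies use non-missing calls only; an all-missing site gets NaN.
    """
    d = G.dosages
    obs = d != MISSING
    n_obs = obs.sum(axis=0)
    alt = np.where(obs, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    mac = np.minimum(alt, 2 * n_obs - alt)
    return {
        "alt_freq": alt_freq,
        "maf": maf,
        "missing_rate": 1.0 - n_obs / G.n_samples,
        "mac": mac.astype(int),
        "n_obs": n_obs.astype(int),
    }


def filter_variants(G: GenotypeMatrix, max_missing: float = 0.2,
                    min_maf: float = 0.0, min_mac: int = 0,
                    drop_monomorphic: bool = True
                    ) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove variants failing missingness / MAF / MAC / monomorphism rules.

    ``min_mac=3`` reproduces "remove singletons and doubletons".  Rule counts
    are attributed in the order missingness, monomorphic, MAF, MAC (each
    variant counted once, at the first rule it fails).
    """
    st = allele_stats(G)
    rep = FilterReport(n_input=G.n_variants)
    keep = np.ones(G.n_variants, dtype=bool)

    fail = st["missing_rate"] > max_missing
    rep.n_missingness = int(fail.sum())
    keep &= ~fail

    if drop_monomorphic:
        with np.errstate(invalid="ignore"):
            mono = ~(st["maf"] > 0)  # maf == 0 or NaN
        fail = keep & mono
        rep.n_monomorphic = int(fail.sum())
        keep &= ~fail
    if min_maf > 0:
        fail = keep & ~(st["maf"] >= min_maf)  # NaN maf fails
        rep.n_maf = int(fail.sum())
        keep &= ~fail
    if min_mac > 0:
        fail = keep & (st["mac"] < min_mac)
        rep.n_mac = int(fail.sum())
        keep &= ~fail

    rep.n_kept = int(keep.sum())
    if rep.n_kept == 0:
        logger.warning("filter_variants: all %d variants removed", rep.n_input)
    return G.take_variants(keep), rep


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def _iter_windows(G: GenotypeMatrix, window_bp: int):
    """Yield (chrom, start, end, variant index array) tiling from 0."""
    chroms = G.chromosomes
    pos = G.positions
    for c in sorted(set(chroms), key=natural_sort_key):
        sel = np.flatnonzero(chroms == c)
        p = pos[sel]
        last = int(p.max())
        for start in range(0, last + 1, window_bp):
            end = start + window_bp
            in_w = sel[(p > start) & (p <= end)]  # 1-based pos in (start,end]
            yield c, start, end, in_w


def _site_pairwise_pi(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site average pairwise difference among the 2n observed alleles.

    Returns (pi_site, n_alleles); sites with < 2 alleles get pi 0.
    """
    obs = d != MISSING
    n_al = 2 * obs.sum(axis=0)
    alt = np.where(obs, d, 0).sum(axis=0)
    ref = n_al - alt
    denom = n_al * (n_al - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(denom > 0, ref * alt / denom, 0.0)
    return pi, n_al


def nucleotide_diversity_windows(G: GenotypeMatrix, window_bp: int = 1000
                                 ) -> list[WindowStat]:
    """Per-bp nucleotide diversity in tiling windows.

    Per site the unbiased estimator 2*p*q*(2n)/(2n-1) (equivalently the
    average pairwise difference among the 2n alleles); summed over sites and
    divided by the window span in bp.
    """
    pi_site, _ = _site_pairwise_pi(G.dosages)
    out = []
    for c, s, e, idx in _iter_windows(G, window_bp):
        seg = int(np.count_nonzero(pi_site[idx] > 0))
        out.append(WindowStat(c, s, e, float(pi_site[idx].sum()) / window_bp,
                              seg))
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------

def _wc_components(d: np.ndarray, labels: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site W&C (1984) variance components (a, b, c) and a usable mask.

    ``d``: samples x sites dosages with MISSING; ``labels``: integer group
    per sample.  Sites need >= 2 groups with data and mean sample size > 1.
    """
    pops = np.unique(labels)
    obs = d != MISSING
    # per pop per site: n_i (diploids), p_i, h_i
    n_i = np.stack([obs[labels == g].sum(axis=0) for g in pops])  # r x m
    alt = np.stack([np.where(obs[labels == g], d[labels == g], 0).sum(axis=0)
                    for g in pops]).astype(float)
    het = np.stack([((d[labels == g] == 1) & obs[labels == g]).sum(axis=0)
                    for g in pops]).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = alt / (2.0 * n_i)
        h_i = het / n_i

    present = n_i > 0
    r = present.sum(axis=0).astype(float)          # populations with data
    n_tot = n_i.sum(axis=0).astype(float)
    nbar = np.where(r > 0, n_tot / r, np.nan)
    ok = (r >= 2) & (nbar > 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        sum_n2 = (n_i.astype(float) ** 2).sum(axis=0)
        nc = (n_tot - sum_n2 / n_tot) / (r - 1)
        pbar = np.where(present, n_i * np.nan_to_num(p_i), 0).sum(axis=0) / n_tot
        s2 = (np.where(present, n_i * (np.nan_to_num(p_i) - pbar) ** 2, 0)
              .sum(axis=0)) / ((r - 1) * nbar)
        hbar = np.where(present, n_i * np.nan_to_num(h_i), 0).sum(axis=0) / n_tot

        pq = pbar * (1 - pbar)
        a = (nbar / nc) * (
            s2 - (pq - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pq - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0

    for arr in (a, b, c):
        arr[~ok] = np.nan
    # guard nc <= 0 (all data in one pop after masking)
    bad = ~(nc > 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c, ok & (nc > 0)


def weir_cockerham_fst(G: GenotypeMatrix, group_labels,
                       window_bp: int | None = None):
    """Weir & Cockerham theta-hat per site and (optionally) per window.

    Returns ``(per_site_theta, global_theta)`` or, with ``window_bp``,
    ``(per_site_theta, global_theta, window_stats)``.  Windowed and global
    estimates are ratio-of-sums: sum(a) / sum(a+b+c) over usable sites
    (the VCFtools "weighted" estimator).  Per-site values are NaN where the
    denominator is zero; negative estimates are retained.
    """
    labels = np.asarray(group_labels)
    if len(labels) != G.n_samples:
        raise ValueError("group_labels length != n_samples")
    if len(np.unique(labels)) < 2:
        raise ValueError("need >= 2 groups for F_ST")
    a, b, c, ok = _wc_components(G.dosages, labels)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(ok & (denom != 0), a / denom, np.nan)
    use = ok & np.isfinite(denom)
    tot = denom[use].sum()
    global_theta = float(a[use].sum() / tot) if use.any() and tot != 0 else float("nan")

    if window_bp is None:
        return per_site, global_theta
    out = []
    for ch, s, e, idx in _iter_windows(G, window_bp):
        w = idx[use[idx]]
        dsum = denom[w].sum() if w.size else 0.0
        val = float(a[w].sum() / dsum) if w.size and dsum != 0 else None
        out.append(WindowStat(ch, s, e, val, int(w.size)))
    return per_site, global_theta, out


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) constants for n sampled chromosomes."""
    if n < 2:
        raise ValueError("need n >= 2 chromosomes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d_value(pi_sum: float, S: int, n_chrom: int) -> float | None:
    """Tajima's D from summed pairwise diversity, S and chromosome count."""
    if S == 0 or n_chrom < 2:
        return None
    k = tajima_constants(n_chrom)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return None
    return float((pi_sum - S / k["a1"]) / np.sqrt(var))


def tajima_d_windows(G: GenotypeMatrix | np.ndarray, window_bp: int,
                     ploidy: int = 2, min_sites: int = 1) -> list[WindowStat]:
    """Tajima's D in tiling windows from a dosage matrix.

    With ``ploidy=2`` each sample contributes two chromosomes (dosage 0/1/2);
    ``ploidy=1`` treats rows as haplotypes with 0/1 values (used for
    coalescent calibration input).  The chromosome count per window is the
    rounded mean number of observed alleles over its segregating sites (for
    complete data this is exactly ploidy * n_samples).
    """
    if isinstance(G, np.ndarray):
        from .genotype_io import VariantInfo
        m = G.shape[1]
        variants = [VariantInfo("sim", j + 1, id=f"s{j}") for j in range(m)]
        G = GenotypeMatrix(np.asarray(G, dtype=np.int16),
                           [f"h{i}" for i in range(G.shape[0])], variants)
        if ploidy == 1:
            pass  # handled below via allele counting
    d = G.dosages
    obs = d != MISSING
    if ploidy == 1:
        n_al = obs.sum(axis=0)
        alt = np.where(obs, d, 0).sum(axis=0)
        ref = n_al - alt
        denom = n_al * (n_al - 1) / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            pi_site = np.where(denom > 0, ref * alt / denom, 0.0)
    else:
        pi_site, n_al = _site_pairwise_pi(d)

    seg = (pi_site > 0)
    out = []
    for c, s, e, idx in _iter_windows(G, window_bp):
        w = idx[seg[idx]]
        S = int(w.size)
        if S < min_sites:
            out.append(WindowStat(c, s, e, None, S))
            continue
        n_chrom = int(round(n_al[w].mean()))
        out.append(WindowStat(c, s, e,
                              tajima_d_value(float(pi_site[w].sum()), S,
                                             n_chrom), S))
    return out


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors on pairwise-complete
    samples; NaN if either is constant."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return float("nan")
    r = np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy)
    return float(r * r)


def ld_decay(G: GenotypeMatrix, max_dist_bp: int, min_maf: float = 0.05,
             bin_bp: int = 1000, spline_df: int = 8,
             thresholds: tuple[float, ...] = (0.1,)) -> LDDecayCurve:
    """LD decay: binned mean r^2 against distance with a smoothing spline.

    Pairs are restricted to the same chromosome at distance <= max_dist_bp;
    sites below ``min_maf`` are excluded.  Threshold crossings (and the
    half-initial-value distance) are read off the smoothed curve by linear
    interpolation between bin midpoints.
    """
    st = allele_stats(G)
    with np.errstate(invalid="ignore"):
        keep = st["maf"] >= min_maf
    G2 = G.take_variants(keep)
    chroms, pos = G2.chromosomes, G2.positions
    d = G2.dosages
    obs = d != MISSING
    dd = np.where(obs, d, 0).astype(float)

    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    edges = np.arange(n_bins + 1) * bin_bp
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)

    for c in sorted(set(chroms), key=natural_sort_key):
        sel = np.flatnonzero(chroms == c)
        p = pos[sel]
        for ii, i in enumerate(sel):
            js = sel[ii + 1:][(p[ii + 1:] - p[ii] > 0)
                              & (p[ii + 1:] - p[ii] <= max_dist_bp)]
            if js.size == 0:
                continue
            # vectorized pairwise-complete r^2 of site i against sites js
            oi = obs[:, i]
            O = obs[:, js] & oi[:, None]
            n = O.sum(axis=0)
            xi = np.where(O, dd[:, [i]], 0.0)
            yj = np.where(O, dd[:, js], 0.0)
            sx, sy = xi.sum(axis=0), yj.sum(axis=0)
            sxx = (xi * xi).sum(axis=0)
            syy = (yj * yj).sum(axis=0)
            sxy = (xi * yj).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = sxy - sx * sy / n
                vx = sxx - sx * sx / n
                vy = syy - sy * sy / n
                r2 = np.where((vx > 0) & (vy > 0) & (n > 1),
                              cov * cov / (vx * vy), np.nan)
            dist = pos[js] - p[ii]
            bins = np.minimum((dist - 1) // bin_bp, n_bins - 1)
            good = np.isfinite(r2)
            np.add.at(sums, bins[good], r2[good])
            np.add.at(counts, bins[good], 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / counts, np.nan)

    mids = (edges[:-1] + edges[1:]) / 2.0
    filled = np.isfinite(mean_r2)
    smoothed = np.full(n_bins, np.nan)
    if filled.sum() >= 4:
        x, y = mids[filled], mean_r2[filled]
        # cubic smoothing spline; smoothing factor scaled to the target df
        s = max(1e-8, len(x) * np.var(y) / max(spline_df, 1))
        try:
            sp = UnivariateSpline(x, y, k=3, s=s)
            smoothed[filled] = sp(x)
        except Exception:
            smoothed[filled] = y
    elif filled.any():
        smoothed[filled] = mean_r2[filled]

    curve = LDDecayCurve(edges, mean_r2, smoothed, counts)
    sm_x, sm_y = mids[filled], smoothed[filled]
    for t in thresholds:
        curve.crossings[t] = _first_crossing(sm_x, sm_y, t)
    if filled.any():
        curve.half_decay_bp = _first_crossing(sm_x, sm_y, sm_y[0] / 2.0)
    return curve


def _first_crossing(x: np.ndarray, y: np.ndarray,
                    level: float) -> float | None:
    """First distance where the curve drops to ``level`` (linear interp)."""
    if x.size == 0 or y[0] <= level:
        return float(x[0]) if x.size else None
    below = np.flatnonzero(y <= level)
    if below.size == 0:
        return None
    j = below[0]
    x0, x1, y0, y1 = x[j - 1], x[j], y[j - 1], y[j]
    if y0 == y1:
        return float(x1)
    return float(x0 + (y0 - level) * (x1 - x0) / (y0 - y1))


# ---------------------------------------------------------------------------
# Per-sample QC
# ---------------------------------------------------------------------------

def sample_qc(G: GenotypeMatrix) -> list[SampleQC]:
    """Observed heterozygosity and inbreeding F per sample.

    F = 1 - observed_het / expected_het, expectation from per-site 2*p*q
    (panel-wide frequencies) averaged over the sample's non-missing
    polymorphic sites.  F is None for samples with no such sites.
    """
    st = allele_stats(G)
    p = st["alt_freq"]
    with np.errstate(invalid="ignore"):
        exp_het_site = 2.0 * p * (1.0 - p)
    poly = np.nan_to_num(exp_het_site) > 0
    d = G.dosages
    out = []
    for i, sid in enumerate(G.sample_ids):
        obs = (d[i] != MISSING) & poly
        n = int(obs.sum())
        if n == 0:
            out.append(SampleQC(sid, 0.0, None, 0))
            continue
        o_het = float((d[i][obs] == 1).mean())
        e_het = float(exp_het_site[obs].mean())
        f = 1.0 - o_het / e_het if e_het > 0 else None
        out.append(SampleQC(sid, o_het, f, n))
    return out
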