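"""Candidate-gene colocalization and enrichment tests.

A gene is "hit" by a set of genomic points (outlier SNPs or high-D windows)
when the gap between the gene interval and the nearest point is at most a
window (100 kb by default).  Enrichment of the a-priori candidate set over
the background of all annotated genes is tested two ways: a 2x2 Pearson
chi-square (candidate vs other x hit vs not), and a whole-genome gene-set
permutation that redraws candidate-sized gene sets uniformly and compares
hit counts.

All interval arithmetic is 0-based half-open; a SNP at 1-based position P is
the interval [P-1, P), so the gap between a gene [s, e) and a point works out
to max(s - (P-1) - 1, (P-1) - e, 0) -- e.g. a gene ending at 105,000 is
45,000 bp from a SNP at 150,001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GeneAnnotation
from .popgen_stats import WindowStat

logger = logging.getLogger("clinalscan")

__all__ = ["EnrichmentResult", "colocalize", "chisq_enrichment",
           "tajima_gene_permutation", "interval_gap"]


@dataclass
class EnrichmentResult:
    n_candidates_hit: int
    n_candidates: int
    n_all_genes_hit: int
    n_all_genes: int
    chi2_statistic: float | None = None
    chi2_p: float | None = None
    perm_p: float | None = None
    n_perm: int = 0
    null_hit_counts: np.ndarray | None = field(default=None, repr=False)

    @property
    def prop_candidates(self) -> float:
        return self.n_candidates_hit / self.n_candidates if self.n_candidates else 0.0

    @property
    def prop_all(self) -> float:
        return self.n_all_genes_hit / self.n_all_genes if self.n_all_genes else 0.0


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two 0-based half-open intervals (0 if overlapping)."""
    return max(a_start - b_end, b_start - a_end, 0)


def _points_to_intervals(points) -> pd.DataFrame:
    """Normalize SNPs (chrom, pos 1-based) or windows (chrom, start, end)
    to 0-based half-open intervals."""
    rows = []
    for p in points:
        if len(p) == 2:
            chrom, pos = p
            rows.append((str(chrom), int(pos) - 1, int(pos)))
        elif len(p) == 3:
            chrom, s, e = p
            rows.append((str(chrom), int(s), int(e)))
        else:
            raise ValueError(f"point {p!r} is neither (chrom,pos) nor "
                             "(chrom,start,end)")
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def colocalize(points, genes: list[GeneAnnotation],
               window_bp: int = 100_000
               ) -> tuple[dict[str, bool], pd.DataFrame]:
    """Flag genes within ``window_bp`` of any point; report nearest genes.

    ``points``: iterable of (chrom, pos) 1-based SNPs or (chrom, start, end)
    0-based half-open windows.  Returns (gene_id -> hit flag, per-point table
    with the nearest gene and distance).  Chromosome names present in the
    points but absent from the annotation (or vice versa with no overlap at
    all) raise.
    """
    pts = _points_to_intervals(points)
    gene_chroms = {g.chromosome for g in genes}
    bad = sorted(set(pts["chrom"]) - gene_chroms)
    if bad:
        raise ValueError(f"point chromosomes not in annotation: {bad}")

    hits: dict[str, bool] = {}
    by_chrom: dict[str, pd.DataFrame] = {
        c: sub for c, sub in pts.groupby("chrom")}
    nearest = np.full(len(pts), None, dtype=object)
    nearest_d = np.full(len(pts), np.inf)

    for g in genes:
        sub = by_chrom.get(g.chromosome)
        if sub is None:
            hits[g.gene_id] = False
            continue
        gaps = np.maximum.reduce([
            g.start - sub["end"].to_numpy(),
            sub["start"].to_numpy() - g.end,
            np.zeros(len(sub), dtype=int),
        ])
        hits[g.gene_id] = bool((gaps <= window_bp).any())
        closer = gaps < nearest_d[sub.index]
        nearest_d[sub.index[closer]] = gaps[closer]
        nearest[sub.index[closer]] = g.gene_id

    table = pts.copy()
    table["nearest_gene"] = nearest
    table["distance_bp"] = [d if np.isfinite(d) else None for d in nearest_d]
    return hits, table


def chisq_enrichment(hit_flags: dict[str, bool] | np.ndarray,
                     candidate_flags: dict[str, bool] | np.ndarray
                     ) -> EnrichmentResult:
    """2x2 Pearson chi-square (no continuity correction) of candidate vs
    background hit proportions.

    Inputs are aligned hit/candidate flags over all genes (dicts keyed by
    gene id, or parallel boolean arrays).  A zero expected cell leaves the
    p-value missing with a warning.
    """
    if isinstance(hit_flags, dict):
        keys = list(hit_flags)
        if isinstance(candidate_flags, dict):
            hit = np.array([bool(hit_flags[k]) for k in keys])
            cand = np.array([bool(candidate_flags.get(k, False)) for k in keys])
        else:
            raise TypeError("mixed dict/array inputs")
    else:
        hit = np.asarray(hit_flags, dtype=bool)
        cand = np.asarray(candidate_flags, dtype=bool)
        if hit.shape != cand.shape:
            raise ValueError("flag arrays differ in length")

    table = np.array([
        [int((cand & hit).sum()), int((cand & ~hit).sum())],
        [int((~cand & hit).sum()), int((~cand & ~hit).sum())],
    ], dtype=float)
    res = EnrichmentResult(
        n_candidates_hit=int(table[0, 0]), n_candidates=int(table[0].sum()),
        n_all_genes_hit=int(hit.sum()), n_all_genes=int(hit.size))

    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    exp = row @ col / table.sum()
    if (exp == 0).any():
        logger.warning("chisq_enrichment: zero expected cell; p missing")
        return res
    chi2 = float(((table - exp) ** 2 / exp).sum())
    res.chi2_statistic = chi2
    res.chi2_p = float(stats.chi2.sf(chi2, df=1))
    return res


def tajima_gene_permutation(window_stats: list[WindowStat],
                            genes: list[GeneAnnotation],
                            candidate_ids: set[str] | list[str],
                            d_threshold: float = 0.0, n_perm: int = 1000,
                            seed: int = 0) -> EnrichmentResult:
    """Whole-genome gene-set permutation enrichment for high-D windows.

    The observed statistic is the number of candidate genes overlapping a
    window with D >= d_threshold; the null redraws |candidates| genes
    uniformly without replacement from all genes, ``n_perm`` times;
    p = (1 + #{null >= observed})/(n_perm + 1).
    """
    candidate_ids = set(candidate_ids)
    gene_ids = [g.gene_id for g in genes]
    unknown = candidate_ids - set(gene_ids)
    if unknown:
        raise ValueError(f"candidate ids not in gene set: {sorted(unknown)[:5]}")
    if len(candidate_ids) > len(genes):
        raise ValueError("more candidates than genes")

    high = [(w.chromosome, w.start, w.end) for w in window_stats
            if w.value is not None and w.value >= d_threshold]
    overlap = np.zeros(len(genes), dtype=bool)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in high:
        by_chrom.setdefault(c, []).append((s, e))
    for i, g in enumerate(genes):
        for s, e in by_chrom.get(g.chromosome, ()):
            if min(g.end, e) - max(g.start, s) > 0:
                overlap[i] = True
                break

    is_cand = np.array([gid in candidate_ids for gid in gene_ids])
    observed = int(overlap[is_cand].sum())

    rng = np.random.default_rng(seed)
    k = int(is_cand.sum())
    null = np.empty(n_perm, dtype=int)
    for t in range(n_perm):
        draw = rng.choice(len(genes), size=k, replace=False)
        null[t] = int(overlap[draw].sum())
    p = (1.0 + int((null >= observed).sum())) / (n_perm + 1.0)
    return EnrichmentResult(
        n_candidates_hit=observed, n_candidates=k,
        n_all_genes_hit=int(overlap.sum()), n_all_genes=len(genes),
        perm_p=p, n_perm=n_perm, null_hit_counts=null)
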