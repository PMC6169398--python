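"""Synthetic landscape-genomics datasets with known truth.

Generates genotype panels that mimic the statistical structure of a highly
selfing cereal landrace collection sampled along a single climatic gradient:

* population structure from a Balding-Nichols model (k groups around an
  ancestral frequency, differentiation set by Wright's F),
* high within-individual inbreeding (genotype frequencies
  p^2 + pqF, 2pq(1-F), q^2 + pqF),
* one dominant climate axis (an annual-precipitation proxy) collinear with
  latitude at a configurable correlation, plus nine noisy companion
  climate variables,
* a subset of "clinal" loci whose allele frequency follows a logistic cline
  on the standardized climate axis, independently of group membership,
* multi-garden phenotypes with additive genetic values from planted QTLs.

Every draw comes from one seeded numpy Generator, so output is deterministic
under (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .genotype_io import (GeneAnnotation, GenotypeMatrix, SampleTable,
                          VariantInfo)

__all__ = [
    "LandscapeConfig", "TruthTable", "simulate_landscape",
    "simulate_phenotypes", "simulate_coalescent_sites",
    "place_candidate_genes",
]

#: names and target correlations (with the main precipitation axis) of the
#: companion climate variables; bio12 itself is the driving gradient.
_CLIMATE_COMPANIONS = {
    "bio16": 0.90, "bio17": 0.85, "bio18": 0.80, "bio19": 0.75,
    "bio1": -0.23, "bio8": -0.20, "bio9": 0.15, "bio10": -0.10, "bio11": 0.10,
}


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape.

    Defaults describe the clinal regime the package targets: three genetic
    groups at F_ST ~ 0.2, selfing-level inbreeding F ~ 0.8, a precipitation
    axis correlated with latitude at r = -0.86 and enough clinal loci to put
    roughly 3% of SNP variance in the climate-collinear fraction.
    """

    n_samples: int = 300
    n_snps: int = 5000
    k_groups: int = 3
    fst_target: float = 0.2
    n_clinal_loci: int = 500
    clinal_slope: float = 0.9
    climate_space_r: float = -0.86
    selfing_f: float = 0.8
    h2: float = 0.4
    n_gardens: int = 3
    seed: int = 0
    # genome layout (desk scale: densities support 100-kb window statistics)
    n_chromosomes: int = 10
    chrom_length_bp: int = 2_000_000
    # clinal loci drawn singly (1) or in runs of consecutive variants,
    # emulating adaptive regions that dominate their genomic window
    clinal_cluster_size: int = 1
    # trait architecture used by the pipeline
    n_qtl: int = 5
    trait_name: str = "trait"

    def __post_init__(self):
        if not 0 < self.fst_target < 1:
            raise ValueError("fst_target must be in (0,1)")
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must be in [0,1]")
        if abs(self.climate_space_r) > 1:
            raise ValueError("infeasible climate_space_r (|r| > 1)")
        if not 0 <= self.selfing_f <= 1:
            raise ValueError("selfing_f must be in [0,1]")

    @classmethod
    def null(cls, **kw) -> "LandscapeConfig":
        """Calibration regime: no clinal loci, climate independent of space
        and of genotype."""
        kw.setdefault("n_clinal_loci", 0)
        kw.setdefault("climate_space_r", 0.0)
        return cls(**kw)


@dataclass
class TruthTable:
    """Ground truth emitted alongside a simulated landscape."""

    clinal_locus_ids: list[str] = field(default_factory=list)
    clinal_slopes: dict[str, float] = field(default_factory=dict)
    clinal_positions: list[tuple[str, int]] = field(default_factory=list)
    trait_causal: dict[str, list[tuple[str, float]]] = field(
        default_factory=dict)
    group_labels: list[int] = field(default_factory=list)
    candidate_map: dict[str, str | None] = field(default_factory=dict)
    genetic_values: dict[str, list[float]] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["clinal_positions"] = [list(t) for t in self.clinal_positions]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            d = json.load(fh)
        d["clinal_positions"] = [tuple(t) for t in d["clinal_positions"]]
        d["trait_causal"] = {k: [tuple(x) for x in v]
                             for k, v in d["trait_causal"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def simulate_landscape(config: LandscapeConfig
                       ) -> tuple[GenotypeMatrix, SampleTable, TruthTable]:
    """Draw a genotype panel, sample table and truth table.

    Group allele frequencies come from a Balding-Nichols Beta around an
    ancestral Uniform(0.05, 0.95) frequency; genotypes are drawn with
    within-individual inbreeding ``selfing_f``; clinal loci replace the
    group frequency with a logistic cline on the standardized climate axis.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, m, k = cfg.n_samples, cfg.n_snps, cfg.k_groups
    if cfg.n_clinal_loci > m:
        raise ValueError("n_clinal_loci exceeds n_snps")

    # -- variants ------------------------------------------------------------
    chroms = [f"Chr{c + 1:02d}" for c in range(cfg.n_chromosomes)]
    chrom_of = rng.integers(0, cfg.n_chromosomes, size=m)
    pos = rng.integers(1, cfg.chrom_length_bp + 1, size=m)
    order = np.lexsort((pos, chrom_of))
    chrom_of, pos = chrom_of[order], pos[order]
    variants = [VariantInfo(chroms[c], int(p), "A", "T", f"S{c + 1}_{p}")
                for c, p in zip(chrom_of, pos)]
    # resolve duplicate ids (same chrom+pos drawn twice)
    seen: dict[str, int] = {}
    for i, v in enumerate(variants):
        if v.id in seen:
            seen[v.id] += 1
            variants[i] = VariantInfo(v.chromosome, v.position, v.ref, v.alt,
                                      f"{v.id}_{seen[v.id]}")
        else:
            seen[v.id] = 0

    # -- structure: Balding-Nichols group frequencies ------------------------
    # ancestral spectrum is rare-dominated (log-uniform minor-allele
    # frequency, ALT/REF symmetric), mimicking a GBS SNP panel
    F = cfg.fst_target
    maf_anc = 0.005 * (0.5 / 0.005) ** rng.random(m)
    flip = rng.random(m) < 0.5
    p_anc = np.where(flip, 1.0 - maf_anc, maf_anc)
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    group_freq = np.clip(rng.beta(a, b, size=(k, m)), 1e-9, 1 - 1e-9)
    groups = rng.permuted(np.arange(n) % k)

    # -- geography and climate ----------------------------------------------
    latitude = rng.uniform(4.0, 14.0, size=n)
    longitude = rng.uniform(3.0, 15.0, size=n)
    z_lat = (latitude - latitude.mean()) / latitude.std()
    r = cfg.climate_space_r
    eps = rng.standard_normal(n)
    z12 = r * z_lat + np.sqrt(1 - r * r) * eps
    z12 = (z12 - z12.mean()) / z12.std()
    climate = {"bio12": 1100.0 + 600.0 * z12}
    for name, rho in _CLIMATE_COMPANIONS.items():
        e = rng.standard_normal(n)
        zc = rho * z12 + np.sqrt(1 - rho * rho) * e
        if name.startswith("bio1") and name not in ("bio16", "bio17",
                                                    "bio18", "bio19"):
            climate[name] = 27.0 + 1.5 * zc   # temperature, deg C
        else:
            climate[name] = 900.0 + 450.0 * zc  # precipitation, mm

    # -- per-individual allele frequencies ----------------------------------
    P = group_freq[groups, :]  # n x m
    clinal_idx = np.array([], dtype=int)
    if cfg.n_clinal_loci:
        csize = max(1, cfg.clinal_cluster_size)
        if csize == 1:
            clinal_idx = rng.choice(m, size=cfg.n_clinal_loci, replace=False)
        else:
            n_clusters = -(-cfg.n_clinal_loci // csize)
            starts = rng.choice(max(1, m - csize), size=n_clusters,
                                replace=False)
            runs = np.unique(np.concatenate(
                [np.arange(s, s + csize) for s in starts]))
            if runs.size < cfg.n_clinal_loci:
                extra = rng.permutation(np.setdiff1d(np.arange(m), runs))
                runs = np.concatenate(
                    [runs, extra[:cfg.n_clinal_loci - runs.size]])
            clinal_idx = np.sort(runs[:cfg.n_clinal_loci])
        # clinal loci sit at intermediate frequency (maintained by the
        # gradient, the balancing-selection-like regime of stable clines)
        p0 = rng.uniform(0.2, 0.8, size=cfg.n_clinal_loci)
        logits = logit(p0)[None, :] + cfg.clinal_slope * z12[:, None]
        P = P.copy()
        P[:, clinal_idx] = expit(logits)

    # -- genotypes with inbreeding -------------------------------------------
    selfed = rng.random((n, m)) < cfg.selfing_f
    g_self = 2 * (rng.random((n, m)) < P).astype(np.int16)
    g_out = rng.binomial(2, P).astype(np.int16)
    dosages = np.where(selfed, g_self, g_out).astype(np.int16)

    sample_ids = [f"NGA{i + 1:04d}" for i in range(n)]
    gm = GenotypeMatrix(dosages, sample_ids, variants)

    # -- sample table ---------------------------------------------------------
    df = pd.DataFrame({"latitude": latitude, "longitude": longitude,
                       **climate, "group": groups},
                      index=pd.Index(sample_ids, name="sample_id"))
    table = SampleTable(df, ["bio12"] + list(_CLIMATE_COMPANIONS))

    # -- truth ----------------------------------------------------------------
    ids = gm.variant_ids
    clinal_ids = [ids[i] for i in clinal_idx]
    truth = TruthTable(
        clinal_locus_ids=clinal_ids,
        clinal_slopes={cid: float(cfg.clinal_slope) for cid in clinal_ids},
        clinal_positions=[(gm.variants[i].chromosome, gm.variants[i].position)
                          for i in clinal_idx],
        group_labels=[int(g) for g in groups],
        config=asdict(cfg),
    )
    # trait architecture: QTLs drawn from common variants for usable MAF
    if cfg.n_qtl:
        freq = P.mean(axis=0)
        common = np.flatnonzero((freq > 0.1) & (freq < 0.9))
        pool = common if common.size >= cfg.n_qtl else np.arange(m)
        qtl = rng.choice(pool, size=cfg.n_qtl, replace=False)
        effects = rng.normal(0, 1, size=cfg.n_qtl)
        truth.trait_causal[cfg.trait_name] = [
            (ids[i], float(e)) for i, e in zip(qtl, effects)]
    return gm, table, truth


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(truth: TruthTable, genotypes: GenotypeMatrix,
                        h2: float, garden_effects, seed: int,
                        n_gardens: int = 3, trait: str | None = None,
                        mu: float = 100.0) -> pd.DataFrame:
    """Emit per-garden phenotype records y = mu + garden + genetic + residual.

    ``h2`` is the within-garden fraction var(genetic)/var(total); the
    residual SD is scaled from the realized genetic variance to meet it.
    ``garden_effects`` is either a scalar SD for random garden offsets or an
    explicit sequence of offsets (length ``n_gardens``).
    """
    if not 0 <= h2 <= 1:
        raise ValueError("h2 must be in [0,1]")
    rng = np.random.default_rng(seed)
    if trait is None:
        trait = next(iter(truth.trait_causal), "trait")
    causal = truth.trait_causal.get(trait, [])
    n = genotypes.n_samples

    if h2 > 0:
        if not causal:
            raise ValueError(f"h2 > 0 but no causal loci for trait {trait!r}")
        idx = {vid: i for i, vid in enumerate(genotypes.variant_ids)}
        gvals = np.zeros(n)
        D = genotypes.masked()
        for vid, eff in causal:
            col = D[:, idx[vid]]
            gvals += eff * np.asarray(col.filled(col.mean()))
        gvals -= gvals.mean()
        var_g = gvals.var()
        if var_g == 0:
            raise ValueError("causal loci are monomorphic; h2 > 0 infeasible")
        resid_sd = float(np.sqrt(var_g * (1 - h2) / h2)) if h2 < 1 else 0.0
    else:
        gvals = np.zeros(n)
        resid_sd = 1.0
    truth.genetic_values[trait] = [float(v) for v in gvals]

    if np.isscalar(garden_effects):
        offsets = rng.normal(0.0, float(garden_effects), size=n_gardens)
    else:
        offsets = np.asarray(garden_effects, dtype=float)
        n_gardens = len(offsets)

    rows = []
    for j in range(n_gardens):
        resid = rng.normal(0.0, resid_sd, size=n) if resid_sd else np.zeros(n)
        y = mu + offsets[j] + gvals + resid
        rows.append(pd.DataFrame({
            "accession": genotypes.sample_ids,
            "garden": f"garden{j + 1}",
            "trait": trait,
            "value": y,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Coalescent calibration input
# ---------------------------------------------------------------------------

def simulate_coalescent_sites(n_chromosomes: int, theta: float,
                              seed: int) -> np.ndarray:
    """Standard neutral coalescent haplotypes under infinite sites.

    Returns an (n_chromosomes x S) 0/1 matrix of segregating sites.  Time is
    in standard coalescent units (pairwise coalescence rate 1), mutations
    fall at rate theta/2 on total branch length, so E[S] = theta * a1 with
    a1 = sum_{i<n} 1/i.
    """
    if n_chromosomes < 2:
        raise ValueError("need at least 2 chromosomes")
    if theta <= 0:
        raise ValueError("theta must be positive")
    import msprime

    # two decorrelated sub-seeds (consecutive raw seeds must not share
    # streams between the ancestry and mutation passes of neighboring runs)
    s_anc, s_mut = (int(x) % (2 ** 31 - 1) + 1 for x in
                    np.random.SeedSequence(int(seed)).generate_state(2))
    ts = msprime.sim_ancestry(samples=n_chromosomes, ploidy=1,
                              population_size=1.0, random_seed=s_anc)
    mts = msprime.sim_mutations(ts, rate=theta / 2.0, random_seed=s_mut,
                                discrete_genome=False,
                                model=msprime.BinaryMutationModel())
    if mts.num_sites == 0:
        return np.zeros((n_chromosomes, 0), dtype=np.int8)
    return mts.genotype_matrix().T.astype(np.int8)


# ---------------------------------------------------------------------------
# Candidate-gene placement
# ---------------------------------------------------------------------------

def place_candidate_genes(truth: TruthTable, n_genes: int, n_candidates: int,
                          linked_fraction: float, window_bp: int, seed: int,
                          gene_length: int = 5000,
                          max_per_locus: int = 10) -> list[GeneAnnotation]:
    """Place genes on the truth's genome; a fraction of candidates near
    clinal loci.

    ``linked_fraction`` of the candidate genes are placed within
    ``window_bp`` of a true clinal locus; all other genes are uniform.
    """
    if not 0 <= linked_fraction <= 1:
        raise ValueError("linked_fraction must be in [0,1]")
    if n_candidates > n_genes:
        raise ValueError("n_candidates > n_genes")
    cfg = truth.config
    n_chrom = cfg.get("n_chromosomes", 10)
    clen = cfg.get("chrom_length_bp", 2_000_000)
    chroms = [f"Chr{c + 1:02d}" for c in range(n_chrom)]

    n_linked = int(round(linked_fraction * n_candidates))
    n_loci = len(truth.clinal_positions)
    if n_linked > n_loci * max_per_locus:
        raise ValueError(
            f"{n_linked} linked candidates exceed capacity "
            f"({n_loci} clinal loci x {max_per_locus})")

    rng = np.random.default_rng(seed)
    genes: list[GeneAnnotation] = []
    candidate_map: dict[str, str | None] = {}

    def uniform_gene(gid: str, is_cand: bool) -> GeneAnnotation:
        c = chroms[rng.integers(0, n_chrom)]
        s = int(rng.integers(0, max(1, clen - gene_length)))
        return GeneAnnotation(gid, c, s, s + gene_length, is_cand)

    locus_use = np.zeros(max(n_loci, 1), dtype=int)
    for i in range(n_genes):
        gid = f"gene{i + 1:05d}"
        is_cand = i < n_candidates
        if is_cand and i < n_linked:
            avail = np.flatnonzero(locus_use < max_per_locus)
            li = int(rng.choice(avail))
            locus_use[li] += 1
            chrom, lpos = truth.clinal_positions[li]
            lo = max(0, lpos - window_bp)
            hi = min(clen - gene_length, lpos + window_bp - gene_length)
            s = int(rng.integers(lo, max(lo + 1, hi)))
            genes.append(GeneAnnotation(gid, chrom, s, s + gene_length, True))
            candidate_map[gid] = truth.clinal_locus_ids[li]
        else:
            genes.append(uniform_gene(gid, is_cand))
            if is_cand:
                candidate_map[gid] = None
    truth.candidate_map = candidate_map
    return genes
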