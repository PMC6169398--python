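"""End-to-end pipeline: QC -> popgen stats -> structure -> RDA -> scans ->
enrichment, driven by one config with per-stage checkpointing.

Each stage writes its tables plus a small ``<stage>.json`` of headline
numbers into the run directory; a stage is recomputed only when its JSON is
missing, so deleting one stage output and re-running recomputes just that
stage.  ``summary.json`` merges the stage JSONs (no timestamps, sorted keys),
making reruns byte-identical under fixed seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, enrichment, genotype_io, popgen_stats, structure
from . import synthetic_landscape as synth
from . import variance_partition as vp

logger = logging.getLogger("clinalscan")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline settings; defaults follow the printed analysis settings
    (missingness < 0.2, MAF 0.03 for GWAS, MAC 3, 1-kb pi windows, 100-kb D
    and colocalization windows, prune r^2 0.5, 1000 permutations)."""

    # inputs; when vcf is None the synthetic landscape is generated
    vcf: str | None = None
    sample_table: str | None = None
    genes: str | None = None
    candidate_file: str | None = None
    phenotypes: str | None = None
    simulate: dict = field(default_factory=dict)

    # filters
    max_missing: float = 0.2
    min_mac: int = 3
    gwas_min_maf: float = 0.03
    pca_min_maf: float = 0.05
    # windows (bp)
    pi_window: int = 1000
    tajima_window: int = 100_000
    coloc_window: int = 100_000
    ld_max_dist: int = 200_000
    ld_bin: int = 5000
    prune_r2: float = 0.5
    # tests
    n_perm: int = 1000
    outlier_quantile: float = 0.01
    dapc_k_max: int = 6
    trait: str = "trait"
    climate_vars: list[str] = field(default_factory=lambda: ["bio12", "bio17",
                                                             "bio1"])
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _dump(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _round(x, nd=10):
    if isinstance(x, float):
        return round(x, nd)
    return x


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages into ``outdir``; returns the merged summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_fh = logging.FileHandler(out / "run.log")
    log_fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(log_fh)
    logger.setLevel(logging.INFO)
    state: dict = {}
    stages = [
        ("data", _stage_data), ("filter", _stage_filter),
        ("popgen", _stage_popgen), ("structure", _stage_structure),
        ("varpart", _stage_varpart), ("scans", _stage_scans),
        ("enrichment", _stage_enrichment),
    ]
    try:
        for name, fn in stages:
            marker = out / f"{name}.json"
            if marker.exists():
                logger.info("stage %s: cached, skipping", name)
                _load_stage(name, out, config, state)
                continue
            t0 = time.perf_counter()
            logger.info("stage %s: running", name)
            result = fn(config, out, state)
            _dump(result, marker)
            logger.info("stage %s: done in %.2fs", name,
                        time.perf_counter() - t0)
        summary = {"config": config.to_dict()}
        for name, _ in stages:
            with open(out / f"{name}.json") as fh:
                summary[name] = json.load(fh)
        _dump(summary, out / "summary.json")
        return summary
    finally:
        logger.removeHandler(log_fh)
        log_fh.close()


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_data(cfg: RunConfig, out: Path, state: dict) -> dict:
    if cfg.vcf is None:
        sim_kw = dict(cfg.simulate)
        sim_kw.setdefault("seed", cfg.seed)
        lc = synth.LandscapeConfig(**sim_kw)
        gm, table, truth = synth.simulate_landscape(lc)
        phen = synth.simulate_phenotypes(truth, gm, lc.h2, 5.0,
                                         seed=cfg.seed + 1,
                                         n_gardens=lc.n_gardens,
                                         trait=cfg.trait)
        genes = synth.place_candidate_genes(truth, n_genes=1000,
                                            n_candidates=100,
                                            linked_fraction=1.0,
                                            window_bp=cfg.coloc_window,
                                            seed=cfg.seed + 2)
        genotype_io.write_vcf(gm, out / "genotypes.vcf")
        genotype_io.write_table(table, out / "samples.tsv")
        genotype_io.write_gff3(genes, out / "genes.gff3")
        genotype_io.write_table(phen, out / "phenotypes.tsv")
        truth.to_json(out / "truth.json")
        with open(out / "candidates.txt", "w") as fh:
            for g in genes:
                if g.is_candidate:
                    fh.write(g.gene_id + "\n")
    else:
        gm = genotype_io.read_vcf(cfg.vcf)
        table = genotype_io.read_sample_table(cfg.sample_table)
        cand = []
        if cfg.candidate_file:
            cand = [line.strip() for line in open(cfg.candidate_file)
                    if line.strip()]
        genes = genotype_io.read_genes(cfg.genes, cand) if cfg.genes else []
        phen = (pd.read_csv(cfg.phenotypes, sep="\t")
                if cfg.phenotypes else None)
        truth = None
        genotype_io.write_vcf(gm, out / "genotypes.vcf")
        genotype_io.write_table(table, out / "samples.tsv")
        if genes:
            genotype_io.write_gff3(genes, out / "genes.gff3")
        if phen is not None:
            genotype_io.write_table(phen, out / "phenotypes.tsv")
    state.update(gm=gm, table=table, genes=genes, phen=phen, truth=truth)
    return {"n_samples": gm.n_samples, "n_variants": gm.n_variants,
            "n_genes": len(genes),
            "n_candidates": sum(g.is_candidate for g in genes)}


def _stage_filter(cfg: RunConfig, out: Path, state: dict) -> dict:
    gm, rep = popgen_stats.filter_variants(
        state["gm"], max_missing=cfg.max_missing, min_mac=cfg.min_mac)
    genotype_io.write_vcf(gm, out / "filtered.vcf")
    state["gmf"] = gm
    return {"n_input": rep.n_input, "removed_missingness": rep.n_missingness,
            "removed_mac": rep.n_mac, "removed_monomorphic": rep.n_monomorphic,
            "n_kept": rep.n_kept}


def _windows_df(ws) -> pd.DataFrame:
    return pd.DataFrame([{"CHROM": w.chromosome, "BIN_START": w.start,
                          "BIN_END": w.end, "N_SITES": w.n_sites,
                          "VALUE": w.value} for w in ws])


def _stage_popgen(cfg: RunConfig, out: Path, state: dict) -> dict:
    gm = state["gmf"]
    pi = popgen_stats.nucleotide_diversity_windows(gm, cfg.pi_window)
    genotype_io.write_table(_windows_df(pi), out / "pi_windows.tsv")
    taj = popgen_stats.tajima_d_windows(gm, cfg.tajima_window)
    genotype_io.write_table(_windows_df(taj), out / "tajima_windows.tsv")
    state["tajima"] = taj
    qc = popgen_stats.sample_qc(gm)
    genotype_io.write_table(pd.DataFrame(
        [{"sample_id": q.sample_id, "observed_het": q.observed_het,
          "inbreeding_f": q.inbreeding_f} for q in qc]), out / "sample_qc.tsv")
    ld = popgen_stats.ld_decay(gm, cfg.ld_max_dist, bin_bp=cfg.ld_bin)
    genotype_io.write_table(pd.DataFrame(
        {"DIST_BP": ld.midpoints, "MEAN_R2": ld.mean_r2,
         "SMOOTH_R2": ld.smoothed_r2, "N_PAIRS": ld.n_pairs}),
        out / "ld_decay.tsv")
    res = {
        "pi_mean_per_bp": _round(float(np.mean([w.value for w in pi]))),
        "tajima_d_mean": _round(float(np.mean(
            [w.value for w in taj if w.value is not None]))
            if any(w.value is not None for w in taj) else None),
        "mean_observed_het": _round(float(np.mean(
            [q.observed_het for q in qc]))),
        "mean_inbreeding_f": _round(float(np.mean(
            [q.inbreeding_f for q in qc if q.inbreeding_f is not None]))),
        "ld_r2_0.1_crossing_bp": _round(ld.crossings.get(0.1)),
    }
    groups = state["table"].data.get("group")
    if groups is not None and groups.notna().all() \
            and groups.nunique() >= 2:
        lab = groups.loc[gm.sample_ids].to_numpy()
        _, theta = popgen_stats.weir_cockerham_fst(gm, lab)
        res["fst_global"] = _round(float(theta))
    return res


def _stage_structure(cfg: RunConfig, out: Path, state: dict) -> dict:
    gm = state["gmf"]
    pruned = structure.ld_prune(gm, r2_threshold=cfg.prune_r2)
    pcs = structure.pca(pruned, min_maf=cfg.pca_min_maf)
    genotype_io.write_table(pd.DataFrame(
        pcs.scores[:, :10],
        columns=[f"PC{i+1}" for i in range(min(10, pcs.scores.shape[1]))]
    ).assign(sample_id=gm.sample_ids), out / "pca_scores.tsv")
    dapc = structure.dapc_find_clusters(pruned, k_max=cfg.dapc_k_max,
                                        seed=cfg.seed + 10)
    genotype_io.write_table(pd.DataFrame(
        {"sample_id": gm.sample_ids, "group": dapc.assignments}),
        out / "dapc_assignments.tsv")
    genotype_io.write_table(pd.DataFrame(
        {"k": list(dapc.bic_by_k), "bic": list(dapc.bic_by_k.values())}),
        out / "dapc_bic.tsv")
    D = structure.ibs_distance(pruned)
    tree = structure.nj_tree(D, gm.sample_ids)
    genotype_io.write_newick(tree, out / "nj_tree.nwk")
    state["pca"] = pcs
    state["dapc"] = dapc
    return {"n_pruned_variants": pruned.n_variants,
            "k_selected": int(dapc.k_selected),
            "pc1_var_pct": _round(float(
                100 * pcs.explained_variance_fraction[0])),
            "pc2_var_pct": _round(float(
                100 * pcs.explained_variance_fraction[1]))}


def _stage_varpart(cfg: RunConfig, out: Path, state: dict) -> dict:
    gm, table = state["gmf"], state["table"]
    geo = table.aligned_to(gm.sample_ids).georeferenced()
    sub = gm.take_samples(gm.sample_index(geo.sample_ids))
    Y = vp.prepare_response(sub.dosages)
    res = vp.permute_collinear_test(Y, geo.climate_matrix(),
                                    geo.space_matrix(),
                                    n_perm=max(99, cfg.n_perm),
                                    seed=cfg.seed + 20)
    np.savetxt(out / "varpart_null.txt", res.perm_null_values)
    return {"climate_unique_pct": _round(100 * res.frac_climate_unique, 6),
            "collinear_pct": _round(100 * res.frac_collinear, 6),
            "space_unique_pct": _round(100 * res.frac_space_unique, 6),
            "residual_pct": _round(100 * res.frac_residual, 6),
            "perm_p": res.perm_p_collinear,
            "n_perm": res.n_permutations}


def _stage_scans(cfg: RunConfig, out: Path, state: dict) -> dict:
    gm, table = state["gmf"], state["table"]
    res: dict = {}
    # phenotype GWAS
    if state.get("phen") is not None:
        blup = association.estimate_blups(state["phen"], trait=cfg.trait)
        genotype_io.write_table(blup.table, out / "blups.tsv")
        y = blup.series().reindex(gm.sample_ids)
        ok = y.notna().to_numpy()
        sub = gm.take_samples(ok)
        K, _ = association.kinship(sub)
        pcs = structure.pca(sub, min_maf=cfg.pca_min_maf)
        scan = association.mlmm_scan(sub, y.to_numpy()[ok],
                                     pcs.scores[:, :3], K,
                                     min_maf=cfg.gwas_min_maf)
        genotype_io.write_table(scan.table.rename(columns=str.upper),
                                out / f"mlmm_{cfg.trait}.tsv")
        res["mlmm_n_cofactors"] = len(scan.cofactor_path)
        res["mlmm_min_p"] = _round(float(scan.table["p_value"].min()))
        res["bonferroni_threshold"] = _round(scan.threshold, 12)
    # climate GLM scans on georeferenced samples
    geo = table.aligned_to(gm.sample_ids).georeferenced()
    sub = gm.take_samples(np.asarray(
        [gm.sample_ids.index(s) for s in geo.sample_ids]))
    outliers = {}
    for var in cfg.climate_vars:
        env = geo.data[var].to_numpy(dtype=float)
        scan = association.glm_scan(sub, env, min_maf=cfg.gwas_min_maf,
                                    target=var)
        scan = association.select_outliers(scan, cfg.outlier_quantile)
        genotype_io.write_table(scan.table.rename(columns=str.upper),
                                out / f"glm_{var}.tsv")
        outliers[var] = scan
        res[f"glm_{var}_n_outliers"] = int(scan.extra["n_outliers"])
    state["glm_scans"] = outliers
    return res


def _stage_enrichment(cfg: RunConfig, out: Path, state: dict) -> dict:
    genes = state.get("genes") or []
    if not genes:
        return {"skipped": "no gene annotation"}
    cand_flags = {g.gene_id: g.is_candidate for g in genes}
    cand_ids = [g.gene_id for g in genes if g.is_candidate]
    res: dict = {}
    for var, scan in state.get("glm_scans", {}).items():
        t = scan.table[scan.table["outlier"]]
        pts = list(zip(t["chrom"], t["pos"]))
        hits, _ = enrichment.colocalize(pts, genes, cfg.coloc_window)
        enr = enrichment.chisq_enrichment(hits, cand_flags)
        res[f"{var}_pct_candidates_near_outlier"] = _round(
            100 * enr.prop_candidates, 6)
        res[f"{var}_pct_all_genes_near_outlier"] = _round(
            100 * enr.prop_all, 6)
        res[f"{var}_chi2_p"] = _round(enr.chi2_p, 12)
    taj = state.get("tajima")
    if taj is not None and cand_ids:
        enr = enrichment.tajima_gene_permutation(
            taj, genes, cand_ids, d_threshold=0.0,
            n_perm=max(99, cfg.n_perm), seed=cfg.seed + 30)
        np.savetxt(out / "tajima_enrichment_null.txt", enr.null_hit_counts,
                   fmt="%d")
        res["tajima_perm_p"] = enr.perm_p
        res["tajima_candidates_in_positive_windows"] = enr.n_candidates_hit
    return res


# ---------------------------------------------------------------------------
# Cached-stage reload (minimal: only what later stages consume)
# ---------------------------------------------------------------------------

def _load_stage(name: str, out: Path, cfg: RunConfig, state: dict) -> None:
    if name == "data":
        gm = genotype_io.read_vcf(out / "genotypes.vcf")
        table = genotype_io.read_sample_table(out / "samples.tsv")
        genes = []
        if (out / "genes.gff3").exists():
            cand = []
            if (out / "candidates.txt").exists():
                cand = [line.strip() for line in open(out / "candidates.txt")]
            genes = genotype_io.read_genes(out / "genes.gff3", cand)
        phen = None
        if (out / "phenotypes.tsv").exists():
            phen = pd.read_csv(out / "phenotypes.tsv", sep="\t")
        state.update(gm=gm, table=table, genes=genes, phen=phen, truth=None)
    elif name == "filter":
        state["gmf"] = genotype_io.read_vcf(out / "filtered.vcf")
    elif name == "popgen":
        df = pd.read_csv(out / "tajima_windows.tsv", sep="\t")
        state["tajima"] = [
            popgen_stats.WindowStat(r.CHROM, int(r.BIN_START), int(r.BIN_END),
                                    None if pd.isna(r.VALUE) else float(r.VALUE),
                                    int(r.N_SITES))
            for r in df.itertuples()]
    elif name == "scans":
        scans = {}
        for var in cfg.climate_vars:
            f = out / f"glm_{var}.tsv"
            if f.exists():
                t = pd.read_csv(f, sep="\t").rename(columns=str.lower)
                scans[var] = association.ScanResult(t, model="glm",
                                                    target=var)
        state["glm_scans"] = scans
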