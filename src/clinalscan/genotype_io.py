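"""Genotype, sample-table and gene-annotation I/O and the core data model.

The central object is :class:`GenotypeMatrix`, a samples x variants dosage
matrix (count of ALT alleles, 0/1/2) with a sentinel for missing calls.  All
interval arithmetic inside the package is 0-based half-open; GFF3 (1-based
closed) and VCF positions (1-based) are converted on the way in and restored
on the way out.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("clinalscan")

#: Sentinel dosage for a missing genotype call.  Distinct from 0; every
#: statistic in the package masks it explicitly.
MISSING: int = -1

_CLIMATE_COL_RE = re.compile(r"^(bio\d+|clim\w+)$", re.IGNORECASE)


class FormatError(ValueError):
    """Malformed input file (header, ploidy, coordinates, duplicates)."""


def natural_sort_key(chrom: str) -> tuple:
    """Sort key placing Chr2 before Chr10 (natural ordering of digit runs)."""
    return tuple(int(t) if t.isdigit() else t for t in re.split(r"(\d+)", chrom))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantInfo:
    """A biallelic SNP: 1-based position, single-character alleles."""

    chromosome: str
    position: int  # 1-based, per VCF
    ref: str = "A"
    alt: str = "T"
    id: str = "."

    def __post_init__(self):
        if self.position < 1:
            raise FormatError(f"variant position must be >= 1, got {self.position}")


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix (n_samples x n_variants) plus variant metadata.

    ``dosages`` holds values in {0, 1, 2, MISSING}.  Variants are kept sorted
    by (chromosome, position) under natural chromosome ordering.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    variants: list[VariantInfo]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} != "
                f"({len(self.sample_ids)} samples, {len(self.variants)} variants)"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values outside {0,1,2,MISSING}")
        self._sort_variants()

    def _sort_variants(self) -> None:
        order = sorted(
            range(len(self.variants)),
            key=lambda i: (natural_sort_key(self.variants[i].chromosome),
                           self.variants[i].position),
        )
        if order != list(range(len(self.variants))):
            self.variants = [self.variants[i] for i in order]
            self.dosages = self.dosages[:, order]

    # -- convenience views ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.asarray([v.chromosome for v in self.variants])

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([v.position for v in self.variants], dtype=np.int64)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def masked(self) -> np.ma.MaskedArray:
        """Dosages as a float masked array (missing masked)."""
        d = self.dosages
        return np.ma.masked_array(d.astype(float), mask=(d == MISSING))

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            list(self.sample_ids),
            [self.variants[i] for i in index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[index, :],
            [self.sample_ids[i] for i in index],
            list(self.variants),
        )

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.asarray([lookup[s] for s in ids])
        except KeyError as e:
            raise KeyError(f"sample {e} not in genotype matrix") from None

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.sample_ids == other.sample_ids
            and self.variants == other.variants
            and np.array_equal(self.dosages, other.dosages)
        )


@dataclass
class SampleTable:
    """Per-accession geography, climate and (optional) group labels.

    ``data`` is indexed by sample_id with columns ``latitude``, ``longitude``,
    the named climate variables (mm or degrees C), and optional ``race`` and
    ``group``.
    """

    data: pd.DataFrame
    climate_columns: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise FormatError("duplicate sample_id in sample table")
        for c in self.climate_columns:
            if c not in self.data.columns:
                raise ValueError(f"climate column {c!r} missing from table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def georeferenced(self) -> "SampleTable":
        """Subset with finite latitude and longitude (e.g. 443 of 607)."""
        ok = self.data["latitude"].notna() & self.data["longitude"].notna()
        return SampleTable(self.data.loc[ok].copy(), list(self.climate_columns))

    def aligned_to(self, sample_ids: Sequence[str]) -> "SampleTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples absent from table: {missing[:5]}...")
        return SampleTable(self.data.loc[list(sample_ids)].copy(),
                           list(self.climate_columns))

    def climate_matrix(self) -> np.ndarray:
        return self.data[self.climate_columns].to_numpy(dtype=float)

    def space_matrix(self) -> np.ndarray:
        return self.data[["latitude", "longitude"]].to_numpy(dtype=float)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval, stored 0-based half-open, with an a-priori flag."""

    gene_id: str
    chromosome: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    is_candidate: bool = False

    def __post_init__(self):
        if not self.start < self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} !< end {self.end}")


# ---------------------------------------------------------------------------
# Coordinate conversions (inverse pair, used by GFF3 I/O)
# ---------------------------------------------------------------------------

def gff3_to_internal(start_1based: int, end_closed: int) -> tuple[int, int]:
    """GFF3 1-based closed interval -> 0-based half-open."""
    return start_1based - 1, end_closed


def internal_to_gff3(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> GFF3 1-based closed."""
    return start + 1, end


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, missing_policy: str = "mask") -> GenotypeMatrix:
    """Read a VCF 4.x file (GT required) into a GenotypeMatrix.

    Dosage is the ALT-allele count; ``./.`` and half-missing calls become
    MISSING (``missing_policy='mask'``) or the per-site modal dosage
    (``'mode-impute'``).  Multiallelic records are dropped with a logged
    count.  Non-diploid GT raises.
    """
    if missing_policy not in ("mask", "mode-impute"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as e:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"cannot parse VCF {path}: {e}") from e
    samples = list(vcf.samples)
    if not samples:
        raise FormatError("VCF has no sample columns (GT required)")

    rows: list[np.ndarray] = []
    variants: list[VariantInfo] = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gts = rec.genotypes  # list of [a0, a1, phased]
        dos = np.empty(len(samples), dtype=np.int16)
        for i, g in enumerate(gts):
            if len(g) != 3:
                raise FormatError(
                    f"non-diploid genotype at {rec.CHROM}:{rec.POS} sample "
                    f"{samples[i]}")
            a0, a1 = g[0], g[1]
            dos[i] = MISSING if (a0 < 0 or a1 < 0) else a0 + a1
        variants.append(VariantInfo(rec.CHROM, rec.POS, rec.REF, rec.ALT[0],
                                    rec.ID or f"{rec.CHROM}_{rec.POS}"))
        rows.append(dos)
    vcf.close()
    if n_multi:
        logger.info("read_vcf: dropped %d multiallelic records", n_multi)

    dosages = (np.stack(rows, axis=1) if rows
               else np.empty((len(samples), 0), dtype=np.int16))
    gm = GenotypeMatrix(dosages, samples, variants)
    if missing_policy == "mode-impute":
        gm = _mode_impute(gm)
    return gm


def _mode_impute(gm: GenotypeMatrix) -> GenotypeMatrix:
    d = gm.dosages.copy()
    for j in range(d.shape[1]):
        col = d[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        obs = col[~miss]
        fill = np.bincount(obs, minlength=3).argmax() if obs.size else 0
        col[miss] = fill
    return GenotypeMatrix(d, gm.sample_ids, gm.variants)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotype columns."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    chroms = sorted({v.chromosome for v in gm.variants}, key=natural_sort_key)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=clinalscan\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for j, v in enumerate(gm.variants):
            gts = "\t".join(code[int(d)] for d in gm.dosages[:, j])
            fh.write(f"{v.chromosome}\t{v.position}\t{v.id}\t{v.ref}\t{v.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Gene annotations (GFF3 / BED)
# ---------------------------------------------------------------------------

def read_genes(path: str | Path,
               candidate_list: Iterable[str] = ()) -> list[GeneAnnotation]:
    """Read gene intervals from GFF3 (.gff/.gff3, gene features) or BED.

    Format is auto-detected from the extension.  Coordinates are normalized
    to 0-based half-open; ``is_candidate`` marks membership in
    ``candidate_list``.  Duplicate gene ids raise.
    """
    path = Path(path)
    cand = set(candidate_list)
    genes: list[GeneAnnotation] = []
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        attr_re = re.compile(r"ID=([^;]+)")
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9:
                    raise FormatError(f"bad GFF3 line: {line[:60]!r}")
                if f[2] != "gene":
                    continue
                m = attr_re.search(f[8])
                gid = m.group(1) if m else f"{f[0]}:{f[3]}-{f[4]}"
                start, end = gff3_to_internal(int(f[3]), int(f[4]))
                genes.append(GeneAnnotation(gid, f[0], start, end,
                                            gid in cand))
    elif suffix == ".bed":
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 3:
                    raise FormatError(f"bad BED line: {line[:60]!r}")
                gid = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
                genes.append(GeneAnnotation(gid, f[0], int(f[1]), int(f[2]),
                                            gid in cand))
    else:
        raise FormatError(f"cannot detect annotation format from {path.name!r}")

    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"duplicate gene ids: {dup[:5]}")
    missing = cand - set(ids)
    if missing:
        logger.warning("read_genes: %d candidate ids not in annotation",
                       len(missing))
    return genes


def write_gff3(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s1, e1 = internal_to_gff3(g.start, g.end)
            fh.write(f"{g.chromosome}\tclinalscan\tgene\t{s1}\t{e1}\t.\t+\t.\t"
                     f"ID={g.gene_id}\n")


# ---------------------------------------------------------------------------
# Tables and trees
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path,
                      climate_columns: Sequence[str] | None = None
                      ) -> SampleTable:
    """Read a tab-delimited sample table (header required).

    Samples with missing latitude stay in the table (they remain genotyped)
    but drop out of :meth:`SampleTable.georeferenced`.  Climate columns are
    auto-detected (``bio*``/``clim*``) unless given explicitly.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                     na_values=["NA", ""])
    if "sample_id" not in df.columns:
        raise FormatError("sample table must have a sample_id column")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample_id: {dups[:5]}")
    df = df.set_index("sample_id")
    for col in ("latitude", "longitude"):
        if col not in df.columns:
            df[col] = np.nan
    if climate_columns is None:
        climate_columns = [c for c in df.columns if _CLIMATE_COL_RE.match(c)]
    return SampleTable(df, list(climate_columns))


def write_table(obj, path: str | Path, float_format: str = "%.17g") -> None:
    """Write a DataFrame (or SampleTable) as tab-delimited text."""
    if isinstance(obj, SampleTable):
        obj.data.reset_index().rename(
            columns={"index": "sample_id"}).to_csv(
            path, sep="\t", index=False, float_format=float_format)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=False, float_format=float_format)
    else:
        raise TypeError(f"cannot write object of type {type(obj)}")


def write_newick(tree, path: str | Path) -> None:
    """Write an skbio TreeNode in Newick format."""
    tree.write(str(path), format="newick")


def read_newick(path: str | Path):
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")
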