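"""Readers, writers and site-to-gene assignment.

Conventions
-----------
* VCF and allele-count TSV positions are 1-based; gene annotations are
  0-based half-open (BED convention). The conversion lives in one place
  (:func:`pos_to_0based`).
* Chromosome names are normalized at read time: ``chrX`` and ``X`` are the
  same chromosome.
* Allele-count tables travel as :class:`pandas.DataFrame` with columns
  ``cell, chrom, pos, n_ref, n_alt`` (unphased) and, once phase has been
  resolved, additionally ``n_mat, n_pat``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from cyvcf2 import VCF
from intervaltree import IntervalTree

from .types import (
    AlleleCountRecord,
    CatalogEntry,
    GeneModel,
    HetSNP,
    Phase,
)

logger = logging.getLogger(__name__)

#: Sentinel gene id for sites that fall in no annotated gene.
INTERGENIC = "__intergenic__"


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix so ``chrX`` == ``X``."""
    return name[3:] if name.lower().startswith("chr") else name


def pos_to_0based(pos_1based: int) -> int:
    """Convert a 1-based coordinate (VCF/TSV) to 0-based (BED)."""
    return pos_1based - 1


# ---------------------------------------------------------------------------
# hSNPs from VCF
# ---------------------------------------------------------------------------

def read_hsnps(
    vcf_path: str | Path,
    sample: str,
    *,
    paternal_first: bool = True,
) -> list[HetSNP]:
    """Read biallelic heterozygous SNVs for one sample from a VCF.

    Phase is recorded only for ``|``-separated genotypes.  ``paternal_first``
    states which side of the ``|`` is the paternal haplotype; the default
    (first field paternal) matches the usual layout of phased trio VCFs.
    Multiallelic sites, indels and non-het genotypes are skipped; skip
    counts are logged.

    Raises
    ------
    KeyError
        If ``sample`` is not in the VCF header.
    """
    vcf = VCF(str(vcf_path))
    if sample not in vcf.samples:
        raise KeyError(f"sample {sample!r} not found in {vcf_path}")
    sidx = vcf.samples.index(sample)

    hsnps: list[HetSNP] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        gt = var.genotypes[sidx]  # [allele0, allele1, phased_flag]
        if len(gt) < 3:
            n_skipped += 1
            continue
        a0, a1, phased_flag = gt[0], gt[1], bool(gt[-1])
        if {a0, a1} != {0, 1}:
            n_skipped += 1  # homozygous, missing or multiallelic genotype
            continue
        if phased_flag:
            alt_first = a0 == 1
            if alt_first == paternal_first:
                phase = Phase.ALT_IS_PATERNAL
            else:
                phase = Phase.ALT_IS_MATERNAL
        else:
            phase = Phase.UNPHASED
        hsnps.append(
            HetSNP(
                chrom=normalize_chrom(var.CHROM),
                pos=var.POS,
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
                phase=phase,
            )
        )
    if n_skipped:
        logger.info("read_hsnps: skipped %d non-het/non-SNV records", n_skipped)
    return hsnps


def hsnp_index(hsnps: Iterable[HetSNP]) -> dict[tuple[str, int], HetSNP]:
    """Index hSNPs by (chrom, pos)."""
    return {s.key: s for s in hsnps}


# ---------------------------------------------------------------------------
# Allele-count tables
# ---------------------------------------------------------------------------

COUNT_COLUMNS_UNPHASED = ("cell", "chrom", "pos", "n_ref", "n_alt")
COUNT_COLUMNS_PHASED = ("cell", "chrom", "pos", "n_mat", "n_pat")


def read_counts(
    tsv_path: str | Path,
    hsnps: Iterable[HetSNP],
) -> pd.DataFrame:
    """Read a per-cell allele-count TSV and join it to known hSNPs.

    The table must carry either ``(cell, chrom, pos, n_ref, n_alt)`` or
    ``(cell, chrom, pos, n_mat, n_pat)`` columns.  Rows at positions not in
    ``hsnps`` are dropped with a logged tally.  If the input is ref/alt and
    every matched site is phased, maternal/paternal columns are derived via
    :func:`resolve_phase`.

    Raises
    ------
    ValueError
        On negative counts or an unrecognized column set.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"cell": str})
    cols = set(df.columns)
    if {"n_ref", "n_alt"} <= cols:
        c1, c2 = "n_ref", "n_alt"
    elif {"n_mat", "n_pat"} <= cols:
        c1, c2 = "n_mat", "n_pat"
    else:
        raise ValueError(
            "count table must have columns (cell, chrom, pos, n_ref, n_alt) "
            "or (cell, chrom, pos, n_mat, n_pat)"
        )
    if (df[c1] < 0).any() or (df[c2] < 0).any():
        raise ValueError("negative allele counts in count table")

    df = df.copy()
    df["chrom"] = df["chrom"].astype(str).map(normalize_chrom)
    df["pos"] = df["pos"].astype(int)

    index = hsnp_index(hsnps)
    known = df.apply(lambda r: (r["chrom"], r["pos"]) in index, axis=1)
    n_skipped = int((~known).sum())
    if n_skipped:
        logger.warning(
            "read_counts: skipped %d rows at positions absent from hSNP list",
            n_skipped,
        )
    out = df[known].reset_index(drop=True)
    out.attrs["n_skipped_unknown_site"] = n_skipped
    if c1 == "n_ref":
        phases = {k: s.phase for k, s in index.items()}
        if out.apply(
            lambda r: phases[(r["chrom"], r["pos"])] is not Phase.UNPHASED, axis=1
        ).all() and len(out):
            out = resolve_phase(out, index.values())
    return out


def resolve_phase(counts: pd.DataFrame, hsnps: Iterable[HetSNP]) -> pd.DataFrame:
    """Re-express ref/alt counts as maternal/paternal using hSNP phase.

    Adds ``n_mat``/``n_pat`` columns; the ref/alt columns are kept so the
    mapping is invertible (and read totals are conserved by construction).

    Raises
    ------
    ValueError
        If any matched site is unphased.
    """
    index = hsnp_index(hsnps)

    def _resolve(row: pd.Series) -> tuple[int, int]:
        site = index[(row["chrom"], row["pos"])]
        if site.phase is Phase.ALT_IS_PATERNAL:
            return int(row["n_ref"]), int(row["n_alt"])
        if site.phase is Phase.ALT_IS_MATERNAL:
            return int(row["n_alt"]), int(row["n_ref"])
        raise ValueError(f"site {site.key} is unphased; cannot resolve phase")

    out = counts.copy()
    if len(out):
        resolved = out.apply(_resolve, axis=1, result_type="expand")
        out["n_mat"], out["n_pat"] = resolved[0], resolved[1]
    else:
        out["n_mat"] = pd.Series(dtype=int)
        out["n_pat"] = pd.Series(dtype=int)
    return out


def unresolve_phase(counts: pd.DataFrame, hsnps: Iterable[HetSNP]) -> pd.DataFrame:
    """Inverse of :func:`resolve_phase`: recover ref/alt from mat/pat."""
    index = hsnp_index(hsnps)

    def _unresolve(row: pd.Series) -> tuple[int, int]:
        site = index[(row["chrom"], row["pos"])]
        if site.phase is Phase.ALT_IS_PATERNAL:
            return int(row["n_mat"]), int(row["n_pat"])
        if site.phase is Phase.ALT_IS_MATERNAL:
            return int(row["n_pat"]), int(row["n_mat"])
        raise ValueError(f"site {site.key} is unphased")

    out = counts.copy()
    if len(out):
        resolved = out.apply(_unresolve, axis=1, result_type="expand")
        out["n_ref"], out["n_alt"] = resolved[0], resolved[1]
    return out


def write_counts(counts: pd.DataFrame, tsv_path: str | Path) -> None:
    """Write an allele-count table as a tab-separated file."""
    counts.to_csv(tsv_path, sep="\t", index=False)


def records_from_frame(
    counts: pd.DataFrame, hsnps: Iterable[HetSNP], *, phased: bool = False
) -> list[AlleleCountRecord]:
    """Materialize a count table as :class:`AlleleCountRecord` objects."""
    index = hsnp_index(hsnps)
    c1, c2 = ("n_mat", "n_pat") if phased else ("n_ref", "n_alt")
    return [
        AlleleCountRecord(
            cell_id=row.cell,
            site=index[(row.chrom, row.pos)],
            count_ref_or_mat=int(getattr(row, c1)),
            count_alt_or_pat=int(getattr(row, c2)),
            phased=phased,
        )
        for row in counts.itertuples()
    ]


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

def read_genes_bed(
    bed_path: str | Path,
    *,
    par_genes: set[str] | None = None,
    lncrna_genes: set[str] | None = None,
) -> list[GeneModel]:
    """Read gene intervals from BED6 (or BED4): chrom, start, end, name[, score, strand].

    The BED name field serves as both gene_id and symbol. PAR/lncRNA flags
    come from sidecar name sets (see :func:`read_gene_flags`).
    """
    par_genes = par_genes or set()
    lncrna_genes = lncrna_genes or set()
    genes: list[GeneModel] = []
    with open(bed_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom = normalize_chrom(fields[0])
            name = fields[3] if len(fields) > 3 else f"{chrom}:{fields[1]}-{fields[2]}"
            strand = fields[5] if len(fields) > 5 else "."
            genes.append(
                GeneModel(
                    gene_id=name,
                    symbol=name,
                    chrom=chrom,
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=strand,
                    is_par=name in par_genes,
                    is_lncRNA=name in lncrna_genes,
                )
            )
    return genes


def read_genes_gff(
    gff_path: str | Path,
    *,
    feature_type: str = "gene",
    par_genes: set[str] | None = None,
    lncrna_genes: set[str] | None = None,
) -> list[GeneModel]:
    """Read gene intervals from GFF3/GTF via :mod:`gffutils`.

    GFF coordinates are 1-based inclusive; they are converted to the 0-based
    half-open convention used internally.
    """
    import gffutils

    par_genes = par_genes or set()
    lncrna_genes = lncrna_genes or set()
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type(feature_type):
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        symbol = feat.attributes.get("gene_name", [gene_id])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                symbol=symbol,
                chrom=normalize_chrom(feat.seqid),
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand or ".",
                is_par=gene_id in par_genes or symbol in par_genes,
                is_lncRNA=gene_id in lncrna_genes or symbol in lncrna_genes,
            )
        )
    return genes


def read_gene_flags(list_path: str | Path) -> set[str]:
    """Read a one-name-per-line gene list (for PAR or lncRNA flags)."""
    with open(list_path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def write_genes_bed(genes: Sequence[GeneModel], bed_path: str | Path) -> None:
    with open(bed_path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# SNP-to-gene assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAssignment:
    """Genes overlapping one hSNP; ``ambiguous`` when more than one."""

    gene_ids: tuple[str, ...]
    ambiguous: bool


def assign_snps_to_genes(
    hsnps: Iterable[HetSNP],
    genes: Sequence[GeneModel],
) -> dict[tuple[str, int], GeneAssignment]:
    """Map each hSNP to every gene whose interval contains it.

    An hSNP inside two or more overlapping genes is assigned to all of them
    and flagged ambiguous. Sites in no gene map to the :data:`INTERGENIC`
    sentinel.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)

    result: dict[tuple[str, int], GeneAssignment] = {}
    for s in hsnps:
        tree = trees.get(s.chrom)
        hits = sorted(iv.data for iv in tree[pos_to_0based(s.pos)]) if tree else []
        if not hits:
            result[s.key] = GeneAssignment((INTERGENIC,), False)
        else:
            result[s.key] = GeneAssignment(tuple(hits), len(hits) > 1)
    return result


def annotate_counts_with_genes(
    counts: pd.DataFrame,
    assignment: Mapping[tuple[str, int], GeneAssignment],
) -> pd.DataFrame:
    """Explode a count table to one row per (record, overlapping gene).

    Adds ``gene_id`` and ``ambiguous`` columns. Read totals are conserved
    per (cell, site); a site in k genes contributes its counts to each of
    the k genes (callers may drop ambiguous rows via config).
    """
    gene_ids = []
    ambiguous = []
    keep = []
    for i, row in enumerate(counts.itertuples()):
        a = assignment.get((row.chrom, row.pos))
        if a is None:
            a = GeneAssignment((INTERGENIC,), False)
        for gid in a.gene_ids:
            keep.append(i)
            gene_ids.append(gid)
            ambiguous.append(a.ambiguous)
    out = counts.iloc[keep].reset_index(drop=True)
    out["gene_id"] = gene_ids
    out["ambiguous"] = ambiguous
    return out


# ---------------------------------------------------------------------------
# External catalogs
# ---------------------------------------------------------------------------

def read_catalog(tsv_path: str | Path, *, source: str = "") -> list[CatalogEntry]:
    """Read an external escapee catalog TSV with columns (symbol, category[, source])."""
    df = pd.read_csv(tsv_path, sep="\t")
    sym_col = "symbol" if "symbol" in df.columns else "gene"
    entries = []
    for row in df.itertuples():
        entries.append(
            CatalogEntry(
                symbol=str(getattr(row, sym_col)),
                category=str(row.category),
                source=str(getattr(row, "source", source) or source),
            )
        )
    return entries
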