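"""Gene-level escapee calling.

Four protocols aggregate iSNP/read evidence per gene across QC-passing
cells:

* **unphased iSNP** (primary cells, random Xi per cell): a gene is an
  escapee candidate when it accumulates multiple biallelic iSNPs —
  counted across cells and across hSNPs within a cell.
* **phased iSNP** (clonal cells, known Xi): any iSNP expressed from the
  silenced (paternal, by default) haplotype — labeled paternal or
  biallelic — is evidence of escape; a single supporting iSNP suffices
  but is flagged evidence-poor.
* **phased read-based**: reads are accumulated per gene over all cells
  and hSNPs; a minimal number of paternal reads calls the gene an escapee.
* **pooled**: a bulk pool of cells; the gene-level paternal allelic ratio
  above a cutoff calls an escapee.

The reported phased call set defaults to the intersection of the phased
iSNP and read-based protocols (the conservative list); the union is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .labeling import BIALLELIC, MATERNAL, MONO_ALT, PATERNAL, Thresholds
from .types import Consistency, GeneCall, GeneModel, Status


@dataclass(frozen=True)
class CallConfig:
    """Thresholds for the gene-level protocols.

    min_biallelic_isnps : the "multiple biallelic iSNPs" rule of the
        unphased protocol (default 2).
    read_min : minimal paternal reads per gene for the read-based protocol
        (default 7).
    poor_isnp_cut : unphased evidence-poor when a gene has fewer iSNPs than
        this (default 10), or support from at most one cell.
    poor_read_cut : phased evidence-poor when paternal reads are below this
        (default 50) with only one supporting cell.
    pooled_ar_cut : paternal AR above which a pooled gene is an escapee
        (default 0.1).
    strict_min_cells : cells with supporting evidence required in strict
        mode (default 2).
    exclude_ambiguous : drop iSNPs that fall in overlapping genes.
    """

    min_biallelic_isnps: int = 2
    read_min: int = 7
    poor_isnp_cut: int = 10
    poor_read_cut: int = 50
    pooled_ar_cut: float = 0.1
    strict_min_cells: int = 2
    exclude_ambiguous: bool = False

    def __post_init__(self) -> None:
        for name in ("min_biallelic_isnps", "read_min", "poor_isnp_cut",
                     "poor_read_cut", "strict_min_cells"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.pooled_ar_cut < 1:
            raise ValueError("pooled_ar_cut must be in (0, 1)")


def _prep(labels: pd.DataFrame, cfg: CallConfig) -> pd.DataFrame:
    if cfg.exclude_ambiguous and "ambiguous" in labels.columns:
        return labels[~labels["ambiguous"].astype(bool)]
    return labels


# ---------------------------------------------------------------------------
# Unphased protocol (primary cells)
# ---------------------------------------------------------------------------

def call_gene_unphased(
    gene_labels: pd.DataFrame,
    cfg: CallConfig = CallConfig(),
    *,
    gene_id: str = "",
    strict: bool = False,
) -> GeneCall:
    """Call one gene from its unphased iSNP labels.

    Escapee iff the gene has at least ``cfg.min_biallelic_isnps`` biallelic
    iSNPs, aggregated across cells and across hSNPs within a cell; in
    strict mode the biallelic evidence must additionally come from at least
    ``cfg.strict_min_cells`` distinct cells. A gene with iSNPs but too few
    biallelic ones is inactivated; with no iSNPs at all, not expressed.
    """
    call = GeneCall(gene_id=gene_id, protocol="unphased_isnp")
    if gene_labels.empty:
        return call
    bi = gene_labels["label"] == BIALLELIC
    call.n_hsnps = gene_labels["pos"].nunique()
    call.n_isnps = len(gene_labels)
    call.n_biallelic_isnps = int(bi.sum())
    call.n_support_isnps = call.n_biallelic_isnps
    call.n_cells_any = gene_labels["cell"].nunique()
    support_cells = gene_labels.loc[bi, "cell"].unique()
    call.n_cells_support = len(support_cells)
    call.support_cells = tuple(sorted(support_cells))
    call.isnp_ratio = call.n_biallelic_isnps / call.n_isnps
    is_escapee = call.n_biallelic_isnps >= cfg.min_biallelic_isnps
    if strict:
        is_escapee = is_escapee and call.n_cells_support >= cfg.strict_min_cells
    call.status = Status.ESCAPEE if is_escapee else Status.INACTIVATED
    call.evidence_poor = call.n_isnps < cfg.poor_isnp_cut or call.n_cells_support <= 1
    return call


# ---------------------------------------------------------------------------
# Phased protocols (clonal cells)
# ---------------------------------------------------------------------------

def _require_phased(labels: pd.DataFrame) -> None:
    bad = set(labels["label"]) - {MATERNAL, PATERNAL, BIALLELIC}
    if bad:
        raise ValueError(
            f"phased protocol received unphased labels {sorted(bad)}; "
            "label counts with phased=True"
        )


def consistency_check(gene_labels: pd.DataFrame) -> Consistency:
    """Within-cell parental consistency of a gene's phased iSNPs.

    Only (gene, cell) pairs with >= 2 iSNPs at >= 2 distinct sites are
    testable. A pair is inconsistent when the same cell carries both a
    maternal-monoallelic and a paternal-monoallelic iSNP in the gene —
    a single haplotype cannot be transcribed in two opposite monoallelic
    states, so such a pattern indicates unreliable assignment. A gene with
    an inconsistent pair is fully inconsistent when it has no biallelic
    iSNP anywhere, partially inconsistent when biallelic observations
    coexist.
    """
    _require_phased(gene_labels)
    testable = False
    inconsistent = False
    for _, cell_df in gene_labels.groupby("cell"):
        if len(cell_df) < 2 or cell_df["pos"].nunique() < 2:
            continue
        testable = True
        labs = set(cell_df["label"])
        if MATERNAL in labs and PATERNAL in labs:
            inconsistent = True
    if not testable:
        return Consistency.NOT_TESTABLE
    if not inconsistent:
        return Consistency.CONSISTENT
    has_biallelic = bool((gene_labels["label"] == BIALLELIC).any())
    return (
        Consistency.PARTIALLY_INCONSISTENT if has_biallelic else Consistency.FULLY_INCONSISTENT
    )


def call_gene_phased_isnp(
    gene_labels: pd.DataFrame,
    cfg: CallConfig = CallConfig(),
    *,
    gene_id: str = "",
    strict: bool = False,
) -> GeneCall:
    """Call one gene from its phased iSNP labels.

    Supporting iSNPs are those labeled paternal or biallelic (expression
    from the silenced haplotype). One supporting iSNP suffices for an
    escapee call; the evidence-poor flag marks calls with a within-cell
    consistency failure, or with fewer than ``cfg.poor_read_cut`` paternal
    reads supported by only one cell.
    """
    call = GeneCall(gene_id=gene_id, protocol="phased_isnp")
    if gene_labels.empty:
        return call
    _require_phased(gene_labels)
    support = gene_labels["label"].isin([PATERNAL, BIALLELIC])
    call.n_hsnps = gene_labels["pos"].nunique()
    call.n_isnps = len(gene_labels)
    call.n_paternal_isnps = int((gene_labels["label"] == PATERNAL).sum())
    call.n_biallelic_isnps = int((gene_labels["label"] == BIALLELIC).sum())
    call.n_support_isnps = int(support.sum())
    call.n_cells_any = gene_labels["cell"].nunique()
    support_cells = gene_labels.loc[support, "cell"].unique()
    call.n_cells_support = len(support_cells)
    call.support_cells = tuple(sorted(support_cells))
    call.isnp_ratio = call.n_support_isnps / call.n_isnps
    call.total_reads = int(gene_labels["total"].sum())
    call.paternal_reads = int(gene_labels["n2"].sum())
    if call.total_reads:
        call.paternal_ratio = call.paternal_reads / call.total_reads
    call.consistency = consistency_check(gene_labels)
    is_escapee = call.n_support_isnps >= 1
    if strict:
        is_escapee = is_escapee and call.n_cells_support >= cfg.strict_min_cells
    call.status = Status.ESCAPEE if is_escapee else Status.INACTIVATED
    call.evidence_poor = call.consistency in (
        Consistency.FULLY_INCONSISTENT,
        Consistency.PARTIALLY_INCONSISTENT,
    ) or (call.paternal_reads < cfg.poor_read_cut and call.n_cells_support <= 1)
    return call


def call_gene_phased_reads(
    gene_counts: pd.DataFrame,
    cfg: CallConfig = CallConfig(),
    *,
    gene_id: str = "",
) -> GeneCall:
    """Call one gene by accumulating phased reads across cells and hSNPs.

    ``gene_counts`` needs ``n_mat``/``n_pat`` columns (one row per cell x
    site). Escapee iff the summed paternal reads reach ``cfg.read_min``.
    """
    call = GeneCall(gene_id=gene_id, protocol="phased_reads")
    if gene_counts.empty:
        return call
    if "n_pat" not in gene_counts.columns:
        raise ValueError("phased read-based protocol requires n_mat/n_pat columns")
    call.n_hsnps = gene_counts["pos"].nunique()
    call.paternal_reads = int(gene_counts["n_pat"].sum())
    call.total_reads = call.paternal_reads + int(gene_counts["n_mat"].sum())
    if call.total_reads == 0:
        return call
    call.paternal_ratio = call.paternal_reads / call.total_reads
    if "cell" in gene_counts.columns:
        call.n_cells_any = gene_counts["cell"].nunique()
        support_cells = gene_counts.loc[gene_counts["n_pat"] > 0, "cell"].unique()
        call.n_cells_support = len(support_cells)
        call.support_cells = tuple(sorted(support_cells))
    call.status = (
        Status.ESCAPEE if call.paternal_reads >= cfg.read_min else Status.INACTIVATED
    )
    call.evidence_poor = (
        call.paternal_reads < cfg.poor_read_cut and call.n_cells_support <= 1
    )
    return call


def call_gene_pooled(
    gene_counts: pd.DataFrame,
    cfg: CallConfig = CallConfig(),
    th: Thresholds = Thresholds(),
    *,
    gene_id: str = "",
) -> GeneCall:
    """Call one gene from a pooled (bulk) library with no cell dimension.

    Paternal and maternal reads are summed over the gene's hSNPs; the gene
    is an escapee iff its paternal allelic ratio exceeds
    ``cfg.pooled_ar_cut`` and the total is at least ``th.min_reads``.
    """
    call = GeneCall(gene_id=gene_id, protocol="pooled")
    if gene_counts.empty:
        return call
    if "n_pat" not in gene_counts.columns:
        raise ValueError("pooled protocol requires n_mat/n_pat columns")
    call.n_hsnps = gene_counts["pos"].nunique()
    call.paternal_reads = int(gene_counts["n_pat"].sum())
    call.total_reads = call.paternal_reads + int(gene_counts["n_mat"].sum())
    if call.total_reads == 0:
        return call
    call.paternal_ratio = call.paternal_reads / call.total_reads
    is_escapee = (
        call.paternal_ratio > cfg.pooled_ar_cut and call.total_reads >= th.min_reads
    )
    call.status = Status.ESCAPEE if is_escapee else Status.INACTIVATED
    return call


# ---------------------------------------------------------------------------
# Whole-table drivers and protocol combination
# ---------------------------------------------------------------------------

def _group_by_gene(table: pd.DataFrame) -> Iterable[tuple[str, pd.DataFrame]]:
    from .io import INTERGENIC

    if "gene_id" not in table.columns:
        raise ValueError("table lacks a gene_id column; run gene assignment first")
    for gid, df in table.groupby("gene_id", sort=True):
        if gid == INTERGENIC:
            continue
        yield str(gid), df


def call_genes(
    table: pd.DataFrame,
    protocol: str,
    cfg: CallConfig = CallConfig(),
    th: Thresholds = Thresholds(),
    *,
    strict: bool = False,
) -> dict[str, GeneCall]:
    """Run one protocol over every gene in an iSNP-label or count table.

    ``protocol`` is one of ``unphased_isnp``, ``phased_isnp``,
    ``phased_reads``, ``pooled``. Intergenic rows are ignored; ambiguous
    rows are dropped when ``cfg.exclude_ambiguous``.
    """
    table = _prep(table, cfg)
    calls: dict[str, GeneCall] = {}
    for gid, df in _group_by_gene(table):
        if protocol == "unphased_isnp":
            calls[gid] = call_gene_unphased(df, cfg, gene_id=gid, strict=strict)
        elif protocol == "phased_isnp":
            calls[gid] = call_gene_phased_isnp(df, cfg, gene_id=gid, strict=strict)
        elif protocol == "phased_reads":
            calls[gid] = call_gene_phased_reads(df, cfg, gene_id=gid)
        elif protocol == "pooled":
            calls[gid] = call_gene_pooled(df, cfg, th, gene_id=gid)
        else:
            raise ValueError(f"unknown protocol {protocol!r}")
    return calls


def combine_phased_calls(
    isnp_calls: Mapping[str, GeneCall],
    read_calls: Mapping[str, GeneCall],
    *,
    mode: str = "intersection",
) -> dict[str, GeneCall]:
    """Combine the phased iSNP and read-based escapee sets.

    ``intersection`` (default) keeps genes called escapee by both
    protocols — the conservative reported list; ``union`` keeps genes
    called by either. The returned calls are the iSNP-protocol calls
    enriched with the read-protocol read totals, demoted to inactivated
    where the combination rule rejects the gene.
    """
    if mode not in ("intersection", "union"):
        raise ValueError("mode must be 'intersection' or 'union'")
    esc_isnp = {g for g, c in isnp_calls.items() if c.status is Status.ESCAPEE}
    esc_read = {g for g, c in read_calls.items() if c.status is Status.ESCAPEE}
    kept = esc_isnp & esc_read if mode == "intersection" else esc_isnp | esc_read
    out: dict[str, GeneCall] = {}
    for gid in set(isnp_calls) | set(read_calls):
        base = isnp_calls.get(gid) or read_calls[gid]
        call = GeneCall(**{**base.__dict__})
        rc = read_calls.get(gid)
        if rc is not None:
            call.total_reads = rc.total_reads
            call.paternal_reads = rc.paternal_reads
            call.paternal_ratio = rc.paternal_ratio
        if call.status is not Status.NOT_EXPRESSED:
            call.status = Status.ESCAPEE if gid in kept else Status.INACTIVATED
        call.protocol = f"phased_{mode}"
        out[gid] = call
    return out


# ---------------------------------------------------------------------------
# Bookkeeping metrics
# ---------------------------------------------------------------------------

def par_detection_rates(
    calls: Mapping[str, GeneCall],
    genes: Sequence[GeneModel],
) -> dict[str, float]:
    """Escapee detection rate over expressed pseudoautosomal genes.

    PAR genes are expressed from both alleles by construction, so every
    expressed PAR gene should be called an escapee; the miss fraction
    estimates the protocol's false-negative rate.

    Returns ``{n_expressed_par, n_detected_par, detection_rate,
    false_negative_rate}``.

    Raises
    ------
    ValueError
        If no PAR gene has expression evidence (rates undefined).
    """
    par_ids = {g.gene_id for g in genes if g.is_par}
    expressed = [
        gid
        for gid, c in calls.items()
        if gid in par_ids and c.status is not Status.NOT_EXPRESSED
    ]
    if not expressed:
        raise ValueError("rate undefined: no expressed PAR genes among the calls")
    detected = [gid for gid in expressed if calls[gid].status is Status.ESCAPEE]
    rate = len(detected) / len(expressed)
    return {
        "n_expressed_par": len(expressed),
        "n_detected_par": len(detected),
        "detection_rate": rate,
        "false_negative_rate": 1.0 - rate,
    }


def escapee_fraction(calls: Mapping[str, GeneCall]) -> float:
    """Escapee genes as a fraction of all expressed genes in the call set."""
    expressed = [c for c in calls.values() if c.status is not Status.NOT_EXPRESSED]
    if not expressed:
        raise ValueError("no expressed genes")
    return sum(c.status is Status.ESCAPEE for c in expressed) / len(expressed)


def single_cell_support_report(calls: Mapping[str, GeneCall]) -> pd.DataFrame:
    """Escapee calls whose support rests on a single cell.

    Mirrors the sensitivity concern that one outlier cell can dominate the
    candidate list: the frame lists each single-cell-supported escapee and
    the cell that carries it.
    """
    rows = [
        {"gene_id": gid, "cell": c.support_cells[0] if c.support_cells else ""}
        for gid, c in sorted(calls.items())
        if c.status is Status.ESCAPEE and c.n_cells_support == 1
    ]
    return pd.DataFrame(rows, columns=["gene_id", "cell"])


def calls_to_frame(calls: Mapping[str, GeneCall]) -> pd.DataFrame:
    """Flatten calls into a report table (ratios rounded to 3 d.p.,
    round-half-even; internal objects keep full precision)."""
    rows = []
    for gid in sorted(calls):
        c = calls[gid]
        rows.append(
            {
                "gene_id": gid,
                "protocol": c.protocol,
                "status": c.status.value,
                "n_hsnps": c.n_hsnps,
                "n_isnps": c.n_isnps,
                "n_biallelic_isnps": c.n_biallelic_isnps,
                "n_paternal_isnps": c.n_paternal_isnps,
                "n_support_isnps": c.n_support_isnps,
                "n_cells_any": c.n_cells_any,
                "n_cells_support": c.n_cells_support,
                "isnp_ratio": None if c.isnp_ratio is None else round(c.isnp_ratio, 3),
                "total_reads": c.total_reads,
                "paternal_reads": c.paternal_reads,
                "paternal_ratio": (
                    None if c.paternal_ratio is None else round(c.paternal_ratio, 3)
                ),
                "evidence_poor": c.evidence_poor,
                "consistency": c.consistency.value,
            }
        )
    return pd.DataFrame(rows)
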