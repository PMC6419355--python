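"""Seedable generative model of single-cell allele-specific expression.

The generator emulates the statistical structure that makes escapee
calling from single cells hard:

* **X-inactivation** — each cell silences one X; clonal populations share
  the choice, primary populations draw it per cell (Bernoulli 1/2).
* **Escape** — escapee genes leak expression from the inactive X at a
  configurable fraction of total gene output; pseudoautosomal (PAR) genes
  and autosomal genes express both alleles symmetrically; inactivated
  X genes emit nothing from Xi.
* **Transcriptional bursting** — each allele of each gene is "on" in a
  given cell with probability ``burst_p``, independently per allele, so
  even biallelic genes often look monoallelic in any one cell.
* **Overdispersed depth** — per (cell, gene, allele) expression level is
  gamma-distributed and read counts per hSNP are Poisson around it
  (a negative-binomial mixture), giving realistic depth variation.
* **Reference-mapping bias** — each read originating from the alternative
  allele is mis-counted toward the reference with probability
  ``ref_bias``, shifting allelic ratios toward 0.
* **Doublets** — with probability ``doublet_rate`` a library merges the
  counts of two independently drawn cells; in a primary population the
  two cells may have opposite Xi, mimicking chromosome-wide escape.

All randomness flows through one :func:`numpy.random.default_rng`
generator seeded from ``SimConfig.seed``, so outputs are byte-identical
across runs with the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import GeneCall, GeneModel, HetSNP, Phase, Status

GENE_CLASSES = ("autosomal", "x_inactivated", "x_escapee", "par")

#: Gene classes whose ground truth is "expressed from both haplotypes on X".
ESCAPEE_TRUTH_CLASSES = frozenset({"x_escapee", "par"})


@dataclass(frozen=True)
class GeneSpec:
    """One simulated gene: identity, class and hSNP count."""

    gene_id: str
    gene_class: str
    n_hsnps: int = 3
    xi_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.gene_class!r}")
        if not 0 <= self.xi_fraction <= 0.5:
            raise ValueError("xi_fraction must be in [0, 0.5]")
        if self.n_hsnps < 1:
            raise ValueError("n_hsnps must be >= 1")


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the generative model.

    Defaults describe a primary-cell experiment: ~100 cells with random
    per-cell Xi choice, per-allele burst probability 0.3 (so a biallelic
    gene shows both alleles in ~18% of the cell-gene pairs where it is
    seen at all), mean depth 30 reads per expressed hSNP allele with
    gamma dispersion 2, a 5% reference-assignment bias and a 3% doublet
    rate.
    """

    n_cells: int = 100
    clonal: bool = False
    genes: tuple[GeneSpec, ...] = ()
    burst_p: float = 0.3
    depth_mean: float = 30.0
    dispersion: float = 2.0
    ref_bias: float = 0.05
    doublet_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for p, name in ((self.burst_p, "burst_p"), (self.ref_bias, "ref_bias"),
                        (self.doublet_rate, "doublet_rate")):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.depth_mean <= 0 or self.dispersion <= 0:
            raise ValueError("depth_mean and dispersion must be > 0")
        if not self.genes:
            object.__setattr__(self, "genes", default_gene_panel())


def default_gene_panel(
    n_autosomal: int = 20,
    n_x_inactivated: int = 30,
    n_x_escapee: int = 8,
    n_par: int = 4,
    n_hsnps: int = 3,
    xi_fraction: float = 0.3,
) -> tuple[GeneSpec, ...]:
    """A gene panel with roughly the composition of an expressed X panel:
    mostly inactivated genes, a modest escapee minority, a few PAR
    positive controls, and autosomal genes for comparison."""
    panel: list[GeneSpec] = []
    for i in range(n_par):
        panel.append(GeneSpec(f"PAR{i+1}", "par", n_hsnps, xi_fraction))
    for i in range(n_x_escapee):
        panel.append(GeneSpec(f"ESC{i+1}", "x_escapee", n_hsnps, xi_fraction))
    for i in range(n_x_inactivated):
        panel.append(GeneSpec(f"INA{i+1}", "x_inactivated", n_hsnps, xi_fraction))
    for i in range(n_autosomal):
        panel.append(GeneSpec(f"AUT{i+1}", "autosomal", n_hsnps, xi_fraction))
    return tuple(panel)


@dataclass
class SimResult:
    """Everything the pipeline needs, plus ground truth."""

    config: SimConfig
    genes: list[GeneModel]
    hsnps: list[HetSNP]
    counts: pd.DataFrame  # cell, chrom, pos, n_ref, n_alt, n_mat, n_pat
    truth_genes: pd.DataFrame  # gene_id, gene_class, is_escapee
    truth_cells: pd.DataFrame  # cell, xi_parent, is_doublet


# gene interval layout: 10 kb genes every 20 kb; PAR genes are placed first
# on X so they sit at the p-arm tip, as real PAR1 does.
_GENE_SPAN = 10_000
_GENE_STRIDE = 20_000


def _layout_genes(specs: Sequence[GeneSpec]) -> list[GeneModel]:
    models = []
    offsets = {"X": 0, "17": 0}
    ordered = sorted(specs, key=lambda s: (s.gene_class != "par",))
    for spec in ordered:
        chrom = "17" if spec.gene_class == "autosomal" else "X"
        start = offsets[chrom]
        offsets[chrom] += _GENE_STRIDE
        models.append(
            GeneModel(
                gene_id=spec.gene_id,
                symbol=spec.gene_id,
                chrom=chrom,
                start=start,
                end=start + _GENE_SPAN,
                strand="+",
                is_par=spec.gene_class == "par",
            )
        )
    return models


_BASES = ("A", "C", "G", "T")


def simulate(cfg: SimConfig) -> SimResult:
    """Draw a full synthetic experiment from the generative model.

    Deterministic given ``cfg`` (including its seed). For each cell x gene,
    per-allele burst indicators gate gamma-Poisson read counts at every
    hSNP; inactivated genes emit nothing from Xi, escapees emit from Xi at
    ``xi_fraction`` of gene output, reference bias re-assigns alt-origin
    reads, and doublet libraries merge two independently drawn cells.
    """
    rng = np.random.default_rng(cfg.seed)
    spec_by_id = {s.gene_id: s for s in cfg.genes}
    genes = _layout_genes(cfg.genes)

    # hSNPs: evenly spaced in each gene body, random alleles, random phase
    hsnps: list[HetSNP] = []
    site_rows: list[tuple[str, str, int, bool]] = []  # gene_id, chrom, pos, alt_is_pat
    for gm in genes:
        spec = spec_by_id[gm.gene_id]
        step = _GENE_SPAN // (spec.n_hsnps + 1)
        for j in range(spec.n_hsnps):
            pos = gm.start + (j + 1) * step + 1  # 1-based, inside [start, end)
            ref, alt = rng.choice(4, size=2, replace=False)
            alt_is_pat = bool(rng.random() < 0.5)
            hsnps.append(
                HetSNP(
                    chrom=gm.chrom,
                    pos=pos,
                    ref_allele=_BASES[ref],
                    alt_allele=_BASES[alt],
                    phase=Phase.ALT_IS_PATERNAL if alt_is_pat else Phase.ALT_IS_MATERNAL,
                )
            )
            site_rows.append((gm.gene_id, gm.chrom, pos, alt_is_pat))

    sites_by_gene: dict[str, list[tuple[str, int]]] = {}
    for gid, chrom, pos, _a in site_rows:
        sites_by_gene.setdefault(gid, []).append((chrom, pos))

    # per-cell Xi choice ("maternal"/"paternal" = the silenced haplotype)
    if cfg.clonal:
        xi = np.full(cfg.n_cells, "paternal", dtype=object)  # maternal Xa
    else:
        xi = np.where(rng.random(cfg.n_cells) < 0.5, "maternal", "paternal")

    def draw_cell(xi_parent: str) -> dict[tuple[str, int], tuple[int, int]]:
        """Counts {(chrom,pos): (n_mat, n_pat)} for one cell."""
        out: dict[tuple[str, int], tuple[int, int]] = {}
        for gm in genes:
            spec = spec_by_id[gm.gene_id]
            # relative transcription rate of each haplotype
            rate_mat, rate_pat = 1.0, 1.0
            if spec.gene_class == "x_inactivated":
                if xi_parent == "maternal":
                    rate_mat = 0.0
                else:
                    rate_pat = 0.0
            elif spec.gene_class == "x_escapee":
                leak = spec.xi_fraction / (1.0 - spec.xi_fraction)
                if xi_parent == "maternal":
                    rate_mat = leak
                else:
                    rate_pat = leak
            burst_mat = rng.random() < cfg.burst_p
            burst_pat = rng.random() < cfg.burst_p
            shape = cfg.dispersion
            lam_mat = (
                rng.gamma(shape, cfg.depth_mean * rate_mat / shape)
                if burst_mat and rate_mat > 0
                else 0.0
            )
            lam_pat = (
                rng.gamma(shape, cfg.depth_mean * rate_pat / shape)
                if burst_pat and rate_pat > 0
                else 0.0
            )
            for chrom, pos in sites_by_gene[gm.gene_id]:
                n_mat = int(rng.poisson(lam_mat)) if lam_mat > 0 else 0
                n_pat = int(rng.poisson(lam_pat)) if lam_pat > 0 else 0
                if n_mat or n_pat:
                    out[(chrom, pos)] = (n_mat, n_pat)
        return out

    alt_is_pat_by_site = {(c, p): a for _g, c, p, a in site_rows}

    records = []
    truth_cell_rows = []
    for ci in range(cfg.n_cells):
        cell_id = f"cell{ci:04d}"
        counts = draw_cell(str(xi[ci]))
        is_doublet = bool(rng.random() < cfg.doublet_rate)
        mixed_xi = False
        if is_doublet:
            partner_xi = (
                str(xi[ci])
                if cfg.clonal
                else ("maternal" if rng.random() < 0.5 else "paternal")
            )
            mixed_xi = partner_xi != str(xi[ci])
            partner = draw_cell(partner_xi)
            for key, (m, p) in partner.items():
                m0, p0 = counts.get(key, (0, 0))
                counts[key] = (m0 + m, p0 + p)
        truth_cell_rows.append(
            {
                "cell": cell_id,
                "xi_parent": str(xi[ci]),
                "is_doublet": is_doublet,
                # only doublets mixing two different inactive X's are
                # detectable by the biallelic-ratio screen
                "doublet_mixed_xi": mixed_xi,
            }
        )
        for (chrom, pos), (n_mat, n_pat) in sorted(counts.items()):
            # express as ref/alt, apply reference-assignment bias there
            if alt_is_pat_by_site[(chrom, pos)]:
                n_ref, n_alt = n_mat, n_pat
            else:
                n_ref, n_alt = n_pat, n_mat
            if cfg.ref_bias > 0 and n_alt > 0:
                flipped = int(rng.binomial(n_alt, cfg.ref_bias))
                n_alt -= flipped
                n_ref += flipped
            # re-derive mat/pat from the biased assignment so both framings
            # describe the same (biased) observation
            if alt_is_pat_by_site[(chrom, pos)]:
                n_mat, n_pat = n_ref, n_alt
            else:
                n_mat, n_pat = n_alt, n_ref
            records.append(
                {
                    "cell": cell_id,
                    "chrom": chrom,
                    "pos": pos,
                    "n_ref": n_ref,
                    "n_alt": n_alt,
                    "n_mat": n_mat,
                    "n_pat": n_pat,
                }
            )

    counts_df = pd.DataFrame(
        records, columns=["cell", "chrom", "pos", "n_ref", "n_alt", "n_mat", "n_pat"]
    )
    truth_genes = pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in cfg.genes],
            "gene_class": [s.gene_class for s in cfg.genes],
            "is_escapee": [s.gene_class in ESCAPEE_TRUTH_CLASSES for s in cfg.genes],
        }
    )
    return SimResult(
        config=cfg,
        genes=genes,
        hsnps=hsnps,
        counts=counts_df,
        truth_genes=truth_genes,
        truth_cells=pd.DataFrame(truth_cell_rows),
    )


def pool_counts(counts: pd.DataFrame, *, pool_id: str = "pool") -> pd.DataFrame:
    """Sum counts over cells into one pooled library.

    Emulates a bulk pool of the same cells: the stochastic single-cell
    monoallelic signal averages out while genuine allelic silencing
    remains.
    """
    agg = (
        counts.groupby(["chrom", "pos"], sort=True)[["n_ref", "n_alt", "n_mat", "n_pat"]]
        .sum()
        .reset_index()
    )
    agg.insert(0, "cell", pool_id)
    return agg


# ---------------------------------------------------------------------------
# Truth-based evaluation
# ---------------------------------------------------------------------------

def truth_eval(
    calls: Mapping[str, GeneCall],
    truth_genes: pd.DataFrame,
    *,
    chromosome_x_only: bool = True,
) -> dict[str, float]:
    """Confusion-matrix rates of a call set against simulated truth.

    Positives are genes simulated as expressed from both haplotypes on X
    (escapees and PAR genes); negatives are X-inactivated genes. Only genes
    that were called at all and showed expression enter the matrix.

    Returns ``{sensitivity, specificity, fdr, tp, fp, tn, fn}``.
    """
    truth = dict(zip(truth_genes["gene_id"], truth_genes["gene_class"]))
    shared = [g for g in calls if g in truth]
    if not shared:
        raise ValueError("calls and truth share no genes")
    tp = fp = tn = fn = 0
    for gid in shared:
        cls = truth[gid]
        if chromosome_x_only and cls == "autosomal":
            continue
        call = calls[gid]
        if call.status is Status.NOT_EXPRESSED:
            continue
        called_esc = call.status is Status.ESCAPEE
        truly_esc = cls in ESCAPEE_TRUTH_CLASSES
        if truly_esc and called_esc:
            tp += 1
        elif truly_esc:
            fn += 1
        elif called_esc:
            fp += 1
        else:
            tn += 1
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    return {
        "sensitivity": sens,
        "specificity": spec,
        "fdr": fdr,
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }


# ---------------------------------------------------------------------------
# Writers (the exact formats the readers consume)
# ---------------------------------------------------------------------------

def write_vcf(
    hsnps: Sequence[HetSNP], path: str | Path, *, sample: str = "SIM"
) -> None:
    """Write the simulated hSNPs as a minimal phased VCF 4.2 file.

    All sites are heterozygous; phased sites are written as ``1|0``/``0|1``
    under the first-column-is-paternal convention, unphased as ``0/1``.
    """
    chroms = sorted({s.chrom for s in hsnps})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for s in sorted(hsnps, key=lambda s: (s.chrom, s.pos)):
            if s.phase is Phase.ALT_IS_PATERNAL:
                gt = "1|0"
            elif s.phase is Phase.ALT_IS_MATERNAL:
                gt = "0|1"
            else:
                gt = "0/1"
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref_allele}\t{s.alt_allele}\t.\tPASS\t.\tGT\t{gt}\n"
            )


def write_truth(result: SimResult, genes_path: str | Path, cells_path: str | Path) -> None:
    result.truth_genes.to_csv(genes_path, sep="\t", index=False)
    result.truth_cells.to_csv(cells_path, sep="\t", index=False)
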