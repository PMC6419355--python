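"""Core domain types for allele-specific expression analysis of X-inactivation.

The unit of observation is a read count pair at a heterozygous SNP (hSNP) in
one cell.  Downstream objects (iSNP labels, gene-level calls) are built from
these records by the :mod:`xescape.labeling` and :mod:`xescape.calling`
modules.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Phase(enum.Enum):
    """Parental phase of the ALT allele at a heterozygous site.

    ``UNPHASED`` means the VCF genotype was ``0/1``-style; the other two
    values record which haplotype column of a phased ``0|1``/``1|0`` genotype
    carried the ALT allele, interpreted under the configured haplotype
    convention (by default the first column is paternal).
    """

    UNPHASED = "unphased"
    ALT_IS_PATERNAL = "alt_is_paternal"
    ALT_IS_MATERNAL = "alt_is_maternal"


@dataclass(frozen=True)
class HetSNP:
    """A biallelic heterozygous SNV, optionally phased.

    Positions are 1-based (VCF convention). Chromosome names are stored
    normalized (no ``chr`` prefix), so ``chrX`` and ``X`` compare equal.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    phase: Phase = Phase.UNPHASED

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class AlleleCountRecord:
    """Read counts for the two alleles of one hSNP in one cell.

    In unphased mode the two counts are (ref, alt); once phase is resolved
    they are (maternal, paternal). ``phased`` records which interpretation
    applies. The mapping between the two framings is an involution handled
    by :func:`xescape.io.resolve_phase`.
    """

    cell_id: str
    site: HetSNP
    count_ref_or_mat: int
    count_alt_or_pat: int
    phased: bool = False

    def __post_init__(self) -> None:
        if self.count_ref_or_mat < 0 or self.count_alt_or_pat < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def total(self) -> int:
        return self.count_ref_or_mat + self.count_alt_or_pat


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with the annotation flags the pipeline needs.

    ``start``/``end`` are 0-based half-open (BED convention). ``is_par``
    marks pseudoautosomal genes, which are expected to show biallelic
    expression and serve as positive controls for escapee detection.
    """

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    is_par: bool = False
    is_lncRNA: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.is_par and self.chrom != "X":
            raise ValueError(f"gene {self.gene_id}: PAR flag requires chromosome X")

    def contains(self, pos_1based: int) -> bool:
        """Whether a 1-based position falls inside the 0-based half-open interval."""
        return self.start <= pos_1based - 1 < self.end


#: The closed nine-category vocabulary used by the literature-based ChrX catalog.
CATALOG_CATEGORIES = frozenset(
    {
        "PAR",
        "escapee",
        "mostly-escapee",
        "variable-escapee",
        "mostly-variable-escapee",
        "discordant",
        "inactivated",
        "mostly-inactivated",
        "no-data",
    }
)

#: Categories counted as escapee-associated when compiling the benchmark set.
ESCAPEE_ASSOCIATED_CATEGORIES = frozenset(
    {
        "PAR",
        "escapee",
        "mostly-escapee",
        "variable-escapee",
        "mostly-variable-escapee",
        "discordant",
    }
)


@dataclass(frozen=True)
class CatalogEntry:
    """One gene's annotation in an external escapee catalog."""

    symbol: str
    category: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATALOG_CATEGORIES:
            raise ValueError(
                f"unknown catalog category {self.category!r}; "
                f"expected one of {sorted(CATALOG_CATEGORIES)}"
            )

    @property
    def escapee_associated(self) -> bool:
        return self.category in ESCAPEE_ASSOCIATED_CATEGORIES


class Status(enum.Enum):
    """Gene-level call outcome."""

    ESCAPEE = "escapee"
    INACTIVATED = "inactivated"
    NOT_EXPRESSED = "not_expressed"


class Consistency(enum.Enum):
    """Within-cell agreement of iSNP labels along a gene (phased mode).

    A (gene, cell) pair is inconsistent when the same cell shows strictly
    maternal-monoallelic expression at one hSNP and strictly
    paternal-monoallelic at another hSNP of the same gene.
    """

    CONSISTENT = "consistent"
    PARTIALLY_INCONSISTENT = "partially_inconsistent"
    FULLY_INCONSISTENT = "fully_inconsistent"
    NOT_TESTABLE = "not_testable"


@dataclass
class GeneCall:
    """Per-gene aggregation of iSNP/read evidence under one calling protocol.

    ``isnp_ratio`` is the fraction of supporting iSNPs among all iSNPs of the
    gene: biallelic iSNPs in the unphased protocol, paternal-or-biallelic
    iSNPs in the phased protocol.  ``paternal_ratio`` is the read-level
    fraction of paternal reads (phased protocols only).
    """

    gene_id: str
    protocol: str
    status: Status = Status.NOT_EXPRESSED
    n_hsnps: int = 0
    n_isnps: int = 0
    n_biallelic_isnps: int = 0
    n_paternal_isnps: int = 0
    n_support_isnps: int = 0
    n_cells_any: int = 0
    n_cells_support: int = 0
    isnp_ratio: Optional[float] = None
    total_reads: int = 0
    paternal_reads: int = 0
    paternal_ratio: Optional[float] = None
    evidence_poor: bool = False
    consistency: Consistency = Consistency.NOT_TESTABLE
    support_cells: tuple[str, ...] = field(default_factory=tuple)
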