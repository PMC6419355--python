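"""Allelic-ratio computation and informative-SNP (iSNP) labeling.

An hSNP observed in a cell with at least ``min_reads`` total reads is an
informative SNP (iSNP). Its allelic ratio is

    AR = n_alt / (n_alt + n_ref)        (unphased)
    AR = n_pat / (n_pat + n_mat)        (phased)

and its label follows the asymmetric threshold rule:

    AR <= mono_low            -> monoallelic (reference / maternal)
    AR >  mono_high           -> monoallelic (alternative / paternal)
    mono_low < AR <= mono_high -> biallelic

With the defaults (0.1, 0.9) the boundaries matter: AR exactly 0.1 is
monoallelic while AR exactly 0.9 is biallelic. Because counts are integers
the comparisons are done in exact rational arithmetic, so labels are
bit-exact and free of floating-point boundary artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import pandas as pd

# Label vocabulary
MONO_REF = "monoallelic_ref"
MONO_ALT = "monoallelic_alt"
MATERNAL = "maternal"
PATERNAL = "paternal"
BIALLELIC = "biallelic"

LEAN_PATERNAL = "paternal"
LEAN_MATERNAL = "maternal"
LEAN_BALANCED = "balanced"


@dataclass(frozen=True)
class Thresholds:
    """iSNP eligibility and monoallelic/biallelic thresholds.

    ``min_reads`` applies to the per-(cell, site) read total. The ratio
    cutoffs are stored as exact rationals (floats such as 0.1 are converted
    through their decimal string, so ``Thresholds(mono_low=0.1)`` means
    exactly 1/10).
    """

    min_reads: int = 7
    mono_low: Fraction = Fraction(1, 10)
    mono_high: Fraction = Fraction(9, 10)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mono_low", _as_fraction(self.mono_low))
        object.__setattr__(self, "mono_high", _as_fraction(self.mono_high))
        if not (0 <= self.mono_low < self.mono_high <= 1):
            raise ValueError("require 0 <= mono_low < mono_high <= 1")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")


def _as_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, float):
        return Fraction(str(x))
    return Fraction(x)


def compute_ar(count_major_axis: int, count_other: int) -> float:
    """Allelic ratio: the major-axis count over the total.

    The major axis is the alternative allele (unphased mode) or the
    paternal allele (phased mode).

    Raises
    ------
    ValueError
        If both counts are zero (no expression) or either is negative.
    """
    if count_major_axis < 0 or count_other < 0:
        raise ValueError("counts must be non-negative")
    total = count_major_axis + count_other
    if total == 0:
        raise ValueError("cannot compute allelic ratio with zero total reads")
    return count_major_axis / total


def classify_ar(count_major_axis: int, count_other: int, th: Thresholds) -> str:
    """Exact-rational three-way classification of a count pair.

    Returns one of ``"low"`` (AR <= mono_low), ``"high"`` (AR > mono_high)
    or ``"mid"`` (biallelic band).
    """
    total = count_major_axis + count_other
    ar = Fraction(count_major_axis, total)
    if ar <= th.mono_low:
        return "low"
    if ar > th.mono_high:
        return "high"
    return "mid"


@dataclass(frozen=True)
class ISNPLabel:
    """One labeled informative SNP in one cell."""

    cell_id: str
    chrom: str
    pos: int
    ar: float
    label: str
    leaning: Optional[str] = None  # phased biallelic iSNPs only


def label_isnp(
    cell_id: str,
    chrom: str,
    pos: int,
    count_major_axis: int,
    count_other: int,
    th: Thresholds = Thresholds(),
    *,
    phased: bool = False,
) -> Optional[ISNPLabel]:
    """Label one (cell, site) count pair, or return None if not informative.

    In unphased mode the major axis is the ALT allele and the labels are
    ``monoallelic_ref`` / ``monoallelic_alt`` / ``biallelic``; in phased mode
    the major axis is the paternal allele and the monoallelic labels become
    ``maternal`` / ``paternal``. Phased biallelic iSNPs additionally carry a
    leaning (paternal if AR > 0.5, maternal if AR < 0.5).
    """
    total = count_major_axis + count_other
    if total < th.min_reads:
        return None
    band = classify_ar(count_major_axis, count_other, th)
    ar = compute_ar(count_major_axis, count_other)
    if band == "low":
        label = MATERNAL if phased else MONO_REF
    elif band == "high":
        label = PATERNAL if phased else MONO_ALT
    else:
        label = BIALLELIC

    leaning = None
    if phased and label == BIALLELIC:
        frac = Fraction(count_major_axis, total)
        if frac > Fraction(1, 2):
            leaning = LEAN_PATERNAL
        elif frac < Fraction(1, 2):
            leaning = LEAN_MATERNAL
        else:
            leaning = LEAN_BALANCED
    return ISNPLabel(cell_id=cell_id, chrom=chrom, pos=pos, ar=ar, label=label, leaning=leaning)


def label_counts(
    counts: pd.DataFrame,
    th: Thresholds = Thresholds(),
    *,
    phased: bool = False,
) -> pd.DataFrame:
    """Label every informative row of an allele-count table.

    ``counts`` must carry ``n_ref``/``n_alt`` (unphased) or ``n_mat``/``n_pat``
    (phased); ``gene_id``/``ambiguous`` columns are carried through when
    present. Rows below ``min_reads`` are dropped. Returns the iSNP table
    with columns ``cell, chrom, pos, [gene_id, ambiguous,] n1, n2, total,
    ar, label, leaning`` where ``(n1, n2)`` is (ref, alt) or (mat, pat).
    """
    c_other, c_major = ("n_mat", "n_pat") if phased else ("n_ref", "n_alt")
    if c_major not in counts.columns:
        raise ValueError(
            f"count table lacks {'phased' if phased else 'unphased'} columns "
            f"({c_other}, {c_major})"
        )
    rows = []
    carry = [c for c in ("gene_id", "ambiguous") if c in counts.columns]
    for row in counts.itertuples():
        lab = label_isnp(
            row.cell,
            row.chrom,
            row.pos,
            int(getattr(row, c_major)),
            int(getattr(row, c_other)),
            th,
            phased=phased,
        )
        if lab is None:
            continue
        rec = {
            "cell": row.cell,
            "chrom": row.chrom,
            "pos": row.pos,
            "n1": int(getattr(row, c_other)),
            "n2": int(getattr(row, c_major)),
            "total": int(getattr(row, c_other)) + int(getattr(row, c_major)),
            "ar": lab.ar,
            "label": lab.label,
            "leaning": lab.leaning,
        }
        for c in carry:
            rec[c] = getattr(row, c)
        rows.append(rec)
    cols = ["cell", "chrom", "pos", *carry, "n1", "n2", "total", "ar", "label", "leaning"]
    return pd.DataFrame(rows, columns=cols)
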