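"""Distribution summaries, catalog-overlap and positional statistics.

Two distinct notions of "monoallelic" are used deliberately and named
apart:

* *label-monoallelic* — the iSNP labeling thresholds (AR <= 0.1 or
  AR > 0.9), used by the calling protocols;
* *strict-monoallelic* — AR exactly 0 or exactly 1, used by the AR
  distribution summaries, which focus their histograms on everything else.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import CatalogEntry, GeneModel


@dataclass(frozen=True)
class ARDistributionSummary:
    """AR histogram and strict-monoallelic split for one gene set."""

    gene_set: str
    n_isnps: int
    fraction_monoallelic: float
    fraction_non_monoallelic: float
    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]


def ar_distribution(
    ars: Iterable[float],
    *,
    gene_set: str = "",
    n_bins: int = 20,
) -> ARDistributionSummary:
    """Summarize an AR sample: strict-monoallelic fraction and a histogram.

    Strict-monoallelic means AR exactly 0 or exactly 1 (the histogram of
    the remaining iSNPs is where allelic imbalance is visible).

    Raises
    ------
    ValueError
        On an empty sample.
    """
    arr = np.asarray(list(ars), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty AR sample")
    mono = (arr == 0.0) | (arr == 1.0)
    counts, edges = np.histogram(arr, bins=n_bins, range=(0.0, 1.0))
    return ARDistributionSummary(
        gene_set=gene_set,
        n_isnps=int(arr.size),
        fraction_monoallelic=float(mono.mean()),
        fraction_non_monoallelic=float((~mono).mean()),
        bin_edges=tuple(edges.tolist()),
        counts=tuple(int(c) for c in counts),
    )


@dataclass(frozen=True)
class OverlapTestSpec:
    """Hypergeometric overlap test layout.

    N : catalog population (genes with a label other than no-data);
    k : escapee-associated genes in the catalog;
    n : escapees identified by the protocol under test;
    x : overlap between the two lists.
    """

    N: int
    k: int
    n: int
    x: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.N and 0 <= self.n <= self.N):
            raise ValueError("require k <= N and n <= N")
        if not 0 <= self.x <= min(self.k, self.n):
            raise ValueError("require x <= min(k, n)")


def hypergeom_tail_curve(N: int, k: int, n: int, tail: str = "ge") -> np.ndarray:
    """Hypergeometric tail probabilities for every overlap x = 0..min(k, n).

    ``tail='ge'`` gives P[X >= x]; ``tail='gt'`` gives P[X > x].
    """
    if tail not in ("ge", "gt"):
        raise ValueError("tail must be 'ge' or 'gt'")
    if N == 0:  # empty population: X = 0 surely
        return np.array([1.0 if tail == "ge" else 0.0])
    xs = np.arange(min(k, n) + 1)
    shift = 1 if tail == "ge" else 0
    return np.asarray(sps.hypergeom.sf(xs - shift, N, k, n), dtype=float)


def hypergeom_overlap(spec: OverlapTestSpec, tail: str = "ge") -> float:
    """Exact hypergeometric tail probability of the observed overlap.

    ``tail='ge'`` (default) returns P[X >= x], the standard enrichment
    convention; ``tail='gt'`` returns the strict P[X > x].
    """
    return float(hypergeom_tail_curve(spec.N, spec.k, spec.n, tail)[spec.x])


def ks_positional_test(
    positions_subset: Sequence[float],
    positions_all: Sequence[float],
) -> dict[str, float]:
    """Two-sample Kolmogorov–Smirnov test of genomic position distributions.

    Tests whether a gene subset (e.g. called escapees) is positioned along
    the chromosome like the full gene population. Positions are gene start
    coordinates by convention (pass midpoints if preferred).

    Raises
    ------
    ValueError
        With fewer than 2 positions in either sample.
    """
    a = np.asarray(positions_subset, dtype=float)
    b = np.asarray(positions_all, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("KS test needs >= 2 positions per sample")
    res = sps.ks_2samp(a, b, method="asymp")
    return {"D": float(res.statistic), "p_value": float(res.pvalue)}


# ---------------------------------------------------------------------------
# Confidence partition against external catalogs
# ---------------------------------------------------------------------------

CONFIDENCE_TIERS = ("confirmed", "approved", "probable", "possible")


def escapee_associated_set(catalog: Iterable[CatalogEntry]) -> set[str]:
    """Symbols in the escapee-associated categories of a nine-category catalog."""
    return {e.symbol for e in catalog if e.escapee_associated}


def confidence_partition(
    escapees: Iterable[str],
    *,
    balaton_esc: set[str],
    tukiainen_esc: set[str],
    zhang_esc: set[str],
) -> dict[str, str]:
    """Tier each called escapee by its external support.

    confirmed — in both primary external escapee resources;
    approved  — in exactly one of the two;
    probable  — only in the third, independent resource;
    possible  — in none (no literature evidence).
    """
    tiers: dict[str, str] = {}
    for g in escapees:
        in_b, in_t = g in balaton_esc, g in tukiainen_esc
        if in_b and in_t:
            tiers[g] = "confirmed"
        elif in_b or in_t:
            tiers[g] = "approved"
        elif g in zhang_esc:
            tiers[g] = "probable"
        else:
            tiers[g] = "possible"
    return tiers


def gene_positions(
    genes: Iterable[GeneModel],
    *,
    chrom: str = "X",
    use_midpoint: bool = False,
) -> dict[str, float]:
    """Start (or midpoint) coordinate per gene on one chromosome."""
    out = {}
    for g in genes:
        if g.chrom != chrom:
            continue
        out[g.gene_id] = (g.start + g.end) / 2 if use_midpoint else float(g.start)
    return out


def monoallelic_mislabel_bound(
    frac_mat_mono: float, frac_pat_mono: float
) -> float:
    """Upper bound on false monoallelic gene labeling for an autosome.

    Under the assumption of no systematic allelic bias on an autosome,
    every gene observed as monoallelic toward either parent is a labeling
    artifact, so the two monoallelic fractions add up to a bound on the
    mislabeling likelihood.
    """
    if not (0 <= frac_mat_mono <= 1 and 0 <= frac_pat_mono <= 1):
        raise ValueError("fractions must be in [0, 1]")
    return frac_mat_mono + frac_pat_mono
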