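"""Doublet screening by chromosome-wide biallelic fraction.

A library that accidentally captured two cells with opposite inactivated
X chromosomes shows biallelic expression along the whole X. Each cell's
biallelic ratio (biallelic iSNPs / total iSNPs on the assessed chromosome)
is therefore compared against the population; cells more than ``z_cut``
standard deviations above the mean are flagged and removed from all
downstream analyses. The test is one-sided: a low biallelic ratio is
expected on X and never suspicious.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .labeling import BIALLELIC

logger = logging.getLogger(__name__)


def biallelic_ratio_per_cell(labels: pd.DataFrame, chrom: str = "X") -> pd.DataFrame:
    """Per-cell biallelic ratio over the iSNPs of one chromosome.

    Cells with zero iSNPs on ``chrom`` are absent from the result (they
    cannot be assessed); a warning tallies them.

    Returns a frame with columns ``cell, n_isnps, n_biallelic, biallelic_ratio``.
    """
    on_chrom = labels[labels["chrom"] == chrom]
    n_dropped = labels["cell"].nunique() - on_chrom["cell"].nunique()
    if n_dropped > 0:
        logger.warning(
            "biallelic_ratio_per_cell: %d cells have no iSNP on %s and are "
            "excluded from QC",
            n_dropped,
            chrom,
        )
    grouped = on_chrom.groupby("cell", sort=True)
    out = grouped.agg(
        n_isnps=("label", "size"),
        n_biallelic=("label", lambda s: int((s == BIALLELIC).sum())),
    ).reset_index()
    out["biallelic_ratio"] = out["n_biallelic"] / out["n_isnps"]
    return out


def flag_doublets(
    qc: pd.DataFrame,
    z_cut: float = 3.0,
    *,
    ddof: int = 1,
) -> pd.DataFrame:
    """Flag cells whose biallelic ratio exceeds mean + z_cut * SD.

    Mean and SD are computed in a single pass over all cells, candidates
    included (no iterative re-fitting). ``ddof=1`` gives the sample SD;
    set ``ddof=0`` for the population SD. The inequality is strict, so with
    SD = 0 only cells strictly above the mean are flagged (none, when all
    ratios are identical).

    Raises
    ------
    ValueError
        With fewer than 3 cells (the SD is meaningless).
    """
    if len(qc) < 3:
        raise ValueError("insufficient cells for outlier QC (need >= 3)")
    ratios = qc["biallelic_ratio"].to_numpy(dtype=float)
    mean = ratios.mean()
    sd = ratios.std(ddof=ddof)
    out = qc.copy()
    if sd > 0:
        out["zscore"] = (ratios - mean) / sd
    else:
        out["zscore"] = np.where(ratios > mean, np.inf, 0.0)
    out["flagged"] = out["zscore"] > z_cut
    return out


def passing_cells(qc_flagged: pd.DataFrame) -> set[str]:
    """Cells that passed the doublet screen."""
    return set(qc_flagged.loc[~qc_flagged["flagged"], "cell"])
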