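"""Shared fixtures: tiny hand-written inputs plus one simulated dataset."""

from __future__ import annotations

import textwrap

import pandas as pd
import pytest

from xescape.simulate import SimConfig, simulate
from xescape.types import GeneModel, HetSNP, Phase

VCF_TEXT = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##contig=<ID=X>
    ##contig=<ID=17>
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
    X\t1000\t.\tA\tG\t.\tPASS\t.\tGT\t0/1
    X\t2000\t.\tC\tT\t.\tPASS\t.\tGT\t1|0
    X\t3000\t.\tG\tA\t.\tPASS\t.\tGT\t0|1
    X\t4000\t.\tT\tC\t.\tPASS\t.\tGT\t1/1
    X\t5000\t.\tA\tAT\t.\tPASS\t.\tGT\t0/1
    X\t6000\t.\tG\tC,T\t.\tPASS\t.\tGT\t1/2
    17\t500\t.\tA\tC\t.\tPASS\t.\tGT\t0/1
    """
)


@pytest.fixture()
def vcf_file(tmp_path):
    p = tmp_path / "hsnps.vcf"
    p.write_text(VCF_TEXT)
    return p


@pytest.fixture()
def hsnps():
    return [
        HetSNP("X", 1000, "A", "G", Phase.UNPHASED),
        HetSNP("X", 2000, "C", "T", Phase.ALT_IS_PATERNAL),
        HetSNP("X", 3000, "G", "A", Phase.ALT_IS_MATERNAL),
        HetSNP("17", 500, "A", "C", Phase.UNPHASED),
    ]


@pytest.fixture()
def genes():
    return [
        GeneModel("GENE_A", "GENE_A", "X", 900, 2500),
        GeneModel("GENE_B", "GENE_B", "X", 2400, 3500),
        GeneModel("PAR1G", "PAR1G", "X", 100, 300, is_par=True),
    ]


def make_counts(rows):
    """Rows of (cell, chrom, pos, n_ref, n_alt) -> count frame."""
    return pd.DataFrame(rows, columns=["cell", "chrom", "pos", "n_ref", "n_alt"])


@pytest.fixture(scope="session")
def primary_sim():
    """A primary-cell (random Xi) simulation used across tests."""
    return simulate(SimConfig(n_cells=60, clonal=False, seed=20260928, doublet_rate=0.0))


@pytest.fixture(scope="session")
def clonal_sim():
    """A clonal (fixed Xi, phased, diploid-aligned) simulation."""
    return simulate(
        SimConfig(n_cells=25, clonal=True, seed=20260928, doublet_rate=0.0, ref_bias=0.0)
    )
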