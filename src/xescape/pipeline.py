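"""End-to-end pipeline orchestration: read -> label -> QC -> call -> evaluate.

A :class:`RunConfig` bundles every stage's parameters; :func:`run_pipeline`
executes the stages in order, writes the gene-call, iSNP and QC tables plus
a statistics report and a run manifest, and returns the in-memory results.
Outputs are a pure function of (inputs, config), and on any stage failure
partial outputs are removed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .calling import (
    CallConfig,
    call_genes,
    calls_to_frame,
    combine_phased_calls,
    escapee_fraction,
    par_detection_rates,
    single_cell_support_report,
)
from .io import (
    annotate_counts_with_genes,
    assign_snps_to_genes,
    read_counts,
    read_genes_bed,
    read_gene_flags,
    read_hsnps,
)
from .labeling import Thresholds, label_counts
from .qc import biallelic_ratio_per_cell, flag_doublets, passing_cells
from .stats import ar_distribution
from .types import Status

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``mode`` selects the study design: ``unphased`` (primary cells, random
    Xi) or ``phased`` (clonal cells with a phased genome). In phased mode
    the reported calls follow ``phased_combine`` (intersection of the iSNP
    and read-based protocols by default).
    """

    mode: str = "unphased"
    vcf: Optional[str] = None
    sample: Optional[str] = None
    counts_tsv: Optional[str] = None
    genes_bed: Optional[str] = None
    par_list: Optional[str] = None
    lncrna_list: Optional[str] = None
    out_dir: str = "xescape_out"
    thresholds: Thresholds = field(default_factory=Thresholds)
    call_config: CallConfig = field(default_factory=CallConfig)
    qc_chrom: str = "X"
    z_cut: float = 3.0
    strict: bool = False
    phased_combine: str = "intersection"
    paternal_first: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        th = Thresholds(**raw.pop("thresholds", {}))
        cc = CallConfig(**raw.pop("call_config", {}))
        return cls(thresholds=th, call_config=cc, **raw)


@dataclass
class RunResult:
    labels: pd.DataFrame
    qc: pd.DataFrame
    calls_frame: pd.DataFrame
    stats: dict
    manifest: dict


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(
        {k: str(v) for k, v in cfg.__dict__.items()}, sort_keys=True
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute the full pipeline and write its five outputs.

    Writes ``isnps.tsv``, ``qc.tsv``, ``gene_calls.tsv``, ``stats.json``
    and ``manifest.json`` under ``cfg.out_dir``.

    Raises
    ------
    RuntimeError
        Wrapping any stage failure with the stage name; partial outputs
        are removed first.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "read"
        if cfg.vcf is None or cfg.counts_tsv is None or cfg.genes_bed is None:
            raise ValueError("vcf, counts_tsv and genes_bed are all required")
        hsnps = read_hsnps(cfg.vcf, cfg.sample or "SIM", paternal_first=cfg.paternal_first)
        par = read_gene_flags(cfg.par_list) if cfg.par_list else set()
        lnc = read_gene_flags(cfg.lncrna_list) if cfg.lncrna_list else set()
        genes = read_genes_bed(cfg.genes_bed, par_genes=par, lncrna_genes=lnc)
        counts = read_counts(cfg.counts_tsv, hsnps)
        logger.info("read: %d hSNPs, %d genes, %d count rows", len(hsnps), len(genes), len(counts))

        stage = "assign"
        assignment = assign_snps_to_genes(hsnps, genes)
        counts = annotate_counts_with_genes(counts, assignment)

        stage = "label"
        phased = cfg.mode == "phased"
        labels = label_counts(counts, cfg.thresholds, phased=phased)
        logger.info("label: %d iSNPs kept of %d count rows", len(labels), len(counts))

        stage = "qc"
        qc = biallelic_ratio_per_cell(labels, chrom=cfg.qc_chrom)
        qc = flag_doublets(qc, z_cut=cfg.z_cut)
        keep = passing_cells(qc)
        n_flagged = int(qc["flagged"].sum())
        logger.info("qc: %d cells flagged as suspected doublets", n_flagged)
        labels = labels[labels["cell"].isin(keep)].reset_index(drop=True)
        counts = counts[counts["cell"].isin(keep)].reset_index(drop=True)

        stage = "call"
        if phased:
            isnp_calls = call_genes(labels, "phased_isnp", cfg.call_config,
                                    cfg.thresholds, strict=cfg.strict)
            read_calls = call_genes(counts, "phased_reads", cfg.call_config, cfg.thresholds)
            calls = combine_phased_calls(isnp_calls, read_calls, mode=cfg.phased_combine)
        else:
            calls = call_genes(labels, "unphased_isnp", cfg.call_config,
                               cfg.thresholds, strict=cfg.strict)
        n_escapees = sum(c.status is Status.ESCAPEE for c in calls.values())
        logger.info("call: %d genes, %d escapee candidates", len(calls), n_escapees)

        stage = "evaluate"
        stats: dict = {
            "n_cells_flagged": n_flagged,
            "n_genes_called": len(calls),
            "n_escapees": n_escapees,
        }
        try:
            stats["escapee_fraction"] = escapee_fraction(calls)
        except ValueError:
            pass
        try:
            stats["par_rates"] = par_detection_rates(calls, genes)
        except ValueError:
            pass
        x_labels = labels[labels["chrom"] == "X"]
        if len(x_labels):
            summ = ar_distribution(x_labels["ar"], gene_set="X")
            stats["ar_distribution_X"] = {
                "n_isnps": summ.n_isnps,
                "fraction_non_monoallelic": summ.fraction_non_monoallelic,
            }
        stats["single_cell_supported_escapees"] = single_cell_support_report(
            calls
        ).to_dict(orient="records")

        stage = "write"
        calls_frame = calls_to_frame(calls)
        for name, obj in (
            ("isnps.tsv", labels),
            ("qc.tsv", qc),
            ("gene_calls.tsv", calls_frame),
        ):
            p = out_dir / name
            obj.to_csv(p, sep="\t", index=False)
            written.append(p)
        p = out_dir / "stats.json"
        p.write_text(json.dumps(stats, indent=2, sort_keys=True) + "\n")
        written.append(p)
        manifest = {
            "version": __version__,
            "config_hash": _config_hash(cfg),
            "mode": cfg.mode,
            "seed": cfg.seed,
            "n_hsnps": len(hsnps),
            "n_genes": len(genes),
            "n_cells_flagged": n_flagged,
        }
        p = out_dir / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(p)
        return RunResult(labels=labels, qc=qc, calls_frame=calls_frame,
                         stats=stats, manifest=manifest)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
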