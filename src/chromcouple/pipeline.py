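"""End-to-end orchestration of the two-population comparison.

Stage order: the expression and accessibility branches are independent;
coupling consumes both; motif enrichment consumes the accessibility
branch.  All thresholds live in :class:`PipelineConfig` and are echoed
verbatim into the summary report, together with a consistency audit that
recomputes every reported count from the stage output tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accessibility as atac
from . import coupling as cpl
from . import expression as expr
from . import motifs as mot
from .formats import (
    read_counts,
    read_fasta,
    read_gene_table,
    read_narrowpeak,
    read_pfm,
    write_narrowpeak,
)

logger = logging.getLogger("chromcouple")

__all__ = ["PipelineConfig", "SummaryReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Input paths, analysis thresholds and the pipeline seed.

    The defaults are the analysis constants of the study design this
    pipeline models: differential accessibility kept at FDR 10%,
    differential expression called at adjusted p < 0.05 (with a stricter
    |log2FC| >= 1 & FDR <= 0.01 volcano set), coupling at FDR < 0.1 in
    both assays, peak-to-gene annotation within +/-150 kb of the summit,
    400-bp summit windows against 20,000 random 400-bp background
    windows, order-3 motif combinations within 500 bp, and a detection
    threshold at the 95th percentile of 5-kb intergenic windows.
    """

    dataset_dir: str = "."
    output_dir: str = "results"
    da_fdr: float = 0.10
    da_min_abs_log2fc: float = 0.0
    de_adj_p: float = 0.05
    de_volcano_log2fc: float = 1.0
    de_volcano_fdr: float = 0.01
    coupling_fdr: float = 0.1
    annotation_window: int = 150_000
    tss_margin: int = 1_000
    summit_flank: int = 200
    background_n: int = 20_000
    background_len: int = 400
    combination_order: int = 3
    combination_span: int = 500
    scan_threshold_fraction: float = 0.8
    detection_percentile: float = 95.0
    intergenic_window: int = 5_000
    min_support: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.da_fdr < 1 or not 0 < self.coupling_fdr < 1:
            raise ValueError("FDR thresholds must be in (0, 1)")
        if not 0 < self.detection_percentile <= 100:
            raise ValueError("detection_percentile must be in (0, 100]")
        if self.combination_order < 2:
            raise ValueError("combination_order must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class SummaryReport:
    """Machine-readable pipeline summary."""

    gene_partition: dict[str, int]
    detection_threshold: float
    peak_class_counts: dict[str, int]
    peak_class_fractions: dict[str, float]
    n_da_significant: int
    n_de_adj_p: int
    n_de_volcano: int
    coupling_counts: dict[str, int]
    tss_overrepresentation: dict[str, float]
    top_combinations: list[dict]
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _replicate_paths(dataset: Path, pop: str) -> list[Path]:
    paths = sorted(dataset.glob(f"{pop}_rep*.narrowPeak"))
    if not paths:
        raise FileNotFoundError(
            f"no {pop}_rep*.narrowPeak files under {dataset}"
        )
    return paths


def _validate_inputs(dataset: Path) -> None:
    required = [
        "genome.fa", "genes.tsv", "gene_counts.tsv", "peak_counts.tsv",
        "intergenic_counts.tsv", "motifs.pfm",
    ]
    missing = [f for f in required if not (dataset / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"missing input files under {dataset}: {missing}"
        )


def run_pipeline(config: PipelineConfig) -> SummaryReport:
    """Run all stages and write the stage outputs plus summary.json."""
    t0 = time.time()
    dataset = Path(config.dataset_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _validate_inputs(dataset)

    # ---- expression branch ------------------------------------------------
    logger.info("expression: normalization and differential expression")
    gene_counts = read_counts(dataset / "gene_counts.tsv")
    gene_counts = expr.filter_null_expression(gene_counts)
    factors = expr.size_factors_median_of_ratios(gene_counts)
    intergenic = read_counts(dataset / "intergenic_counts.tsv")
    threshold = expr.detection_threshold(
        intergenic, factors, config.detection_percentile,
        config.intergenic_window,
    )
    norm = expr.normalized_log_expression(gene_counts, factors)
    partition = expr.partition_expressed(norm, gene_counts.groups,
                                         threshold)
    de_res, de_calls = expr.differential_expression(
        gene_counts, factors,
        adj_p_threshold=config.de_adj_p,
        volcano_log2fc=config.de_volcano_log2fc,
        volcano_fdr=config.de_volcano_fdr,
    )
    de_res.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (g, "shared") for g in sorted(partition.shared)
        ]
        + [(g, "specific_A") for g in sorted(partition.specific_A)]
        + [(g, "specific_B") for g in sorted(partition.specific_B)],
        columns=["gene_id", "set"],
    ).to_csv(outdir / "partition.tsv", sep="\t", index=False)
    with open(outdir / "threshold.json", "w") as fh:
        json.dump(
            {
                "value": threshold.value,
                "percentile": threshold.percentile,
                "n_windows": threshold.n_windows,
                "window_size": threshold.window_size,
                "per_sample": threshold.per_sample,
            },
            fh, indent=2, sort_keys=True,
        )

    # ---- accessibility branch --------------------------------------------
    logger.info("accessibility: consensus, classification, affinity test")
    reps_A = [read_narrowpeak(p) for p in _replicate_paths(dataset, "A")]
    reps_B = [read_narrowpeak(p) for p in _replicate_paths(dataset, "B")]
    consensus_A = atac.merge_replicate_peaks(reps_A, config.min_support,
                                             population="A")
    consensus_B = atac.merge_replicate_peaks(reps_B, config.min_support,
                                             population="B")
    pooled, classification = atac.classify_peaks(consensus_A, consensus_B)
    for name, cons in (("A", consensus_A), ("B", consensus_B),
                       ("pooled", pooled)):
        write_narrowpeak(cons.peaks, outdir / f"consensus_{name}.narrowPeak")
    pd.DataFrame(
        sorted(classification.class_of_peak.items()),
        columns=["peak_id", "class"],
    ).to_csv(outdir / "peak_classes.tsv", sep="\t", index=False)

    peak_counts_atlas = read_counts(dataset / "peak_counts.tsv")
    peak_counts = atac.assign_counts_to_peaks(pooled, peak_counts_atlas)
    atac_factors = expr.size_factors_median_of_ratios(peak_counts)
    da_res, da_significant = atac.differential_accessibility(
        peak_counts, atac_factors,
        fdr_threshold=config.da_fdr,
        min_abs_log2fc=config.da_min_abs_log2fc,
    )
    da_res.to_csv(outdir / "da_results.tsv", sep="\t", index=False)
    da_res[["feature_id", "a_value", "log2fc", "fdr"]].rename(
        columns={"a_value": "A", "log2fc": "M"}
    ).to_csv(outdir / "ma_table.tsv", sep="\t", index=False,
             float_format="%.6g")

    genes = read_gene_table(dataset / "genes.tsv")
    annotations = atac.annotate_peaks(
        pooled, genes, window=config.annotation_window,
        tss_margin=config.tss_margin,
    )
    pd.DataFrame(
        [
            (a.peak_id, a.nearest_gene or "",
             "" if a.signed_distance is None else a.signed_distance,
             a.category)
            for a in annotations
        ],
        columns=["peak_id", "nearest_gene", "signed_distance", "category"],
    ).to_csv(outdir / "annotations.tsv", sep="\t", index=False)

    ann_by_peak = {a.peak_id: a for a in annotations}
    excl_A_ann = [
        ann_by_peak[p]
        for p, c in classification.class_of_peak.items()
        if c == "exclusive_A"
    ]
    excl_B_ann = [
        ann_by_peak[p]
        for p, c in classification.class_of_peak.items()
        if c == "exclusive_B"
    ]
    if excl_A_ann and excl_B_ann:
        odds, p_tss = atac.tss_overrepresentation(excl_A_ann, excl_B_ann)
    else:
        odds, p_tss = float("nan"), 1.0

    # ---- coupling ---------------------------------------------------------
    logger.info("coupling: joint accessibility/expression classes")
    records = cpl.couple(annotations, da_res, de_res,
                         fdr_threshold=config.coupling_fdr)
    cpl.records_table(records).to_csv(
        outdir / "coupling.tsv", sep="\t", index=False
    )
    coupling_counts = cpl.coupling_summary(records)
    with open(outdir / "coupling_summary.json", "w") as fh:
        json.dump(coupling_counts, fh, indent=2, sort_keys=True)

    # ---- motifs -----------------------------------------------------------
    logger.info("motifs: summit extraction, scanning, enrichment")
    genome = read_fasta(dataset / "genome.fa")
    pwms = read_pfm(dataset / "motifs.pfm")
    excl_A_peaks = [
        p for p in pooled.peaks
        if classification.class_of_peak[p.name] == "exclusive_A"
    ]
    summit_seqs = mot.extract_summit_sequences(
        excl_A_peaks, genome, flank=config.summit_flank
    )
    peak_seq_pairs = [(s.sequence_id, s.sequence) for s in summit_seqs]
    from .formats import write_fasta

    write_fasta(peak_seq_pairs, outdir / "summit_seqs.fa")
    background = mot.sample_background(
        genome, n=config.background_n, length=config.background_len,
        seed=config.seed,
    )
    write_fasta(background.sequences, outdir / "background.fa")
    single = mot.single_motif_enrichment(
        peak_seq_pairs, background, pwms,
        threshold_fraction=config.scan_threshold_fraction,
    )
    single.to_csv(outdir / "single_motif_enrichment.tsv", sep="\t",
                  index=False, float_format="%.6g")
    combo = mot.combination_enrichment(
        peak_seq_pairs, background, pwms,
        order=config.combination_order, span=config.combination_span,
        threshold_fraction=config.scan_threshold_fraction,
    )
    combo.to_csv(outdir / "combination_enrichment.tsv", sep="\t",
                 index=False, float_format="%.6g")

    # ---- summary + audit --------------------------------------------------
    report = SummaryReport(
        gene_partition=partition.counts(),
        detection_threshold=threshold.value,
        peak_class_counts=classification.counts(),
        peak_class_fractions=classification.fractions(),
        n_da_significant=len(da_significant),
        n_de_adj_p=len(de_calls["adj_p"]),
        n_de_volcano=len(de_calls["volcano"]),
        coupling_counts=coupling_counts,
        tss_overrepresentation={"odds_ratio": odds, "p": p_tss},
        top_combinations=[
            {
                "motif_ids": row.motif_ids,
                "k_peak": int(row.k_peak),
                "k_bg": int(row.k_bg),
                "p": float(row.p),
                "fdr": float(row.fdr),
            }
            for row in combo.head(5).itertuples()
        ],
        provenance={
            "config": asdict(config),
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "elapsed_s": round(time.time() - t0, 2),
        },
    )
    _audit(report, outdir)
    # elapsed time is provenance, not part of the audited payload; keep
    # the written summary deterministic for a fixed config and inputs
    report.provenance.pop("elapsed_s")
    with open(outdir / "summary.json", "w") as fh:
        fh.write(report.to_json())
    return report


def _audit(report: SummaryReport, outdir: Path) -> None:
    """Recompute every summary count from the written stage tables."""
    classes = pd.read_csv(outdir / "peak_classes.tsv", sep="\t")
    recount = classes["class"].value_counts().to_dict()
    for klass, n in report.peak_class_counts.items():
        if recount.get(klass, 0) != n:
            raise AssertionError(
                f"audit: peak class {klass} count mismatch "
                f"({recount.get(klass, 0)} != {n})"
            )
    partition = pd.read_csv(outdir / "partition.tsv", sep="\t")
    pcount = partition["set"].value_counts().to_dict()
    for key, n in report.gene_partition.items():
        if pcount.get(key, 0) != n:
            raise AssertionError(f"audit: partition {key} mismatch")
    da = pd.read_csv(outdir / "da_results.tsv", sep="\t")
    cfg = report.provenance["config"]
    mask = da["fdr"] <= cfg["da_fdr"]
    if cfg["da_min_abs_log2fc"] > 0:
        mask &= np.abs(da["log2fc"]) >= cfg["da_min_abs_log2fc"]
    if int(mask.sum()) != report.n_da_significant:
        raise AssertionError("audit: DA significant count mismatch")
    de = pd.read_csv(outdir / "de_results.tsv", sep="\t")
    if int((de["fdr"] < cfg["de_adj_p"]).sum()) != report.n_de_adj_p:
        raise AssertionError("audit: DE adj-p count mismatch")
    coupling = pd.read_csv(outdir / "coupling.tsv", sep="\t")
    ccount = coupling["klass"].value_counts().to_dict()
    for klass, n in report.coupling_counts.items():
        if ccount.get(klass, 0) != n:
            raise AssertionError(f"audit: coupling class {klass} mismatch")
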