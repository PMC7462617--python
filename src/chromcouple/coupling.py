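"""Joint accessibility-expression classification of pooled peaks.

Each pooled consensus peak is linked to its nearest gene (TSS within the
annotation window) and classified by the joint significance of its
differential-accessibility and differential-expression tests:

* ``concordant_A`` — both FDR below threshold, both log ratios > 0
  (more open and more expressed in population A);
* ``concordant_B`` — both significant, both log ratios < 0;
* ``discordant`` — both significant, strictly opposite signs;
* ``not_significant`` — anything else with an assigned gene (a log
  ratio of exactly zero carries no direction and lands here);
* ``unassigned`` — no gene within the annotation window.

Both log ratios follow the package-wide A-over-B orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .accessibility import PeakAnnotation

__all__ = ["CouplingRecord", "couple", "coupling_scatter_table",
           "coupling_summary"]

KLASSES = (
    "concordant_A",
    "concordant_B",
    "discordant",
    "not_significant",
    "unassigned",
)


@dataclass(frozen=True)
class CouplingRecord:
    peak_id: str
    gene_id: str | None
    atac_log_ratio: float
    rna_log_ratio: float
    atac_fdr: float
    rna_fdr: float
    klass: str


def _classify(
    atac_lr: float, rna_lr: float, atac_fdr: float, rna_fdr: float,
    threshold: float,
) -> str:
    if not (atac_fdr < threshold and rna_fdr < threshold):
        return "not_significant"
    if atac_lr > 0 and rna_lr > 0:
        return "concordant_A"
    if atac_lr < 0 and rna_lr < 0:
        return "concordant_B"
    if atac_lr * rna_lr < 0:
        return "discordant"
    return "not_significant"  # a zero ratio has no direction


def couple(
    annotations: list[PeakAnnotation],
    da: pd.DataFrame,
    de: pd.DataFrame,
    fdr_threshold: float = 0.1,
) -> list[CouplingRecord]:
    """Join per-peak accessibility and per-gene expression statistics.

    ``da`` is keyed by peak (``feature_id``), ``de`` by gene; the
    annotations provide the peak-to-nearest-gene link.  Every annotated
    peak must be present in ``da``; a peak whose gene is missing from
    ``de`` (e.g. filtered before testing) is treated as unassigned.
    """
    da_lr = dict(zip(da["feature_id"], da["log2fc"]))
    da_fdr = dict(zip(da["feature_id"], da["fdr"]))
    de_lr = dict(zip(de["feature_id"], de["log2fc"]))
    de_fdr = dict(zip(de["feature_id"], de["fdr"]))
    missing = [a.peak_id for a in annotations if a.peak_id not in da_lr]
    if missing:
        raise ValueError(
            f"{len(missing)} annotated peaks missing from the "
            f"accessibility results, e.g. {missing[:5]}"
        )
    records: list[CouplingRecord] = []
    for ann in annotations:
        atac_lr = float(da_lr[ann.peak_id])
        atac_fdr = float(da_fdr[ann.peak_id])
        if ann.nearest_gene is None or ann.nearest_gene not in de_lr:
            records.append(
                CouplingRecord(
                    ann.peak_id, None, atac_lr, float("nan"), atac_fdr,
                    float("nan"), "unassigned",
                )
            )
            continue
        rna_lr = float(de_lr[ann.nearest_gene])
        rna_fdr = float(de_fdr[ann.nearest_gene])
        records.append(
            CouplingRecord(
                ann.peak_id,
                ann.nearest_gene,
                atac_lr,
                rna_lr,
                atac_fdr,
                rna_fdr,
                _classify(atac_lr, rna_lr, atac_fdr, rna_fdr,
                          fdr_threshold),
            )
        )
    return records


def coupling_scatter_table(records: list[CouplingRecord]) -> pd.DataFrame:
    """The plotted quantities: one row per assigned peak, pass-through."""
    rows = [
        (r.peak_id, r.gene_id, r.atac_log_ratio, r.rna_log_ratio, r.klass)
        for r in records
        if r.klass != "unassigned"
    ]
    return pd.DataFrame(
        rows, columns=["peak_id", "gene_id", "x", "y", "klass"]
    )


def coupling_summary(records: list[CouplingRecord]) -> dict[str, int]:
    """Class counts; always sums to the number of records."""
    counts = {k: 0 for k in KLASSES}
    for r in records:
        counts[r.klass] += 1
    assert sum(counts.values()) == len(records)
    return counts


def records_table(records: list[CouplingRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            (r.peak_id, r.gene_id if r.gene_id is not None else "",
             r.atac_log_ratio, r.rna_log_ratio, r.atac_fdr, r.rna_fdr,
             r.klass)
            for r in records
        ],
        columns=[
            "peak_id", "gene_id", "atac_log_ratio", "rna_log_ratio",
            "atac_fdr", "rna_fdr", "klass",
        ],
    )
    return df
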