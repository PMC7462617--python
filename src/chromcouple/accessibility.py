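"""ATAC branch: consensus peaks, peak classes, differential accessibility.

Replicate peak sets are merged into population consensus sets by
single-bp interval union, with a replicate-support filter standing in for
a rank-consistency (IDR-style) reproducibility step.  The two population
consensus sets are then compared twice:

* qualitatively — every pooled consensus peak is classified shared /
  exclusive_A / exclusive_B by presence in each population's consensus;
* quantitatively — read counts in pooled peaks are tested with the same
  negative-binomial Wald engine as the expression branch ("affinity
  analysis"), significant at FDR <= 0.10 by default.

Peaks are annotated to the nearest TSS within +/-150 kb of the summit,
and a Fisher test asks whether TSS-proximal peaks are over-represented
among one population's exclusive peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .expression import SizeFactors, nb_wald_test, size_factors_median_of_ratios
from .formats import CountTable, GenomicInterval, GeneRecord, NarrowPeak

__all__ = [
    "ConsensusPeakSet",
    "PeakClassification",
    "PeakAnnotation",
    "merge_replicate_peaks",
    "classify_peaks",
    "count_reads_in_peaks",
    "assign_counts_to_peaks",
    "differential_accessibility",
    "annotate_peaks",
    "tss_overrepresentation",
]


@dataclass
class ConsensusPeakSet:
    """Merged, non-overlapping peaks with replicate support."""

    population: str  # "A", "B" or "pooled"
    peaks: list[NarrowPeak]
    support_of_peak: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev: NarrowPeak | None = None
        for p in sorted(self.peaks, key=lambda q: (q.chrom, q.start)):
            if prev is not None and prev.chrom == p.chrom and p.start < prev.end:
                raise ValueError(
                    f"consensus peaks overlap: {prev.name} and {p.name}"
                )
            prev = p


@dataclass
class PeakClassification:
    """Shared/exclusive classes over the pooled consensus peaks."""

    class_of_peak: dict[str, str]

    CLASSES = ("shared", "exclusive_A", "exclusive_B")

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in self.CLASSES}
        for c in self.class_of_peak.values():
            out[c] += 1
        return out

    def fractions(self) -> dict[str, float]:
        total = len(self.class_of_peak)
        return {c: n / total for c, n in self.counts().items()}


@dataclass
class PeakAnnotation:
    """Nearest-TSS assignment of one pooled peak.

    ``signed_distance`` is summit minus TSS, flipped on minus-strand
    genes so that negative always means upstream of the TSS in the
    gene's reading direction.
    """

    peak_id: str
    nearest_gene: str | None
    signed_distance: int | None
    category: str  # tss_proximal | genic | intergenic


# ---------------------------------------------------------------------------
# merging and classification
# ---------------------------------------------------------------------------


def _merge_intervals(
    tagged: list[tuple[str, int, int, int]],
) -> list[tuple[str, int, int, set[int]]]:
    """Single-linkage union of (chrom, start, end, tag) by >=1 bp overlap."""
    merged: list[tuple[str, int, int, set[int]]] = []
    for chrom, start, end, tag in sorted(tagged):
        if merged and merged[-1][0] == chrom and start < merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end), prev[3] | {tag})
        else:
            merged.append((chrom, start, end, {tag}))
    return merged


def merge_replicate_peaks(
    replicates: list[list[NarrowPeak]],
    min_support: int = 2,
    population: str = "pooled",
) -> ConsensusPeakSet:
    """Merge overlapping replicate peaks into a consensus set.

    A merged region is retained iff peaks from at least ``min_support``
    distinct replicates overlap it (reproducibility filter).  The merged
    summit is the region midpoint, since caller summits are lost on
    merging.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    if min_support > len(replicates):
        raise ValueError(
            f"min_support {min_support} exceeds {len(replicates)} replicates"
        )
    tagged = [
        (p.chrom, p.start, p.end, rep_i)
        for rep_i, peaks in enumerate(replicates)
        for p in peaks
    ]
    peaks: list[NarrowPeak] = []
    support: dict[str, int] = {}
    kept = 0
    for chrom, start, end, reps in _merge_intervals(tagged):
        if len(reps) < min_support:
            continue
        kept += 1
        name = f"{population}_{kept:06d}"
        iv = GenomicInterval(chrom, start, end)
        peaks.append(
            NarrowPeak(iv, name=name, summit_offset=(end - start) // 2)
        )
        support[name] = len(reps)
    return ConsensusPeakSet(population, peaks, support)


def _overlap_any(peak: NarrowPeak, tree_by_chrom: dict[str, IntervalTree]) -> bool:
    tree = tree_by_chrom.get(peak.chrom)
    return bool(tree and tree.overlap(peak.start, peak.end))


def _build_trees(peaks: list[NarrowPeak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    return trees


def classify_peaks(
    consensus_A: ConsensusPeakSet,
    consensus_B: ConsensusPeakSet,
) -> tuple[ConsensusPeakSet, PeakClassification]:
    """Pool the two consensus sets and classify every pooled peak.

    The pooled set is the interval union of both populations' consensus
    peaks; a pooled peak is ``shared`` when overlapped by peaks from both
    populations and ``exclusive_*`` otherwise.  Returns the pooled set
    and the classification; class counts always sum to the pooled total.
    """
    if not consensus_A.peaks and not consensus_B.peaks:
        raise ValueError("both consensus sets are empty")
    tagged = [(p.chrom, p.start, p.end, 0) for p in consensus_A.peaks] + [
        (p.chrom, p.start, p.end, 1) for p in consensus_B.peaks
    ]
    pooled_peaks: list[NarrowPeak] = []
    classes: dict[str, str] = {}
    support: dict[str, int] = {}
    for i, (chrom, start, end, pops) in enumerate(_merge_intervals(tagged), 1):
        name = f"pooled_{i:06d}"
        iv = GenomicInterval(chrom, start, end)
        pooled_peaks.append(
            NarrowPeak(iv, name=name, summit_offset=(end - start) // 2)
        )
        if pops == {0, 1}:
            classes[name] = "shared"
        elif pops == {0}:
            classes[name] = "exclusive_A"
        else:
            classes[name] = "exclusive_B"
        support[name] = len(pops)
    pooled = ConsensusPeakSet("pooled", pooled_peaks, support)
    cls = PeakClassification(classes)
    assert sum(cls.counts().values()) == len(pooled_peaks)
    return pooled, cls


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------


def count_reads_in_peaks(
    pooled: ConsensusPeakSet,
    fragments_per_sample: dict[str, list[GenomicInterval]],
    groups: dict[str, str],
) -> CountTable:
    """Count fragment midpoints falling inside each pooled peak.

    Midpoint assignment avoids double counting a fragment spanning two
    peaks.  Fragments on chromosomes absent from the peak set are skipped
    with a warning count in the returned table's attrs.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom in {p.chrom for p in pooled.peaks}:
        ps = sorted(
            (p for p in pooled.peaks if p.chrom == chrom),
            key=lambda p: p.start,
        )
        by_chrom[chrom] = (
            np.array([p.start for p in ps]),
            np.array([p.end for p in ps]),
            [p.name for p in ps],
        )
    names = [p.name for p in pooled.peaks]
    counts = pd.DataFrame(
        0, index=names, columns=list(fragments_per_sample), dtype=np.int64
    )
    skipped = 0
    for sample, frags in fragments_per_sample.items():
        for frag in frags:
            entry = by_chrom.get(frag.chrom)
            if entry is None:
                skipped += 1
                continue
            starts, ends, peak_names = entry
            mid = frag.midpoint
            j = int(np.searchsorted(starts, mid, side="right")) - 1
            if j >= 0 and mid < ends[j]:
                counts.at[peak_names[j], sample] += 1
    if skipped:
        import warnings

        warnings.warn(f"skipped {skipped} fragments on unknown chromosomes")
    table = CountTable(counts, dict(groups))
    table.counts.attrs["skipped_fragments"] = skipped
    return table


def _parse_locus_id(feature_id: str) -> tuple[str, int, int] | None:
    """Parse a 'chrom:start-end' count-feature id; None if not positional."""
    try:
        chrom, span = feature_id.rsplit(":", 1)
        start, end = span.split("-")
        return chrom, int(start), int(end)
    except ValueError:
        return None


def assign_counts_to_peaks(
    pooled: ConsensusPeakSet, peak_counts: CountTable
) -> CountTable:
    """Re-key a positional count table onto pooled consensus peaks.

    Quantification upstream happens on a fixed peak atlas whose feature
    ids encode coordinates (``chrom:start-end``).  Each pooled peak
    inherits the summed counts of all atlas features it overlaps; pooled
    peaks overlapping no feature get zero counts.
    """
    trees: dict[str, IntervalTree] = {}
    for i, fid in enumerate(peak_counts.feature_ids):
        parsed = _parse_locus_id(fid)
        if parsed is None:
            raise ValueError(
                f"count feature id {fid!r} is not positional (chrom:start-end)"
            )
        chrom, start, end = parsed
        trees.setdefault(chrom, IntervalTree()).addi(start, end, i)
    mat = peak_counts.counts.to_numpy()
    out = np.zeros((len(pooled.peaks), mat.shape[1]), dtype=np.int64)
    for row, peak in enumerate(pooled.peaks):
        tree = trees.get(peak.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(peak.start, peak.end):
            out[row] += mat[hit.data]
    df = pd.DataFrame(
        out,
        index=[p.name for p in pooled.peaks],
        columns=peak_counts.sample_ids,
    )
    return CountTable(df, dict(peak_counts.groups))


# ---------------------------------------------------------------------------
# differential accessibility
# ---------------------------------------------------------------------------


def differential_accessibility(
    peak_counts: CountTable,
    factors: SizeFactors | None = None,
    fdr_threshold: float = 0.10,
    min_abs_log2fc: float = 0.0,
) -> tuple[pd.DataFrame, list[str]]:
    """NB Wald affinity analysis of peak counts, A versus B.

    Returns the per-peak table with MA columns (``log2fc`` is M; ``a_value``
    is the mean log2 normalized count) and the list of significant peaks
    at ``fdr <= fdr_threshold`` (optionally also ``|log2fc| >=
    min_abs_log2fc``).
    """
    if factors is None:
        factors = size_factors_median_of_ratios(peak_counts)
    res = nb_wald_test(peak_counts, factors)
    sf = factors.as_array(peak_counts.sample_ids)
    norm = peak_counts.counts.to_numpy(dtype=float) / sf
    res["a_value"] = np.log2(norm + 1.0).mean(axis=1)
    mask = res["fdr"] <= fdr_threshold
    if min_abs_log2fc > 0:
        mask &= np.abs(res["log2fc"]) >= min_abs_log2fc
    significant = res.loc[mask, "feature_id"].tolist()
    return res, significant


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def annotate_peaks(
    pooled: ConsensusPeakSet,
    genes: list[GeneRecord],
    window: int = 150_000,
    tss_margin: int = 1_000,
) -> list[PeakAnnotation]:
    """Assign each pooled peak to its nearest TSS within ``window`` bp.

    Distance is |summit - TSS|; ties go to the lexicographically smaller
    gene_id.  Category is ``tss_proximal`` when the distance is within
    ``tss_margin``, else ``genic`` when the summit lies inside any gene
    body, else ``intergenic``.  Peaks with no TSS in the window keep
    ``nearest_gene=None`` but are still categorised.
    """
    tss_by_chrom: dict[str, tuple[np.ndarray, list[GeneRecord]]] = {}
    body_trees: dict[str, IntervalTree] = {}
    for chrom in {g.chrom for g in genes}:
        gs = sorted(
            (g for g in genes if g.chrom == chrom),
            key=lambda g: (g.tss, g.gene_id),
        )
        tss_by_chrom[chrom] = (np.array([g.tss for g in gs]), gs)
        tree = IntervalTree()
        for g in gs:
            tree.addi(g.interval.start, g.interval.end)
        body_trees[chrom] = tree

    annotations: list[PeakAnnotation] = []
    for peak in pooled.peaks:
        summit = peak.summit
        nearest: GeneRecord | None = None
        best_dist: int | None = None
        entry = tss_by_chrom.get(peak.chrom)
        if entry is not None:
            tss_arr, gs = entry
            j = int(np.searchsorted(tss_arr, summit))
            candidates: list[int] = []
            # walk outwards to cover runs of genes sharing a TSS coordinate
            k = j - 1
            while k >= 0 and tss_arr[k] == tss_arr[j - 1]:
                candidates.append(k)
                k -= 1
            k = j
            while k < len(gs) and tss_arr[k] == tss_arr[min(j, len(gs) - 1)]:
                candidates.append(k)
                k += 1
            for k in candidates:
                d = abs(summit - int(tss_arr[k]))
                if (
                    best_dist is None
                    or d < best_dist
                    or (d == best_dist and gs[k].gene_id < nearest.gene_id)
                ):
                    best_dist, nearest = d, gs[k]
            if best_dist is not None and best_dist > window:
                nearest, best_dist = None, None
        if nearest is not None and best_dist is not None and best_dist <= tss_margin:
            category = "tss_proximal"
        else:
            tree = body_trees.get(peak.chrom)
            inside = bool(tree and tree.overlap(summit, summit + 1))
            category = "genic" if inside else "intergenic"
        signed: int | None = None
        if nearest is not None:
            signed = summit - nearest.tss
            if nearest.interval.strand == "-":
                signed = -signed
        annotations.append(
            PeakAnnotation(
                peak_id=peak.name,
                nearest_gene=nearest.gene_id if nearest else None,
                signed_distance=signed,
                category=category,
            )
        )
    return annotations


def tss_overrepresentation(
    annot_A_exclusive: list[PeakAnnotation],
    annot_B_exclusive: list[PeakAnnotation],
) -> tuple[float, float]:
    """One-sided Fisher test for TSS-proximal excess in A-exclusive peaks.

    2x2 table of (tss_proximal vs not) x (A-exclusive vs B-exclusive);
    alternative "greater" asks whether A-exclusive peaks are more often
    TSS-proximal.  Returns (odds_ratio, p); an empty margin yields
    p = 1.0 and odds ratio NaN.
    """
    if not annot_A_exclusive or not annot_B_exclusive:
        raise ValueError("both annotation lists must be non-empty")
    a = sum(1 for x in annot_A_exclusive if x.category == "tss_proximal")
    b = len(annot_A_exclusive) - a
    c = sum(1 for x in annot_B_exclusive if x.category == "tss_proximal")
    d = len(annot_B_exclusive) - c
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    odds, p = stats.fisher_exact(table, alternative="greater")
    return float(odds), float(p)
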