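"""Synthetic two-population ATAC + RNA dataset with known ground truth.

The generator emulates the statistical structure of a two-population
(FACS-sorted) bulk experiment with replicated ATAC-seq and RNA-seq:

* a random genome with configurable GC content;
* non-overlapping true peak loci, each shared between populations or
  exclusive to one of them; every replicate of an emitting population
  reports the locus as a narrowPeak with jittered boundaries;
* negative-binomial count tables for genes, peaks and intergenic
  background windows, with per-sample library-size factors, planted
  differential genes, population-specific and silent genes, and an
  accessibility shift on exclusive peaks;
* planted coupled (peak, gene) pairs whose accessibility and expression
  shifts share a sign and whose gene TSS is the peak's nearest gene;
* a consensus motif triple written into a configurable fraction of
  A-exclusive peak summit windows, for co-occurrence enrichment.

Every stage draws from a child seed derived from the global seed by a
fixed spawn key, so stages are individually reproducible and the whole
dataset is byte-identical under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .formats import (
    CountTable,
    GenomicInterval,
    GeneRecord,
    NarrowPeak,
    Pwm,
    write_counts,
    write_fasta,
    write_gene_table,
    write_narrowpeak,
    write_pfm,
)

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# spawn keys for per-stage child RNGs
_STAGE_GENOME = 0
_STAGE_PEAKS = 1
_STAGE_COUNTS = 2
_STAGE_PLANT = 3
_STAGE_MOTIFS = 4


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(stage,))
    )


def largest_remainder(fractions: list[float], total: int) -> list[int]:
    """Integer class counts summing to ``total`` (largest-remainder rule).

    Ties in the fractional remainders are broken by class order.
    """
    raw = [f * total for f in fractions]
    counts = [math.floor(r) for r in raw]
    short = total - sum(counts)
    order = sorted(
        range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i)
    )
    for i in order[:short]:
        counts[i] += 1
    return counts


def default_motif_set(
    n: int = 12,
    length: int = 8,
    seed: int = 7,
    consensus_prob: float = 0.85,
) -> list[Pwm]:
    """A reproducible set of informative PWMs with distinct consensi.

    Each motif concentrates ``consensus_prob`` on one base per position,
    spreading the rest uniformly — sharp enough that a 0.8 max-score
    threshold essentially requires the consensus word.
    """
    rng = np.random.default_rng(seed)
    pwms: list[Pwm] = []
    seen: set[tuple[int, ...]] = set()
    while len(pwms) < n:
        consensus = tuple(int(x) for x in rng.integers(0, 4, size=length))
        if consensus in seen:
            continue
        seen.add(consensus)
        probs = np.full((length, 4), (1 - consensus_prob) / 3)
        for i, b in enumerate(consensus):
            probs[i, b] = consensus_prob
        pwms.append(Pwm(f"M{len(pwms) + 1:02d}", probs))
    return pwms


def soft_motif_set(
    n: int = 12,
    length: int = 8,
    seed: int = 5,
    row_profile: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1),
) -> list[Pwm]:
    """Smooth, equal-information PWMs for calibration studies.

    Every position carries the same probability profile assigned to a
    random base permutation, so all motifs share one score distribution
    and match probabilities vary smoothly with the scan threshold.
    Sharp consensus motifs (see :func:`default_motif_set`) almost never
    hit random sequence, which makes null enrichment tables degenerate;
    these soft motifs keep presence probabilities moderate so null
    calibration of the enrichment tests can actually be observed.
    """
    if abs(sum(row_profile) - 1.0) > 1e-9:
        raise ValueError("row_profile must sum to 1")
    rng = np.random.default_rng(seed)
    profile = np.asarray(row_profile, dtype=float)
    pwms = []
    for i in range(n):
        probs = np.empty((length, 4))
        for j in range(length):
            probs[j] = profile[rng.permutation(4)]
        pwms.append(Pwm(f"S{i + 1:02d}", probs))
    return pwms


@dataclass
class SimulationConfig:
    """All knobs of the synthetic dataset.

    Defaults follow the scale of a two-population sorted-cell study:
    two populations with three replicates each, ~90% of peaks shared,
    negative-binomial counts with dispersion 0.1, 400-bp peaks with
    summit windows of the same size as the enrichment background
    windows.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = dc_field(
        default_factory=lambda: {"chr1": 3_000_000, "chr2": 3_000_000}
    )
    gc_fraction: float = 0.45
    n_genes: int = 2_000
    n_peaks: int = 3_000
    frac_shared: float = 0.90
    frac_exclusive_A: float = 0.05
    frac_exclusive_B: float = 0.05
    n_replicates: int = 3
    nb_mean_log2_range: tuple[float, float] = (8.0, 12.0)
    nb_dispersion: float = 0.1
    de_fraction: float = 0.10
    de_log2fc: float = 2.0
    frac_gene_specific_A: float = 0.05
    frac_gene_specific_B: float = 0.05
    frac_gene_silent: float = 0.10
    coupled_fraction: float = 0.016
    access_log2fc: float = 3.0
    peak_width: int = 400
    n_intergenic_windows: int = 1_000
    intergenic_mean: float = 4.0
    intergenic_dispersion: float = 0.3
    intergenic_window_size: int = 5_000
    motif_set: list[Pwm] = dc_field(default_factory=default_motif_set)
    planted_triple: tuple[str, str, str] = ("M01", "M02", "M03")
    planted_triple_rate: float = 0.6
    planted_span: int = 300
    summit_flank: int = 200
    gene_length: int = 2_000
    coupled_tss_offset: tuple[int, int] = (200, 3_000)

    def __post_init__(self) -> None:
        fracs = (self.frac_shared, self.frac_exclusive_A,
                 self.frac_exclusive_B)
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("peak class fractions must sum to 1")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        motif_ids = {p.motif_id for p in self.motif_set}
        if not set(self.planted_triple) <= motif_ids:
            raise ValueError("planted_triple must be drawn from motif_set")
        if len(set(self.planted_triple)) != 3:
            raise ValueError("planted_triple needs 3 distinct motifs")
        if self.planted_span > 2 * self.summit_flank:
            raise ValueError(
                "planted_span exceeds the summit window length"
            )
        longest = max(
            len(self.pwm_of(m)) for m in self.planted_triple
        )
        if longest > self.planted_span // 3:
            raise ValueError(
                "planted_span too small to fit three non-overlapping "
                "consensus sequences"
            )

    def pwm_of(self, motif_id: str) -> Pwm:
        for p in self.motif_set:
            if p.motif_id == motif_id:
                return p
        raise KeyError(motif_id)


@dataclass
class TruthTables:
    """Ground truth of one simulated dataset."""

    peak_class_truth: dict[str, str] = dc_field(default_factory=dict)
    peak_locus: dict[str, GenomicInterval] = dc_field(default_factory=dict)
    peak_summit: dict[str, int] = dc_field(default_factory=dict)
    de_truth: dict[str, float] = dc_field(default_factory=dict)
    gene_expression_class: dict[str, str] = dc_field(default_factory=dict)
    coupling_truth: set[tuple[str, str]] = dc_field(default_factory=set)
    planted_positions: dict[str, list[tuple[str, int, str]]] = dc_field(
        default_factory=dict
    )
    gene_records: list[GeneRecord] = dc_field(default_factory=list)


# ---------------------------------------------------------------------------
# stage 1: genome
# ---------------------------------------------------------------------------


def generate_genome(config: SimulationConfig) -> dict[str, str]:
    """I.i.d. random genome with P(G) + P(C) = ``gc_fraction``."""
    if not config.chrom_lengths:
        raise ValueError("chrom_lengths must be non-empty")
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    rng = _rng(config.seed, _STAGE_GENOME)
    genome = {}
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    for chrom, length in config.chrom_lengths.items():
        draws = rng.choice(4, size=length, p=probs)
        genome[chrom] = lut[draws].tobytes().decode("ascii")
    return genome


# ---------------------------------------------------------------------------
# stage 2: peak loci and replicate peak sets
# ---------------------------------------------------------------------------


def _place_disjoint_loci(
    config: SimulationConfig, rng: np.random.Generator
) -> list[GenomicInterval]:
    """Place n_peaks disjoint loci on a slot grid of pitch 2x peak width.

    The grid guarantees disjointness (with a full peak width of spacing,
    enough for boundary jitter and summit windows not to collide with
    neighbours' cores).
    """
    pitch = 2 * config.peak_width
    slots: list[tuple[str, int]] = []
    for chrom, length in config.chrom_lengths.items():
        # keep a margin so summit windows never run off the chromosome
        margin = config.summit_flank + config.peak_width
        for pos in range(margin, length - margin - config.peak_width, pitch):
            slots.append((chrom, pos))
    if len(slots) < config.n_peaks:
        raise ValueError(
            f"genome too small: {len(slots)} slots for "
            f"{config.n_peaks} peaks"
        )
    chosen = rng.choice(len(slots), size=config.n_peaks, replace=False)
    loci = [
        GenomicInterval(slots[i][0], slots[i][1],
                        slots[i][1] + config.peak_width)
        for i in sorted(int(c) for c in chosen)
    ]
    loci.sort(key=lambda iv: (iv.chrom, iv.start))
    return loci


def generate_peak_sets(
    config: SimulationConfig,
) -> tuple[dict[str, list[list[NarrowPeak]]], TruthTables]:
    """True loci, their classes, and jittered per-replicate peak calls.

    Returns ``{"A": [rep1, rep2, ...], "B": [...]}`` and a TruthTables
    with locus ids (``chrom:start-end``), classes and true summits.
    Class counts follow the configured fractions under the
    largest-remainder rule; replicate boundaries jitter by at most 10%
    of the peak width.
    """
    rng = _rng(config.seed, _STAGE_PEAKS)
    loci = _place_disjoint_loci(config, rng)
    classes = ["shared", "exclusive_A", "exclusive_B"]
    counts = largest_remainder(
        [config.frac_shared, config.frac_exclusive_A,
         config.frac_exclusive_B],
        config.n_peaks,
    )
    labels = np.repeat(classes, counts)
    rng.shuffle(labels)

    truth = TruthTables()
    jitter_max = max(config.peak_width // 10, 1)
    replicates: dict[str, list[list[NarrowPeak]]] = {
        "A": [[] for _ in range(config.n_replicates)],
        "B": [[] for _ in range(config.n_replicates)],
    }
    for locus, label in zip(loci, labels):
        locus_id = f"{locus.chrom}:{locus.start}-{locus.end}"
        truth.peak_class_truth[locus_id] = str(label)
        truth.peak_locus[locus_id] = locus
        summit = locus.midpoint
        truth.peak_summit[locus_id] = summit
        pops = {"shared": "AB", "exclusive_A": "A", "exclusive_B": "B"}[
            str(label)
        ]
        for pop in pops:
            for rep in range(config.n_replicates):
                ds = int(rng.integers(-jitter_max, jitter_max + 1))
                de = int(rng.integers(-jitter_max, jitter_max + 1))
                start = max(locus.start + ds, 0)
                end = locus.end + de
                if end <= start:
                    end = start + 1
                offset = min(max(summit - start, 0), end - start - 1)
                replicates[pop][rep].append(
                    NarrowPeak(
                        GenomicInterval(locus.chrom, start, end),
                        name=f"{pop}_rep{rep + 1}_{locus_id}",
                        score=int(rng.integers(100, 1000)),
                        summit_offset=offset,
                    )
                )
    for pop in replicates:
        for rep_peaks in replicates[pop]:
            rep_peaks.sort(key=lambda p: (p.chrom, p.start))
    return replicates, truth


# ---------------------------------------------------------------------------
# stage 3: counts
# ---------------------------------------------------------------------------


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB draws parameterised by mean and dispersion (var = m + a m^2)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-8:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _sample_names(config: SimulationConfig) -> tuple[list[str], dict[str, str]]:
    names = [
        f"{pop}_rep{r + 1}"
        for pop in ("A", "B")
        for r in range(config.n_replicates)
    ]
    groups = {s: s.split("_")[0] for s in names}
    return names, groups


def generate_counts(
    config: SimulationConfig, truth: TruthTables
) -> tuple[CountTable, CountTable, CountTable, dict[str, float]]:
    """Gene, peak and intergenic-window count tables.

    Gene classes (largest-remainder over the configured fractions):
    ``silent`` (background-level in both populations), ``specific_A`` /
    ``specific_B`` (expressed in one population, background-level in the
    other), ``de`` (expressed in both, log2 mean shifted by
    +/- de_log2fc in A, alternating sign) and ``background`` (equal
    means).  Exclusive peaks get a log2 accessibility shift of
    ``access_log2fc`` toward their emitting population.  Coupled
    (peak, gene) pairs tie an exclusive peak to a same-signed DE gene
    and place the gene's TSS next to the peak summit.  Library-size
    factors are drawn log-uniform in [0.5, 2] and multiply every NB
    mean.  Also populates ``truth.de_truth``, ``coupling_truth`` and
    gene placement, and returns the true size factors.
    """
    rng = _rng(config.seed, _STAGE_COUNTS)
    samples, groups = _sample_names(config)
    n_s = len(samples)
    size_factors = np.exp(
        rng.uniform(math.log(0.5), math.log(2.0), size=n_s)
    )
    lo, hi = config.nb_mean_log2_range

    # ---- gene classes -----------------------------------------------------
    n_genes = config.n_genes
    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    frac_de = config.de_fraction
    frac_rest = 1.0 - (
        config.frac_gene_silent
        + config.frac_gene_specific_A
        + config.frac_gene_specific_B
        + frac_de
    )
    if frac_rest < -1e-9:
        raise ValueError("gene class fractions exceed 1")
    class_counts = largest_remainder(
        [
            config.frac_gene_silent,
            config.frac_gene_specific_A,
            config.frac_gene_specific_B,
            frac_de,
            max(frac_rest, 0.0),
        ],
        n_genes,
    )
    gene_classes = np.repeat(
        ["silent", "specific_A", "specific_B", "de", "background"],
        class_counts,
    )
    rng.shuffle(gene_classes)

    base_log2 = rng.uniform(lo, hi, size=n_genes)
    mu_A = np.empty(n_genes)
    mu_B = np.empty(n_genes)
    de_sign = 1
    for i, klass in enumerate(gene_classes):
        b = base_log2[i]
        if klass == "silent":
            mu_A[i] = mu_B[i] = config.intergenic_mean
            truth.de_truth[gene_ids[i]] = 0.0
        elif klass == "specific_A":
            mu_A[i], mu_B[i] = 2.0**b, config.intergenic_mean
            truth.de_truth[gene_ids[i]] = b - math.log2(
                config.intergenic_mean
            )
        elif klass == "specific_B":
            mu_A[i], mu_B[i] = config.intergenic_mean, 2.0**b
            truth.de_truth[gene_ids[i]] = -(
                b - math.log2(config.intergenic_mean)
            )
        elif klass == "de":
            s = de_sign
            de_sign = -de_sign
            mu_A[i] = 2.0 ** (b + s * config.de_log2fc / 2)
            mu_B[i] = 2.0 ** (b - s * config.de_log2fc / 2)
            truth.de_truth[gene_ids[i]] = s * config.de_log2fc
        else:
            mu_A[i] = mu_B[i] = 2.0**b
            truth.de_truth[gene_ids[i]] = 0.0
        truth.gene_expression_class[gene_ids[i]] = str(klass)

    # ---- peak means -------------------------------------------------------
    locus_ids = list(truth.peak_class_truth)
    n_peaks = len(locus_ids)
    peak_base_log2 = rng.uniform(lo, hi, size=n_peaks)
    pk_A = np.empty(n_peaks)
    pk_B = np.empty(n_peaks)
    for i, locus_id in enumerate(locus_ids):
        b = peak_base_log2[i]
        klass = truth.peak_class_truth[locus_id]
        shift = config.access_log2fc / 2
        if klass == "shared":
            pk_A[i] = pk_B[i] = 2.0**b
        elif klass == "exclusive_A":
            pk_A[i], pk_B[i] = 2.0 ** (b + shift), 2.0 ** (b - shift)
        else:
            pk_A[i], pk_B[i] = 2.0 ** (b - shift), 2.0 ** (b + shift)

    # ---- coupled pairs ----------------------------------------------------
    n_coupled = int(round(config.coupled_fraction * n_peaks))
    excl_A = [
        lid for lid in locus_ids
        if truth.peak_class_truth[lid] == "exclusive_A"
    ]
    de_up_A = [
        gid for gid, klass in zip(gene_ids, gene_classes) if klass == "de"
        and truth.de_truth[gid] > 0
    ]
    n_coupled = min(n_coupled, len(excl_A), len(de_up_A))
    coupled_peaks = [excl_A[i] for i in range(n_coupled)]
    coupled_genes = [de_up_A[i] for i in range(n_coupled)]
    truth.coupling_truth = set(zip(coupled_peaks, coupled_genes))

    # ---- gene placement ---------------------------------------------------
    # Coupled genes sit next to their peak's summit; all other genes are
    # rejection-sampled away from coupled summits so the coupled gene is
    # guaranteed to be the peak's nearest TSS.
    coupled_gene_of: dict[str, str] = dict(
        zip(coupled_genes, coupled_peaks)
    )
    coupled_summits: dict[str, list[int]] = {}
    for lid in coupled_peaks:
        iv = truth.peak_locus[lid]
        coupled_summits.setdefault(iv.chrom, []).append(
            truth.peak_summit[lid]
        )
    exclusion = config.coupled_tss_offset[1] + config.gene_length
    chroms = list(config.chrom_lengths)
    chrom_len = config.chrom_lengths
    gene_records: list[GeneRecord] = []
    for gid in gene_ids:
        if gid in coupled_gene_of:
            lid = coupled_gene_of[gid]
            iv = truth.peak_locus[lid]
            off = int(
                rng.integers(config.coupled_tss_offset[0],
                             config.coupled_tss_offset[1] + 1)
            )
            side = 1 if rng.random() < 0.5 else -1
            tss = truth.peak_summit[lid] + side * off
            tss = min(max(tss, 1), chrom_len[iv.chrom] - config.gene_length - 1)
            strand = "+"
            start = tss
            end = min(tss + config.gene_length, chrom_len[iv.chrom])
            gene_records.append(
                GeneRecord(gid, GenomicInterval(iv.chrom, start, end,
                                                strand))
            )
            continue
        for _ in range(1000):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(
                rng.integers(0, chrom_len[chrom] - config.gene_length)
            )
            near = coupled_summits.get(chrom, [])
            tss_candidates = (start, start + config.gene_length - 1)
            if all(
                min(abs(t - s) for t in tss_candidates) > exclusion
                for s in near
            ) or not near:
                break
        else:
            raise RuntimeError("could not place gene away from coupled "
                               "summits")
        strand = "+" if rng.random() < 0.5 else "-"
        gene_records.append(
            GeneRecord(
                gid,
                GenomicInterval(chrom, start,
                                start + config.gene_length, strand),
            )
        )
    truth.gene_records = gene_records

    # ---- draws ------------------------------------------------------------
    def table(mu_a: np.ndarray, mu_b: np.ndarray, ids: list[str],
              dispersion: float) -> CountTable:
        mat = np.empty((len(ids), n_s), dtype=np.int64)
        for j, s in enumerate(samples):
            mu = mu_a if groups[s] == "A" else mu_b
            mat[:, j] = _nb_draw(rng, mu * size_factors[j], dispersion)
        return CountTable(
            pd.DataFrame(mat, index=ids, columns=samples), dict(groups)
        )

    gene_counts = table(mu_A, mu_B, gene_ids, config.nb_dispersion)
    peak_counts = table(pk_A, pk_B, locus_ids, config.nb_dispersion)
    iw_ids = [
        f"iw{i + 1:05d}" for i in range(config.n_intergenic_windows)
    ]
    iw_mu = np.full(config.n_intergenic_windows, config.intergenic_mean)
    intergenic_counts = table(
        iw_mu, iw_mu, iw_ids, config.intergenic_dispersion
    )
    true_factors = dict(zip(samples, size_factors.tolist()))
    return gene_counts, peak_counts, intergenic_counts, true_factors


# ---------------------------------------------------------------------------
# stage 4: motif planting
# ---------------------------------------------------------------------------


def plant_motif_triples(
    config: SimulationConfig,
    genome: dict[str, str],
    truth: TruthTables,
) -> dict[str, str]:
    """Write the planted triple's consensi into A-exclusive summit windows.

    For a fraction ``planted_triple_rate`` of A-exclusive loci, the three
    consensus sequences are placed at non-overlapping offsets inside the
    first ``planted_span`` bp of the summit window (one per third of the
    span), each on a random strand.  Positions are recorded as window
    offsets in ``truth.planted_positions``.  Returns the mutated genome.
    """
    pwms = [config.pwm_of(m) for m in config.planted_triple]
    consensi = [p.consensus() for p in pwms]
    slot = config.planted_span // 3
    if any(len(c) > slot for c in consensi):
        raise ValueError(
            f"planted_span {config.planted_span} too small for three "
            "consensus sequences"
        )
    rng = _rng(config.seed, _STAGE_PLANT)
    excl_A = [
        lid
        for lid, klass in truth.peak_class_truth.items()
        if klass == "exclusive_A"
    ]
    n_plant = int(round(config.planted_triple_rate * len(excl_A)))
    chosen = [
        excl_A[i]
        for i in sorted(
            int(x)
            for x in rng.choice(len(excl_A), size=n_plant, replace=False)
        )
    ] if n_plant else []
    mutable = {c: bytearray(s.encode("ascii")) for c, s in genome.items()}
    for lid in chosen:
        iv = truth.peak_locus[lid]
        window_start = truth.peak_summit[lid] - config.summit_flank
        placements: list[tuple[str, int, str]] = []
        order = rng.permutation(3)
        for slot_i, mi in enumerate(order):
            cons = consensi[mi]
            off_in_slot = int(rng.integers(0, slot - len(cons) + 1))
            offset = slot_i * slot + off_in_slot
            strand = "+" if rng.random() < 0.5 else "-"
            word = cons if strand == "+" else cons.translate(
                _COMPLEMENT
            )[::-1]
            pos = window_start + offset
            mutable[iv.chrom][pos: pos + len(word)] = word.encode("ascii")
            placements.append(
                (config.planted_triple[mi], offset, strand)
            )
        truth.planted_positions[lid] = sorted(
            placements, key=lambda t: t[1]
        )
    return {c: b.decode("ascii") for c, b in mutable.items()}


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """In-memory bundle of one simulated dataset."""

    config: SimulationConfig
    genome: dict[str, str]
    replicate_peaks: dict[str, list[list[NarrowPeak]]]
    gene_records: list[GeneRecord]
    gene_counts: CountTable
    peak_counts: CountTable
    intergenic_counts: CountTable
    true_size_factors: dict[str, float]
    truth: TruthTables


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run all generator stages in order under the configured seed."""
    genome = generate_genome(config)
    replicate_peaks, truth = generate_peak_sets(config)
    gene_counts, peak_counts, intergenic_counts, factors = generate_counts(
        config, truth
    )
    genome = plant_motif_triples(config, genome, truth)
    return SyntheticDataset(
        config=config,
        genome=genome,
        replicate_peaks=replicate_peaks,
        gene_records=truth.gene_records,
        gene_counts=gene_counts,
        peak_counts=peak_counts,
        intergenic_counts=intergenic_counts,
        true_size_factors=factors,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> Path:
    """Write the dataset directory consumed by the pipeline.

    Layout: genome.fa, genes.tsv, {A,B}_rep{i}.narrowPeak,
    gene_counts.tsv, peak_counts.tsv, intergenic_counts.tsv, motifs.pfm,
    truth/*.tsv and a YAML echo of the configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    write_fasta(sorted(dataset.genome.items()), outdir / "genome.fa")
    write_gene_table(dataset.gene_records, outdir / "genes.tsv")
    for pop, reps in dataset.replicate_peaks.items():
        for i, peaks in enumerate(reps, start=1):
            write_narrowpeak(peaks, outdir / f"{pop}_rep{i}.narrowPeak")
    write_counts(dataset.gene_counts, outdir / "gene_counts.tsv",
                 index_label="gene_id")
    write_counts(dataset.peak_counts, outdir / "peak_counts.tsv",
                 index_label="peak_id")
    write_counts(dataset.intergenic_counts,
                 outdir / "intergenic_counts.tsv", index_label="window_id")
    write_pfm(cfg.motif_set, outdir / "motifs.pfm")

    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    truth = dataset.truth
    pd.DataFrame(
        sorted(truth.peak_class_truth.items()),
        columns=["peak_id", "class"],
    ).to_csv(truth_dir / "peak_classes.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.de_truth.items()), columns=["gene_id", "log2fc"]
    ).to_csv(truth_dir / "de_truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.gene_expression_class.items()),
        columns=["gene_id", "class"],
    ).to_csv(truth_dir / "gene_classes.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.coupling_truth), columns=["peak_id", "gene_id"]
    ).to_csv(truth_dir / "coupling.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (lid, m, off, strand)
            for lid, placements in sorted(truth.planted_positions.items())
            for m, off, strand in placements
        ],
        columns=["peak_id", "motif_id", "window_offset", "strand"],
    ).to_csv(truth_dir / "planted_motifs.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(dataset.true_size_factors.items()),
        columns=["sample_id", "size_factor"],
    ).to_csv(truth_dir / "size_factors.tsv", sep="\t", index=False)

    echo = {
        "seed": cfg.seed,
        "chrom_lengths": dict(cfg.chrom_lengths),
        "gc_fraction": cfg.gc_fraction,
        "n_genes": cfg.n_genes,
        "n_peaks": cfg.n_peaks,
        "frac_shared": cfg.frac_shared,
        "frac_exclusive_A": cfg.frac_exclusive_A,
        "frac_exclusive_B": cfg.frac_exclusive_B,
        "n_replicates": cfg.n_replicates,
        "nb_mean_log2_range": list(cfg.nb_mean_log2_range),
        "nb_dispersion": cfg.nb_dispersion,
        "de_fraction": cfg.de_fraction,
        "de_log2fc": cfg.de_log2fc,
        "coupled_fraction": cfg.coupled_fraction,
        "access_log2fc": cfg.access_log2fc,
        "peak_width": cfg.peak_width,
        "planted_triple": list(cfg.planted_triple),
        "planted_triple_rate": cfg.planted_triple_rate,
        "planted_span": cfg.planted_span,
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=True)
    return outdir
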