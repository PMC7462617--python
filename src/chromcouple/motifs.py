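"""PWM scanning and motif-combination co-occurrence enrichment.

Peak summit windows (+/- 200 bp by default) are scanned with a set of
position weight matrices on both strands; a sequence "contains" a motif
when some offset scores at least ``threshold_fraction`` of the motif's
maximum attainable log2-odds.  Enrichment compares peak windows against
random background windows drawn from the genome (20,000 x 400 bp by
default) with one-sided Fisher exact tests, for single motifs and for
all unordered order-3 motif combinations whose hits co-occur within a
span (500 bp by default — for 400-bp windows the span test reduces to
co-presence).

Scanning is done once per (sequence, motif); combination statistics are
computed from the cached hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations as _itertools_combinations

import numpy as np
import pandas as pd
from scipy import stats

from .accessibility import ConsensusPeakSet
from .expression import bh_adjust
from .formats import ALPHABET, NarrowPeak, Pwm

__all__ = [
    "MotifHit",
    "SummitSequence",
    "BackgroundSet",
    "extract_summit_sequences",
    "scan_sequence",
    "scan_sequences",
    "sample_background",
    "single_motif_enrichment",
    "generate_combinations",
    "combination_present",
    "combination_enrichment",
    "fisher_exact_greater",
]

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MotifHit:
    """A scored match of a motif in a sequence (offset is 0-based)."""

    sequence_id: str
    motif_id: str
    offset: int
    strand: str
    score: float


@dataclass(frozen=True)
class SummitSequence:
    """A summit-centred window; ``truncated`` marks chromosome-edge clips."""

    sequence_id: str
    sequence: str
    truncated: bool = False


@dataclass
class BackgroundSet:
    """Random genomic windows used as the enrichment background."""

    sequences: list[tuple[str, str]]
    length: int
    seed: int
    max_n_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name, seq in self.sequences:
            if len(seq) != self.length:
                raise ValueError(
                    f"background window {name} has length {len(seq)}, "
                    f"expected {self.length}"
                )

    @property
    def n(self) -> int:
        return len(self.sequences)


# ---------------------------------------------------------------------------
# sequence extraction and background sampling
# ---------------------------------------------------------------------------


def extract_summit_sequences(
    peaks: ConsensusPeakSet | list[NarrowPeak],
    genome: dict[str, str],
    flank: int = 200,
) -> list[SummitSequence]:
    """Windows of ``2*flank`` bp centred on each peak summit, upper-cased.

    Windows running off a chromosome end are truncated and flagged; a
    peak on a chromosome absent from the genome is an error.
    """
    peak_list = peaks.peaks if isinstance(peaks, ConsensusPeakSet) else peaks
    out: list[SummitSequence] = []
    for p in peak_list:
        if p.chrom not in genome:
            raise KeyError(f"peak {p.name}: unknown chromosome {p.chrom}")
        chrom_seq = genome[p.chrom]
        summit = p.summit
        lo, hi = summit - flank, summit + flank
        truncated = lo < 0 or hi > len(chrom_seq)
        seq = chrom_seq[max(lo, 0): min(hi, len(chrom_seq))].upper()
        out.append(SummitSequence(p.name, seq, truncated))
    return out


def sample_background(
    genome: dict[str, str],
    n: int = 20_000,
    length: int = 400,
    seed: int = 0,
    max_n_fraction: float = 0.1,
    max_tries_factor: int = 20,
) -> BackgroundSet:
    """Uniformly sampled genomic windows for the enrichment background.

    Start positions are uniform over all positions admitting a full
    window across chromosomes; windows with more than ``max_n_fraction``
    ambiguous bases are rejected and resampled (bounded retries).
    """
    chroms = [c for c, s in genome.items() if len(s) >= length]
    if not chroms:
        raise ValueError(f"no chromosome admits a {length}-bp window")
    capacity = np.array([len(genome[c]) - length + 1 for c in chroms],
                        dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(capacity)])
    rng = np.random.default_rng(seed)
    sequences: list[tuple[str, str]] = []
    tries = 0
    max_tries = max(max_tries_factor * n, 1000)
    while len(sequences) < n and tries < max_tries:
        tries += 1
        flat = int(rng.integers(0, cum[-1]))
        ci = int(np.searchsorted(cum, flat, side="right")) - 1
        start = flat - int(cum[ci])
        chrom = chroms[ci]
        seq = genome[chrom][start: start + length].upper()
        n_frac = sum(1 for b in seq if b not in _BASE_INDEX) / length
        if n_frac > max_n_fraction:
            continue
        sequences.append((f"bg_{len(sequences) + 1:06d}", seq))
    if len(sequences) < n:
        raise RuntimeError(
            f"could not collect {n} background windows in {max_tries} tries"
        )
    return BackgroundSet(sequences, length, seed, max_n_fraction)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    """Map ACGT to 0..3 and anything else (N) to 4."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _score_matrix(encoded: np.ndarray, lut: np.ndarray) -> np.ndarray:
    """Sliding log2-odds scores: (n_seq, n_offsets) for fixed-length rows.

    ``lut`` is (L, 5): columns ACGT plus -inf for N.  Accumulates one
    position of the motif at a time, so memory stays at one score
    matrix.
    """
    L = lut.shape[0]
    n_off = encoded.shape[1] - L + 1
    if n_off <= 0:
        return np.empty((encoded.shape[0], 0))
    scores = np.zeros((encoded.shape[0], n_off))
    for j in range(L):
        scores += lut[j, encoded[:, j: j + n_off]]
    return scores


def _lut(pwm: Pwm) -> np.ndarray:
    lo = pwm.log_odds()
    return np.hstack([lo, np.full((lo.shape[0], 1), -np.inf)])


def scan_sequences(
    sequences: list[tuple[str, str]],
    pwm: Pwm,
    threshold_fraction: float = 0.8,
) -> list[MotifHit]:
    """Scan equal-length sequences with one PWM on both strands.

    A hit is any offset whose log2-odds score reaches
    ``threshold_fraction`` of the motif's maximum attainable score.
    Minus-strand hits are scored against the reverse-complement matrix
    and reported at their forward-strand offset.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    if not sequences:
        return []
    lengths = {len(s) for _, s in sequences}
    hits: list[MotifHit] = []
    for seq_len in sorted(lengths):
        group = [(name, s) for name, s in sequences if len(s) == seq_len]
        if seq_len < len(pwm):
            continue
        encoded = np.vstack([_encode(s) for _, s in group])
        cutoff = threshold_fraction * pwm.max_score()
        for strand, matrix in (("+", pwm), ("-", pwm.reverse_complement())):
            scores = _score_matrix(encoded, _lut(matrix))
            rows, cols = np.where(scores >= cutoff)
            for r, c in zip(rows.tolist(), cols.tolist()):
                hits.append(
                    MotifHit(group[r][0], pwm.motif_id, c, strand,
                             float(scores[r, c]))
                )
    hits.sort(key=lambda h: (h.sequence_id, h.offset, h.strand))
    return hits


def scan_sequence(
    seq: str,
    pwm: Pwm,
    threshold_fraction: float = 0.8,
    sequence_id: str = "seq",
) -> list[MotifHit]:
    """Scan a single sequence (see :func:`scan_sequences`)."""
    return scan_sequences([(sequence_id, seq)], pwm, threshold_fraction)


# ---------------------------------------------------------------------------
# Fisher machinery
# ---------------------------------------------------------------------------


def fisher_exact_greater(table) -> tuple[float, float]:
    """One-sided (greater) Fisher exact test on a 2x2 integer table.

    Returns (odds_ratio, p) with the sample odds ratio ad/bc; a zero
    denominator yields ``inf`` (or ``nan`` when the numerator is also
    zero).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("table cells must be non-negative")
    (a, b), (c, d) = t
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(t, alternative="greater")
    return odds, float(p)


def generate_combinations(motif_ids, order: int = 3) -> list[tuple[str, ...]]:
    """All unordered distinct motif combinations, lexicographically sorted."""
    ids = sorted(set(motif_ids))
    if len(ids) < order:
        raise ValueError(
            f"need at least {order} distinct motifs, got {len(ids)}"
        )
    return list(_itertools_combinations(ids, order))


def group_hits(
    hits: list[MotifHit], motif_lengths: dict[str, int]
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """sequence_id -> motif_id -> sorted list of hit spans [start, end)."""
    grouped: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for h in hits:
        span = (h.offset, h.offset + motif_lengths[h.motif_id])
        grouped.setdefault(h.sequence_id, {}).setdefault(
            h.motif_id, []
        ).append(span)
    for per_motif in grouped.values():
        for spans in per_motif.values():
            spans.sort()
    return grouped


def combination_present(
    hits_of_sequence: dict[str, list[tuple[int, int]]],
    triple: tuple[str, ...],
    span: int = 500,
) -> bool:
    """True iff one hit of each motif fits inside some ``span``-bp window.

    The window condition is max(hit ends) - min(hit starts) <= span.
    Any feasible window can be shifted right until its left edge touches
    the earliest hit start it contains, so it suffices to anchor the
    window at each hit start in turn.
    """
    if len(set(triple)) != len(triple):
        raise ValueError("combination has repeated motif ids")
    spans_per_motif = []
    for m in triple:
        spans = hits_of_sequence.get(m)
        if not spans:
            return False
        spans_per_motif.append(spans)
    events = sorted(
        (start, end, mi)
        for mi, spans in enumerate(spans_per_motif)
        for start, end in spans
    )
    k = len(triple)
    for left in range(len(events)):
        anchor = events[left][0]
        present = set()
        for start, end, mi in events[left:]:
            if end <= anchor + span:
                present.add(mi)
                if len(present) == k:
                    return True
    return False


def _presence_matrix(
    grouped: dict[str, dict[str, list[tuple[int, int]]]],
    sequence_ids: list[str],
    motif_ids: list[str],
) -> np.ndarray:
    pres = np.zeros((len(sequence_ids), len(motif_ids)), dtype=bool)
    mindex = {m: j for j, m in enumerate(motif_ids)}
    sindex = {s: i for i, s in enumerate(sequence_ids)}
    for sid, per_motif in grouped.items():
        if sid not in sindex:
            continue
        for m in per_motif:
            pres[sindex[sid], mindex[m]] = True
    return pres


def _scan_all(
    sequences: list[tuple[str, str]],
    pwms: list[Pwm],
    threshold_fraction: float,
) -> tuple[dict[str, dict[str, list[tuple[int, int]]]], dict[str, int]]:
    motif_lengths = {p.motif_id: len(p) for p in pwms}
    all_hits: list[MotifHit] = []
    for pwm in pwms:
        all_hits.extend(scan_sequences(sequences, pwm, threshold_fraction))
    return group_hits(all_hits, motif_lengths), motif_lengths


def single_motif_enrichment(
    peak_seqs: list[tuple[str, str]],
    background: BackgroundSet,
    pwms: list[Pwm],
    threshold_fraction: float = 0.8,
) -> pd.DataFrame:
    """Per-motif presence enrichment in peak windows versus background.

    Presence (>= 1 hit anywhere in the sequence) defines the 2x2 table
    peak/background x present/absent; one-sided (greater) Fisher p-values
    are BH-adjusted over motifs.
    """
    if not peak_seqs or background.n == 0:
        raise ValueError("both sequence sets must be non-empty")
    motif_ids = [p.motif_id for p in pwms]
    peak_grouped, _ = _scan_all(peak_seqs, pwms, threshold_fraction)
    bg_grouped, _ = _scan_all(background.sequences, pwms, threshold_fraction)
    peak_ids = [s for s, _ in peak_seqs]
    bg_ids = [s for s, _ in background.sequences]
    pres_peak = _presence_matrix(peak_grouped, peak_ids, motif_ids)
    pres_bg = _presence_matrix(bg_grouped, bg_ids, motif_ids)
    rows = []
    for j, m in enumerate(motif_ids):
        k_peak = int(pres_peak[:, j].sum())
        k_bg = int(pres_bg[:, j].sum())
        odds, p = fisher_exact_greater(
            [[k_peak, len(peak_ids) - k_peak], [k_bg, len(bg_ids) - k_bg]]
        )
        rows.append((m, k_peak, len(peak_ids), k_bg, len(bg_ids), odds, p))
    df = pd.DataFrame(
        rows,
        columns=["motif_id", "k_peak", "n_peak", "k_bg", "n_bg",
                 "odds_ratio", "p"],
    )
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def combination_enrichment(
    peak_seqs: list[tuple[str, str]],
    background: BackgroundSet,
    pwms: list[Pwm],
    order: int = 3,
    span: int = 500,
    threshold_fraction: float = 0.8,
) -> pd.DataFrame:
    """Order-``order`` motif-combination enrichment, peaks vs background.

    Each sequence set is scanned once per motif; a combination is present
    in a sequence when hits of all its motifs co-occur within ``span`` bp
    (for sequences no longer than ``span`` this is plain co-presence).
    One-sided Fisher p-values over the 2x2 presence tables are
    BH-adjusted across all combinations; rows are sorted by p.
    """
    motif_ids = [p.motif_id for p in pwms]
    combos = generate_combinations(motif_ids, order)
    peak_grouped, _ = _scan_all(peak_seqs, pwms, threshold_fraction)
    bg_grouped, _ = _scan_all(background.sequences, pwms, threshold_fraction)

    mindex = {m: j for j, m in enumerate(motif_ids)}
    combo_cols = np.array([[mindex[m] for m in combo] for combo in combos])

    def presence_counts(
        grouped: dict[str, dict[str, list[tuple[int, int]]]],
        seqs: list[tuple[str, str]],
    ) -> dict[tuple[str, ...], int]:
        ids = [s for s, _ in seqs]
        pres = _presence_matrix(grouped, ids, motif_ids)
        short = np.array([len(q) <= span for _, q in seqs])
        # sequences no longer than the span: co-presence suffices
        co = pres[short][:, combo_cols].all(axis=2).sum(axis=0)
        counts = dict(zip(combos, (int(x) for x in co)))
        for i in np.flatnonzero(~short):
            row = pres[i]
            if row.sum() < order:
                continue
            per_motif = grouped.get(ids[i], {})
            for combo, cols in zip(combos, combo_cols):
                if row[cols].all() and combination_present(
                    per_motif, combo, span
                ):
                    counts[combo] += 1
        return counts

    k_peak = presence_counts(peak_grouped, peak_seqs)
    k_bg = presence_counts(bg_grouped, background.sequences)
    n_peak, n_bg = len(peak_seqs), background.n
    rows = []
    for combo in combos:
        odds, p = fisher_exact_greater(
            [
                [k_peak[combo], n_peak - k_peak[combo]],
                [k_bg[combo], n_bg - k_bg[combo]],
            ]
        )
        rows.append(
            ("+".join(combo), k_peak[combo], n_peak, k_bg[combo], n_bg,
             odds, p)
        )
    df = pd.DataFrame(
        rows,
        columns=["motif_ids", "k_peak", "n_peak", "k_bg", "n_bg",
                 "odds_ratio", "p"],
    )
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values("p", kind="stable").reset_index(drop=True)
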