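"""Readers, writers and the shared genomic data model.

All coordinates in this package are 0-based, half-open (BED convention).
Conversion to 1-based display coordinates, where needed, happens only at
report boundaries.  narrowPeak summits are stored as offsets relative to
the peak start; the absolute summit is ``start + summit_offset``, and a
stored offset of ``-1`` means "unknown", in which case the interval
midpoint (floored) is used.

File formats handled here:

* narrowPeak (BED6+4) peak files,
* a flat tab-separated gene table (``gene_id  chrom  start  end  strand``),
* JASPAR-style position frequency matrices (PFM),
* count tables as TSV (header row = sample ids, first column = feature id),
* FASTA genome files (via Biopython).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
_STRANDS = {"+", "-", "."}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# core data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Single-bp overlap predicate on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class NarrowPeak:
    """One narrowPeak record (BED6+4).

    ``summit_offset`` is relative to ``interval.start``; ``-1`` means the
    caller did not report a summit, in which case :attr:`summit` falls back
    to the interval midpoint.
    """

    interval: GenomicInterval
    name: str = "."
    score: int = 0
    signal: float = 0.0
    neglog10_p: float = -1.0
    neglog10_q: float = -1.0
    summit_offset: int = -1

    def __post_init__(self) -> None:
        width = len(self.interval)
        if self.summit_offset != -1 and not 0 <= self.summit_offset < width:
            raise ValueError(
                f"summit_offset {self.summit_offset} outside peak of width {width} "
                f"({self.interval.chrom}:{self.interval.start}-{self.interval.end})"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def summit(self) -> int:
        """Absolute summit position; interval midpoint when unknown."""
        if self.summit_offset == -1:
            return self.interval.midpoint
        return self.interval.start + self.summit_offset


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its transcription start site.

    The TSS is derived from the strand: ``start`` for ``+`` genes and
    ``end - 1`` for ``-`` genes (0-based).
    """

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', "
                f"got {self.interval.strand!r}"
            )

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class CountTable:
    """Non-negative integer counts (features x samples) with group labels.

    ``counts`` is a pandas DataFrame indexed by feature id with sample-id
    columns; ``groups`` maps every sample id to population ``"A"`` or
    ``"B"``.
    """

    counts: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dup[:5]}")
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = df.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.integer)):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral")
            self.counts = df.astype(np.int64)
            arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            raise ValueError("counts must be non-negative")
        missing = [s for s in df.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        bad = {s: g for s, g in self.groups.items() if g not in ("A", "B")}
        if bad:
            raise ValueError(f"group labels must be 'A' or 'B': {bad}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of_group(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]

    def subset_features(self, ids: Sequence[str]) -> "CountTable":
        return CountTable(self.counts.loc[list(ids)], dict(self.groups))


@dataclass
class Pwm:
    """Position probability matrix over ACGT with a background model.

    ``probs`` has shape (L, 4); every row sums to one after pseudocount
    regularisation of the raw counts.  Scores produced from a Pwm are
    log2-odds against ``background``.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be an (L, 4) matrix")
        if len(self) < 4:
            raise ValueError(f"motif {self.motif_id}: length must be >= 4")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"motif {self.motif_id}: rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        pseudocount: float = 1.0,
        background: np.ndarray | None = None,
    ) -> "Pwm":
        """Build from a count (PFM) matrix: p = (c + pc) / (sum(c) + 4 pc)."""
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must be an (L, 4) matrix")
        totals = counts.sum(axis=1) + 4 * pseudocount
        if np.any(totals <= 0):
            raise ValueError(
                f"motif {motif_id}: zero-count row with zero pseudocount"
            )
        probs = (counts + pseudocount) / totals[:, None]
        kwargs = {} if background is None else {"background": background}
        return cls(motif_id, probs, pseudocount=pseudocount, **kwargs)

    def log_odds(self) -> np.ndarray:
        """(L, 4) log2-odds matrix; zero-probability cells map to -inf."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs) - np.log2(self.background)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        return replace(self, probs=self.probs[::-1, ::-1].copy(),
                       background=self.background[::-1].copy())


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------


def read_narrowpeak(path: str | Path) -> list[NarrowPeak]:
    """Read a narrowPeak (BED6+4) file, sorted by (chrom, start).

    Raises :class:`FormatError` naming the offending line on malformed
    input; summit offsets outside the peak raise a validation error.
    """
    peaks: list[NarrowPeak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated input
                fields = line.split()
            if len(fields) < 10:
                raise FormatError(
                    f"{path}:{lineno}: expected 10 narrowPeak columns, "
                    f"got {len(fields)}"
                )
            try:
                iv = GenomicInterval(
                    fields[0], int(fields[1]), int(fields[2]), fields[5]
                )
                peak = NarrowPeak(
                    interval=iv,
                    name=fields[3],
                    score=int(fields[4]),
                    signal=float(fields[6]),
                    neglog10_p=float(fields[7]),
                    neglog10_q=float(fields[8]),
                    summit_offset=int(fields[9]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            peaks.append(peak)
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return peaks


def write_narrowpeak(peaks: Iterable[NarrowPeak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        str(p.score),
                        p.interval.strand,
                        f"{p.signal:g}",
                        f"{p.neglog10_p:g}",
                        f"{p.neglog10_q:g}",
                        str(p.summit_offset),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read the flat TSV gene table (gene_id, chrom, start, end, strand)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    missing = [c for c in _GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"{path}: duplicated gene_id(s): {dup[:5]}")
    genes = []
    for row in df.itertuples(index=False):
        try:
            iv = GenomicInterval(row.chrom, int(row.start), int(row.end),
                                 str(row.strand))
            genes.append(GeneRecord(str(row.gene_id), iv))
        except ValueError as exc:
            raise FormatError(f"{path}: gene {row.gene_id}: {exc}") from exc
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    rows = [
        (g.gene_id, g.chrom, g.interval.start, g.interval.end,
         g.interval.strand)
        for g in genes
    ]
    pd.DataFrame(rows, columns=_GENE_COLUMNS).to_csv(path, sep="\t",
                                                     index=False)


_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


def read_gtf_genes(path: str | Path) -> list[GeneRecord]:
    """Minimal GTF importer: only ``gene`` features, only id/coords/strand.

    GTF is 1-based inclusive; coordinates are converted to 0-based
    half-open on read.
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "gene":
                continue
            m = _GTF_GENE_ID.search(fields[8])
            if not m:
                raise FormatError(f"{path}:{lineno}: no gene_id attribute")
            gene_id = m.group(1)
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicated gene_id "
                                  f"{gene_id}")
            seen.add(gene_id)
            iv = GenomicInterval(fields[0], int(fields[3]) - 1,
                                 int(fields[4]), fields[6])
            genes.append(GeneRecord(gene_id, iv))
    return genes


# ---------------------------------------------------------------------------
# PFM (JASPAR dialect)
# ---------------------------------------------------------------------------


def read_pfm(path: str | Path, pseudocount: float = 1.0) -> list[Pwm]:
    """Read JASPAR-style PFM blocks into probability matrices.

    Accepts both the bracketed four-line layout::

        >MA0001 name
        A [ 10  3 ... ]
        C [  0  5 ... ]
        ...

    and bare four-line count blocks after a ``>`` header.
    """
    pwms: list[Pwm] = []
    header: str | None = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        if set(rows) != set(ALPHABET):
            raise FormatError(
                f"{path}: motif {header}: expected rows A,C,G,T, "
                f"got {sorted(rows)}"
            )
        counts = np.array([rows[b] for b in ALPHABET]).T  # (L, 4)
        if counts.shape[0] < 4:
            raise FormatError(f"{path}: motif {header}: length < 4")
        pwms.append(Pwm.from_counts(header, counts, pseudocount=pseudocount))
        header, rows = None, {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0]
                continue
            if header is None:
                raise FormatError(f"{path}:{lineno}: counts before header")
            m = re.match(r"^([ACGT])\s*\[?\s*([-\d.eE+\s]*?)\s*\]?$", line)
            if m:
                base, payload = m.group(1), m.group(2)
            else:
                base = ALPHABET[len(rows)] if len(rows) < 4 else "?"
                payload = line
            try:
                values = [float(x) for x in payload.split()]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad count row") from exc
            if base in rows:
                raise FormatError(f"{path}:{lineno}: duplicate {base} row")
            rows[base] = values
    flush()
    return pwms


def write_pfm(pwms: Iterable[Pwm], path: str | Path,
              scale: float = 100.0) -> None:
    """Write probability matrices as JASPAR-style scaled count blocks."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            counts = pwm.probs * scale
            for j, base in enumerate(ALPHABET):
                row = " ".join(f"{c:10.4f}" for c in counts[:, j])
                fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------


def infer_groups(sample_ids: Iterable[str]) -> dict[str, str]:
    """Infer population labels from sample-id prefixes (``A_rep1`` -> A)."""
    groups = {}
    for s in sample_ids:
        prefix = s.split("_")[0]
        if prefix not in ("A", "B"):
            raise FormatError(
                f"cannot infer group of sample {s!r}; pass groups explicitly"
            )
        groups[s] = prefix
    return groups


def read_counts(path: str | Path,
                groups: Mapping[str, str] | None = None) -> CountTable:
    """Read a count TSV (first column feature id, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if groups is None:
        groups = infer_groups(df.columns)
    return CountTable(df, dict(groups))


def write_counts(table: CountTable, path: str | Path,
                 index_label: str = "feature_id") -> None:
    table.counts.to_csv(path, sep="\t", index_label=index_label)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an upper-cased {name: sequence} dict."""
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Iterable[tuple[str, str]],
                path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences
    ]
    SeqIO.write(records, str(path), "fasta")
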