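"""PWM scanning, background sampling, Fisher machinery, combinations."""

import math

import numpy as np
import pytest

from chromcouple.accessibility import ConsensusPeakSet
from chromcouple.formats import GenomicInterval, NarrowPeak, Pwm
from chromcouple.motifs import (
    BackgroundSet,
    combination_enrichment,
    combination_present,
    extract_summit_sequences,
    fisher_exact_greater,
    generate_combinations,
    group_hits,
    sample_background,
    scan_sequence,
    scan_sequences,
    single_motif_enrichment,
)
from chromcouple.synthetic import default_motif_set
from tests.conftest import random_sequence

_RC = str.maketrans("ACGT", "TGCA")


def brute_force_scan(seq, pwm, threshold_fraction):
    """Per-offset log2-odds scoring in pure Python, both strands."""
    hits = []
    cutoff = threshold_fraction * pwm.max_score()
    for strand, matrix in (("+", pwm), ("-", pwm.reverse_complement())):
        lo = matrix.log_odds()
        L = len(matrix)
        for off in range(len(seq) - L + 1):
            score = 0.0
            for i, base in enumerate(seq[off: off + L]):
                if base in "ACGT":
                    score += lo[i, "ACGT".index(base)]
                else:
                    score = -math.inf
                    break
            if score >= cutoff:
                hits.append((off, strand, round(score, 9)))
    return sorted(hits)


class TestScanner:
    def test_sharp_pwm_hits_only_consensus(self):
        # probabilities ~1 at each consensus base, uniform background:
        # max score ~ L * log2(4) bits, attained only at the consensus
        probs = np.full((5, 4), 1e-9)
        consensus = "ACGTA"
        for i, b in enumerate(consensus):
            probs[i, "ACGT".index(b)] = 1 - 3e-9
        pwm = Pwm("sharp", probs)
        assert pwm.max_score() == pytest.approx(5 * 2, abs=1e-6)
        seq = "GGGG" + consensus + "GGGGG"
        hits = scan_sequence(seq, pwm, threshold_fraction=0.99)
        assert [(h.offset, h.strand) for h in hits] == [(4, "+")]

    def test_matches_brute_force(self, rng):
        for trial in range(100):
            r = np.random.default_rng(5000 + trial)
            L = int(r.integers(4, 10))
            pwm = Pwm(
                "rand",
                r.dirichlet(np.full(4, 0.8), size=L),
                background=np.array([0.3, 0.2, 0.2, 0.3]),
            )
            seq = random_sequence(r, int(r.integers(L, 60)))
            tf = float(r.uniform(0.4, 0.95))
            hits = scan_sequence(seq, pwm, tf)
            got = sorted(
                (h.offset, h.strand, round(h.score, 9)) for h in hits
            )
            assert got == brute_force_scan(seq, pwm, tf)

    def test_reverse_complement_symmetry(self, rng):
        pwm = default_motif_set(n=1, seed=3)[0]
        seq = random_sequence(rng, 300)
        rc = seq.translate(_RC)[::-1]
        fwd = scan_sequence(seq, pwm, 0.75)
        rev = scan_sequence(rc, pwm, 0.75)
        L = len(pwm)
        mirrored = sorted(
            (len(seq) - h.offset - L, {"+": "-", "-": "+"}[h.strand],
             round(h.score, 9))
            for h in rev
        )
        assert mirrored == sorted(
            (h.offset, h.strand, round(h.score, 9)) for h in fwd
        )

    def test_n_bases_never_hit(self):
        pwm = default_motif_set(n=1)[0]
        seq = "N" * 50
        assert scan_sequence(seq, pwm, 0.1) == []

    def test_threshold_fraction_validated(self):
        pwm = default_motif_set(n=1)[0]
        with pytest.raises(ValueError):
            scan_sequence("ACGTACGT", pwm, 0.0)
        with pytest.raises(ValueError):
            scan_sequence("ACGTACGT", pwm, 1.5)


class TestSummitExtraction:
    def _pooled(self, *summits, width=400, chrom="chr1"):
        peaks = []
        for i, s in enumerate(summits):
            start = s - width // 2
            peaks.append(
                NarrowPeak(
                    GenomicInterval(chrom, start, start + width),
                    name=f"p{i}", summit_offset=width // 2,
                )
            )
        return ConsensusPeakSet("pooled", peaks)

    def test_window_is_genome_slice(self, rng):
        genome = {"chr1": random_sequence(rng, 10_000)}
        pooled = self._pooled(3_000, 7_000)
        seqs = extract_summit_sequences(pooled, genome, flank=200)
        assert [len(s.sequence) for s in seqs] == [400, 400]
        assert seqs[0].sequence == genome["chr1"][2_800:3_200]
        assert seqs[1].sequence == genome["chr1"][6_800:7_200]
        assert not seqs[0].truncated

    def test_chromosome_edge_truncates_and_flags(self, rng):
        genome = {"chr1": random_sequence(rng, 5_000)}
        peaks = [
            NarrowPeak(GenomicInterval("chr1", 0, 300), name="p0",
                       summit_offset=100)
        ]
        (s,) = extract_summit_sequences(
            ConsensusPeakSet("pooled", peaks), genome, flank=200
        )
        assert s.truncated
        assert len(s.sequence) == 300  # [0, 300) instead of [-100, 300)

    def test_unknown_chromosome_is_error(self, rng):
        genome = {"chr1": random_sequence(rng, 1_000)}
        peaks = [NarrowPeak(GenomicInterval("chrX", 100, 500), name="p")]
        with pytest.raises(KeyError):
            extract_summit_sequences(
                ConsensusPeakSet("pooled", peaks), genome
            )


class TestBackground:
    def test_lengths_and_determinism(self, rng):
        genome = {"chr1": random_sequence(rng, 50_000),
                  "chr2": random_sequence(rng, 30_000)}
        a = sample_background(genome, n=500, length=400, seed=9)
        b = sample_background(genome, n=500, length=400, seed=9)
        c = sample_background(genome, n=500, length=400, seed=10)
        assert a.n == 500
        assert all(len(s) == 400 for _, s in a.sequences)
        assert a.sequences == b.sequences
        assert a.sequences != c.sequences

    def test_zero_n(self, rng):
        genome = {"chr1": random_sequence(rng, 5_000)}
        assert sample_background(genome, n=0, seed=1).n == 0

    def test_ambiguous_windows_rejected(self):
        genome = {"chr1": "N" * 10_000 + "ACGT" * 1_000}
        bg = sample_background(genome, n=50, length=100, seed=2,
                               max_n_fraction=0.0)
        assert all("N" not in s for _, s in bg.sequences)

    def test_too_small_genome_is_error(self):
        with pytest.raises((ValueError, RuntimeError)):
            sample_background({"chr1": "ACGT"}, n=10, length=400, seed=0)


class TestFisher:
    def test_most_extreme_table(self):
        odds, p = fisher_exact_greater([[2, 0], [0, 2]])
        assert p == pytest.approx(1 / 6)
        assert odds == math.inf

    def test_hand_enumerated_table(self):
        # margins (4, 4) x (4, 4): P(X >= 3) = (16 + 1) / 70
        odds, p = fisher_exact_greater([[3, 1], [1, 3]])
        assert p == pytest.approx(17 / 70)
        assert odds == pytest.approx(9.0)

    def test_zero_observed_in_first_cell(self):
        _, p = fisher_exact_greater([[0, 5], [0, 5]])
        assert p == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(1000):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
            _, p = fisher_exact_greater([[a, b], [c, d]])
            assert p == pytest.approx(
                _hypergeom_tail(a, b, c, d), abs=1e-12
            )

    def test_negative_cell_is_error(self):
        with pytest.raises(ValueError):
            fisher_exact_greater([[1, -1], [0, 2]])


def _hypergeom_tail(a, b, c, d):
    """P(X >= a) by explicit enumeration with exact rational arithmetic."""
    from fractions import Fraction

    n, K, m = a + b + c + d, a + c, a + b
    lo, hi = max(0, m - (n - K)), min(K, m)
    total = math.comb(n, m)
    tail = sum(
        Fraction(math.comb(K, x) * math.comb(n - K, m - x), total)
        for x in range(max(a, lo), hi + 1)
    )
    return float(tail)


class TestCombinations:
    def test_counts_and_order(self):
        combos = generate_combinations([f"m{i}" for i in range(10)])
        assert len(combos) == 120  # C(10, 3)
        assert combos == sorted(combos)
        assert all(len(set(c)) == 3 for c in combos)

    def test_single_combination(self):
        assert generate_combinations(["b", "a", "c"]) == [("a", "b", "c")]

    def test_too_few_motifs_is_error(self):
        with pytest.raises(ValueError):
            generate_combinations(["a", "b"], order=3)


class TestCombinationPresent:
    def test_span_window_arithmetic(self):
        # hits at offsets 0, 300, 650 (length 10): max end 660 - 0 > 500
        hits = {"a": [(0, 10)], "b": [(300, 310)], "c": [(650, 660)]}
        assert not combination_present(hits, ("a", "b", "c"), span=500)
        hits["c"] = [(450, 460)]
        assert combination_present(hits, ("a", "b", "c"), span=500)

    def test_missing_motif(self):
        hits = {"a": [(0, 10)], "b": [(20, 30)]}
        assert not combination_present(hits, ("a", "b", "c"), span=500)

    def test_repeated_motif_is_error(self):
        with pytest.raises(ValueError):
            combination_present({}, ("a", "a", "b"))

    def test_multiple_hits_find_feasible_window(self):
        # early isolated hits plus a tight cluster later
        hits = {
            "a": [(0, 8), (900, 908)],
            "b": [(950, 958)],
            "c": [(1000, 1008)],
        }
        assert combination_present(hits, ("a", "b", "c"), span=200)


class TestEnrichment:
    def _planted_sequences(self, rng, pwms, triple, n, length=400,
                           rate=0.8):
        seqs = []
        consensi = {p.motif_id: p.consensus() for p in pwms}
        for i in range(n):
            seq = list(random_sequence(rng, length))
            if rng.random() < rate:
                for k, m in enumerate(triple):
                    off = 30 + 120 * k
                    seq[off: off + len(consensi[m])] = consensi[m]
            seqs.append((f"p{i}", "".join(seq)))
        return seqs

    def test_planted_triple_ranks_first(self, rng):
        pwms = default_motif_set(n=8)
        triple = ("M01", "M02", "M03")
        peak_seqs = self._planted_sequences(rng, pwms, triple, 200,
                                            rate=0.6)
        bg = BackgroundSet(
            [(f"bg_{i}", random_sequence(rng, 400)) for i in range(1000)],
            400, 1,
        )
        df = combination_enrichment(peak_seqs, bg, pwms)
        assert df.iloc[0]["motif_ids"] == "M01+M02+M03"
        assert df.iloc[0]["fdr"] < 1e-10
        assert df.iloc[0]["k_peak"] >= 0.5 * 200

    def test_empty_tables_give_p_one(self, rng):
        pwms = default_motif_set(n=4)
        peak_seqs = [(f"p{i}", random_sequence(rng, 60)) for i in range(20)]
        bg = BackgroundSet(
            [(f"bg_{i}", random_sequence(rng, 60)) for i in range(50)],
            60, 0,
        )
        df = combination_enrichment(peak_seqs, bg, pwms)
        zero = df[(df["k_peak"] == 0) & (df["k_bg"] == 0)]
        assert (zero["p"] == 1.0).all()

    def test_stability_under_motif_set_growth(self, rng):
        pwms_small = default_motif_set(n=5)
        pwms_large = default_motif_set(n=8)  # superset: same seed
        assert [p.motif_id for p in pwms_large[:5]] == [
            p.motif_id for p in pwms_small
        ]
        peak_seqs = self._planted_sequences(rng, pwms_small,
                                            ("M01", "M02", "M03"), 100)
        bg = BackgroundSet(
            [(f"bg_{i}", random_sequence(rng, 400)) for i in range(300)],
            400, 0,
        )
        small = combination_enrichment(peak_seqs, bg, pwms_small)
        large = combination_enrichment(peak_seqs, bg, pwms_large)
        merged = small.merge(
            large, on="motif_ids", suffixes=("_s", "_l")
        )
        assert len(merged) == len(small)
        assert (merged["k_peak_s"] == merged["k_peak_l"]).all()
        assert merged["p_s"].to_numpy() == pytest.approx(
            merged["p_l"].to_numpy()
        )

    def test_span_longer_than_sequence_equals_copresence(self, rng):
        pwms = default_motif_set(n=5)
        peak_seqs = self._planted_sequences(rng, pwms, ("M01", "M02", "M03"),
                                            80, length=300)
        bg = BackgroundSet(
            [(f"bg_{i}", random_sequence(rng, 300)) for i in range(200)],
            300, 0,
        )
        by_span = combination_enrichment(peak_seqs, bg, pwms, span=300)
        by_copresence = combination_enrichment(peak_seqs, bg, pwms,
                                               span=10_000)
        merged = by_span.merge(by_copresence, on="motif_ids",
                               suffixes=("_a", "_b"))
        assert (merged["k_peak_a"] == merged["k_peak_b"]).all()
        assert (merged["k_bg_a"] == merged["k_bg_b"]).all()

    def test_single_motif_enrichment_planted(self, rng):
        pwms = default_motif_set(n=6)
        consensus = pwms[0].consensus()
        peak_seqs = []
        for i in range(200):
            seq = list(random_sequence(rng, 400))
            if i < 160:  # 80% planted
                seq[100: 100 + len(consensus)] = consensus
            peak_seqs.append((f"p{i}", "".join(seq)))
        bg = BackgroundSet(
            [(f"bg_{i}", random_sequence(rng, 400)) for i in range(1000)],
            400, 3,
        )
        df = single_motif_enrichment(peak_seqs, bg, pwms)
        top = df.iloc[0]
        assert top["motif_id"] == "M01"
        assert top["p"] < 1e-50
        assert top["odds_ratio"] > 10

    def test_absent_motif_p_one(self, rng):
        pwms = default_motif_set(n=4)
        # sequences too short to contain any hit
        peak_seqs = [(f"p{i}", "ACGT") for i in range(10)]
        bg = BackgroundSet([(f"bg_{i}", "ACGT") for i in range(10)], 4, 0)
        df = single_motif_enrichment(peak_seqs, bg, pwms)
        assert (df["p"] == 1.0).all()


class TestGroupHits:
    def test_spans_sorted_per_motif(self, rng):
        pwm = default_motif_set(n=1)[0]
        consensus = pwm.consensus()
        seq = consensus + "ACGTACGTAC" + consensus
        hits = scan_sequence(seq, pwm, 0.9, sequence_id="s1")
        grouped = group_hits(hits, {pwm.motif_id: len(pwm)})
        spans = grouped["s1"][pwm.motif_id]
        assert spans == sorted(spans)
        assert len(spans) == 2
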