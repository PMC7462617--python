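"""ATAC branch: merging, classification, counting, DA, annotation."""

import numpy as np
import pytest
from scipy import stats

from chromcouple.accessibility import (
    ConsensusPeakSet,
    annotate_peaks,
    assign_counts_to_peaks,
    classify_peaks,
    count_reads_in_peaks,
    differential_accessibility,
    merge_replicate_peaks,
    tss_overrepresentation,
    PeakAnnotation,
)
from chromcouple.formats import GenomicInterval, GeneRecord, NarrowPeak
from tests.conftest import make_count_table


def _peaks(*spans, chrom="chr1"):
    return [
        NarrowPeak(GenomicInterval(chrom, s, e), name=f"p{s}_{e}")
        for s, e in spans
    ]


class TestMerge:
    def test_identical_replicates(self):
        reps = [_peaks((100, 200), (500, 700)) for _ in range(3)]
        consensus = merge_replicate_peaks(reps, min_support=2)
        spans = [(p.start, p.end) for p in consensus.peaks]
        assert spans == [(100, 200), (500, 700)]
        assert set(consensus.support_of_peak.values()) == {3}

    def test_overlapping_replicates_union(self):
        consensus = merge_replicate_peaks(
            [_peaks((100, 200)), _peaks((150, 300))], min_support=2
        )
        (peak,) = consensus.peaks
        assert (peak.start, peak.end) == (100, 300)
        assert consensus.support_of_peak[peak.name] == 2

    def test_min_support_filters(self):
        reps = [_peaks((100, 200), (500, 600)), _peaks((100, 200))]
        consensus = merge_replicate_peaks(reps, min_support=2)
        assert [(p.start, p.end) for p in consensus.peaks] == [(100, 200)]

    def test_min_support_exceeds_replicates(self):
        with pytest.raises(ValueError):
            merge_replicate_peaks([_peaks((0, 10))], min_support=2)

    def test_merge_is_idempotent(self, rng):
        starts = np.sort(rng.choice(100_000, size=50, replace=False)) * 10
        reps = [
            _peaks(*[(int(s), int(s) + 400) for s in starts]),
            _peaks(*[(int(s) - 20, int(s) + 380) for s in starts]),
        ]
        consensus = merge_replicate_peaks(reps, min_support=2)
        again = merge_replicate_peaks([consensus.peaks], min_support=1)
        assert [(p.start, p.end) for p in again.peaks] == [
            (p.start, p.end) for p in consensus.peaks
        ]

    def test_consensus_count_matches_truth_loci(self):
        from chromcouple.synthetic import SimulationConfig, generate_peak_sets

        cfg = SimulationConfig(
            seed=5, chrom_lengths={"chr1": 2_000_000}, n_genes=10,
            n_peaks=500, frac_shared=1.0, frac_exclusive_A=0.0,
            frac_exclusive_B=0.0,
        )
        replicates, truth = generate_peak_sets(cfg)
        consensus = merge_replicate_peaks(replicates["A"], min_support=2)
        assert len(consensus.peaks) == len(truth.peak_class_truth)


class TestClassify:
    def test_identical_sets_all_shared(self):
        a = merge_replicate_peaks([_peaks((0, 100), (500, 600))], 1, "A")
        b = merge_replicate_peaks([_peaks((0, 100), (500, 600))], 1, "B")
        pooled, cls = classify_peaks(a, b)
        assert cls.fractions()["shared"] == 1.0

    def test_disjoint_sets_no_shared(self):
        a = merge_replicate_peaks([_peaks((0, 100))], 1, "A")
        b = merge_replicate_peaks([_peaks((500, 600))], 1, "B")
        pooled, cls = classify_peaks(a, b)
        counts = cls.counts()
        assert counts == {"shared": 0, "exclusive_A": 1, "exclusive_B": 1}

    def test_conservation_and_truth_recovery(self):
        from chromcouple.synthetic import SimulationConfig, generate_peak_sets

        cfg = SimulationConfig(
            seed=11, chrom_lengths={"chr1": 3_000_000}, n_peaks=1000,
            frac_shared=0.9, frac_exclusive_A=0.05, frac_exclusive_B=0.05,
        )
        replicates, truth = generate_peak_sets(cfg)
        cons_A = merge_replicate_peaks(replicates["A"], 2, "A")
        cons_B = merge_replicate_peaks(replicates["B"], 2, "B")
        pooled, cls = classify_peaks(cons_A, cons_B)
        counts = cls.counts()
        assert sum(counts.values()) == len(pooled.peaks)
        assert counts == {"shared": 900, "exclusive_A": 50,
                          "exclusive_B": 50}
        # every pooled peak's class matches the truth of the locus whose
        # summit it covers (jitter is far smaller than the peak width)
        truth_by_pos = {
            (iv.chrom, truth.peak_summit[lid]): truth.peak_class_truth[lid]
            for lid, iv in truth.peak_locus.items()
        }
        for peak in pooled.peaks:
            matches = [
                klass
                for (chrom, summit), klass in truth_by_pos.items()
                if chrom == peak.chrom and peak.start <= summit < peak.end
            ]
            assert len(matches) == 1
            assert cls.class_of_peak[peak.name] == matches[0]

    def test_empty_pooled_is_error(self):
        a = ConsensusPeakSet("A", [])
        b = ConsensusPeakSet("B", [])
        with pytest.raises(ValueError):
            classify_peaks(a, b)


class TestCounting:
    def test_no_fragments_all_zero(self):
        pooled = ConsensusPeakSet("pooled", _peaks((0, 100)))
        table = count_reads_in_peaks(
            pooled, {"A_rep1": [], "B_rep1": []},
            {"A_rep1": "A", "B_rep1": "B"},
        )
        assert table.counts.to_numpy().sum() == 0

    def test_midpoint_containment(self):
        pooled = ConsensusPeakSet("pooled", _peaks((100, 200)))
        frags = [
            GenomicInterval("chr1", 90, 130),   # midpoint 110 inside
            GenomicInterval("chr1", 150, 170),  # inside
            GenomicInterval("chr1", 190, 230),  # midpoint 210 outside
        ]
        table = count_reads_in_peaks(
            pooled, {"A_rep1": frags, "B_rep1": []},
            {"A_rep1": "A", "B_rep1": "B"},
        )
        assert table.counts.iloc[0, 0] == 2

    def test_matches_brute_force_on_random_fragments(self, rng):
        starts = np.sort(rng.choice(2_000, size=80, replace=False)) * 500
        peaks = _peaks(*[(int(s), int(s) + 300) for s in starts])
        pooled = ConsensusPeakSet("pooled", peaks)
        frags = []
        for _ in range(10_000):
            s = int(rng.integers(0, 1_000_000))
            frags.append(GenomicInterval("chr1", s, s + int(rng.integers(1, 400))))
        table = count_reads_in_peaks(
            pooled, {"A_rep1": frags, "B_rep1": []},
            {"A_rep1": "A", "B_rep1": "B"},
        )
        # O(n*m) brute force
        for peak in peaks:
            expected = sum(
                1 for f in frags if peak.start <= f.midpoint < peak.end
            )
            assert table.counts.at[peak.name, "A_rep1"] == expected

    def test_unknown_chrom_skipped_with_warning(self):
        pooled = ConsensusPeakSet("pooled", _peaks((0, 100)))
        with pytest.warns(UserWarning, match="skipped"):
            table = count_reads_in_peaks(
                pooled,
                {"A_rep1": [GenomicInterval("chrUn", 10, 20)],
                 "B_rep1": []},
                {"A_rep1": "A", "B_rep1": "B"},
            )
        assert table.counts.attrs["skipped_fragments"] == 1

    def test_atlas_counts_rekeyed_by_overlap(self):
        pooled = ConsensusPeakSet("pooled", _peaks((100, 500)))
        atlas = make_count_table(
            [[7, 8], [100, 200]],
            feature_ids=["chr1:120-480", "chr2:0-100"],
            samples=["A_rep1", "B_rep1"],
            groups={"A_rep1": "A", "B_rep1": "B"},
        )
        rekeyed = assign_counts_to_peaks(pooled, atlas)
        assert rekeyed.counts.loc[pooled.peaks[0].name].tolist() == [7, 8]


class TestDifferentialAccessibility:
    def test_label_swap_negates_m(self, rng):
        mu = 2 ** rng.uniform(6, 10, size=200)
        mat = np.column_stack(
            [rng.poisson(mu) for _ in range(3)]
            + [rng.poisson(mu * 2) for _ in range(3)]
        )
        table = make_count_table(mat)
        res, _ = differential_accessibility(table)
        from chromcouple.formats import CountTable

        swapped = CountTable(
            table.counts.copy(),
            {s: ("B" if g == "A" else "A") for s, g in table.groups.items()},
        )
        res2, _ = differential_accessibility(swapped)
        assert res2["log2fc"].to_numpy() == pytest.approx(
            -res["log2fc"].to_numpy(), abs=1e-9
        )

    def test_planted_shift_recovered(self, rng):
        n, frac = 2000, 0.1
        mu = 2 ** rng.uniform(8, 12, size=n)
        shift = np.ones(n)
        planted = rng.choice(n, size=int(n * frac), replace=False)
        shift[planted] = 4.0  # log2fc = 2
        cols = []
        for m in (mu * shift, mu * shift, mu * shift, mu, mu, mu):
            r = 1 / 0.1
            cols.append(rng.negative_binomial(r, r / (r + m)))
        table = make_count_table(np.column_stack(cols))
        res, significant = differential_accessibility(table,
                                                      fdr_threshold=0.1)
        sig_idx = {int(s[1:]) for s in
                   (f.replace("g", "") for f in significant)}
        planted_ids = {
            table.feature_ids[i] for i in planted
        }
        recovered = len(set(significant) & planted_ids)
        assert recovered / len(planted_ids) >= 0.8
        false = len(set(significant) - planted_ids)
        assert false / max(len(significant), 1) <= 0.15


class TestAnnotation:
    def test_summit_at_tss(self, gene_factory):
        peaks = ConsensusPeakSet(
            "pooled",
            [NarrowPeak(GenomicInterval("chr1", 900, 1100), name="p1",
                        summit_offset=100)],
        )
        genes = [gene_factory("g1", "chr1", 1000, 3000, "+")]
        (ann,) = annotate_peaks(peaks, genes)
        assert ann.nearest_gene == "g1"
        assert ann.signed_distance == 0
        assert ann.category == "tss_proximal"

    def test_window_boundary_excludes(self, gene_factory):
        peaks = ConsensusPeakSet(
            "pooled",
            [NarrowPeak(GenomicInterval("chr1", 0, 200), name="p1",
                        summit_offset=100)],
        )
        inside = [gene_factory("g1", "chr1", 150_100, 152_000, "+")]
        outside = [gene_factory("g1", "chr1", 150_101, 152_000, "+")]
        assert annotate_peaks(peaks, inside)[0].nearest_gene == "g1"
        assert annotate_peaks(peaks, outside)[0].nearest_gene is None

    def test_signed_distance_respects_strand(self, gene_factory):
        peaks = ConsensusPeakSet(
            "pooled",
            [NarrowPeak(GenomicInterval("chr1", 4_900, 5_100), name="p1",
                        summit_offset=100)],
        )
        plus = [gene_factory("g1", "chr1", 8_000, 9_000, "+")]
        minus = [gene_factory("g1", "chr1", 1_000, 2_001, "-")]
        assert annotate_peaks(peaks, plus)[0].signed_distance == -3_000
        assert annotate_peaks(peaks, minus)[0].signed_distance == -3_000

    def test_matches_brute_force(self, rng):
        for trial in range(20):
            r = np.random.default_rng(1000 + trial)
            peaks = [
                NarrowPeak(
                    GenomicInterval("chr1", int(s), int(s) + 200),
                    name=f"p{i}", summit_offset=100,
                )
                for i, s in enumerate(
                    np.sort(r.choice(12_500, size=500, replace=False)) * 400
                )
            ]
            genes = [
                GeneRecord(
                    f"g{j:03d}",
                    GenomicInterval(
                        "chr1", int(t), int(t) + 1000,
                        "+" if r.random() < 0.5 else "-",
                    ),
                )
                for j, t in enumerate(
                    np.sort(r.choice(5_000_000, size=200, replace=False))
                )
            ]
            pooled = ConsensusPeakSet("pooled", peaks)
            annotations = annotate_peaks(pooled, genes, window=150_000)
            for peak, ann in zip(peaks, annotations):
                best = None
                for g in genes:
                    d = abs(peak.summit - g.tss)
                    if d > 150_000:
                        continue
                    if (
                        best is None
                        or d < best[0]
                        or (d == best[0] and g.gene_id < best[1].gene_id)
                    ):
                        best = (d, g)
                if best is None:
                    assert ann.nearest_gene is None
                else:
                    assert ann.nearest_gene == best[1].gene_id


class TestTssOverrepresentation:
    def _ann(self, n_prox, n_other):
        out = []
        for i in range(n_prox):
            out.append(PeakAnnotation(f"p{i}", "g", 0, "tss_proximal"))
        for i in range(n_other):
            out.append(PeakAnnotation(f"q{i}", "g", 5000, "intergenic"))
        return out

    def test_equal_proportions_odds_one(self):
        odds, p = tss_overrepresentation(self._ann(10, 90), self._ann(10, 90))
        assert odds == pytest.approx(1.0)

    def test_most_extreme_table(self):
        odds, p = tss_overrepresentation(self._ann(2, 0), self._ann(0, 2))
        assert p == pytest.approx(1 / 6)

    def test_matches_hypergeometric_oracle(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            if (a + b) == 0 or (c + d) == 0:
                continue
            annA = self._ann(a, b)
            annB = self._ann(c, d)
            _, p = tss_overrepresentation(annA, annB)
            if (a + c) == 0 or (b + d) == 0:
                assert p == 1.0
                continue
            expected = stats.hypergeom.sf(
                a - 1, a + b + c + d, a + c, a + b
            )
            assert p == pytest.approx(expected, abs=1e-12)
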