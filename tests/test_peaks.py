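"""Interval algebra: Jaccard, A/B/C partitioning, gene assignment."""

import numpy as np
import pytest

from bindscape.intervals import GenomicInterval, PeakSet, read_bed
from bindscape.peaks import (
    GeneModel,
    assign_genes,
    classify_targets,
    jaccard,
    jaccard_matrix,
    partition_gene_sets,
    regulatory_domains,
)
from bindscape.simulate import PeakSimConfig, simulate_peak_universe

from _oracles import bp_jaccard, gene_domains_per_bp


def iv(chrom, start, end, name=None):
    return GenomicInterval(chrom, start, end, name=name)


class TestJaccard:
    def test_identity_is_one(self):
        a = PeakSet("a", [iv("chr1", 0, 100), iv("chr2", 50, 80)])
        b = PeakSet("b", [iv("chr1", 0, 100), iv("chr2", 50, 80)])
        assert jaccard(a, b) == 1.0

    def test_half_overlap(self):
        a = PeakSet("a", [iv("chr1", 0, 100)])
        b = PeakSet("b", [iv("chr1", 50, 150)])
        assert jaccard(a, b) == pytest.approx(50 / 150)

    def test_both_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            jaccard(PeakSet("a", []), PeakSet("b", []))

    def test_matches_per_bp_oracle_on_random_sets(self):
        rng = np.random.default_rng(11)
        chroms = ["chr1", "chr2"]
        for _ in range(100):
            def random_set(label):
                ivs = []
                for _ in range(rng.integers(1, 15)):
                    c = chroms[rng.integers(2)]
                    s = int(rng.integers(0, 9900))
                    e = s + int(rng.integers(1, 400))
                    ivs.append(iv(c, s, min(e, 10000)))
                return PeakSet(label, ivs)

            a, b = random_set("a"), random_set("b")
            expected = bp_jaccard(
                [(i.chrom, i.start, i.end) for i in a],
                [(i.chrom, i.start, i.end) for i in b],
                10000,
                chroms,
            )
            got = jaccard(a, b)
            assert got == pytest.approx(expected, abs=1e-12)
            assert got == pytest.approx(jaccard(b, a))
            assert 0.0 <= got <= 1.0


class TestJaccardMatrix:
    def test_identical_sets_all_one(self):
        s = [PeakSet(f"s{i}", [iv("chr1", 0, 50)]) for i in range(3)]
        m = jaccard_matrix(s)
        assert np.allclose(m.values, 1.0)

    def test_disjoint_sets_zero_off_diagonal(self):
        s = [
            PeakSet("a", [iv("chr1", 0, 10)]),
            PeakSet("b", [iv("chr1", 20, 30)]),
            PeakSet("c", [iv("chr2", 0, 10)]),
        ]
        m = jaccard_matrix(s)
        off = m.values[~np.eye(3, dtype=bool)]
        assert np.all(off == 0.0)
        assert np.all(np.diag(m.values) == 1.0)

    def test_matches_elementwise_jaccard(self):
        rng = np.random.default_rng(3)
        sets = []
        for k in range(4):
            ivs = [
                iv("chr1", int(s), int(s) + 100)
                for s in rng.integers(0, 5000, size=5) * 2
            ]
            sets.append(PeakSet(f"s{k}", ivs))
        m = jaccard_matrix(sets)
        for i in range(4):
            for j in range(4):
                assert m.values[i, j] == pytest.approx(jaccard(sets[i], sets[j]))

    def test_empty_set_flagged_not_zero(self):
        s = [PeakSet("a", [iv("chr1", 0, 10)]), PeakSet("b", []),
             PeakSet("c", [iv("chr1", 5, 15)])]
        m = jaccard_matrix(s)
        assert "b" in m.flagged
        assert np.isnan(m.values[0, 1]) and np.isnan(m.values[1, 0])
        assert m.values[0, 2] > 0


class TestClassifyTargets:
    def test_constructed_example(self):
        wt = PeakSet("WT", [iv("chr1", 0, 100, "p1"), iv("chr1", 200, 300, "p2"),
                            iv("chr1", 400, 500, "p3")], merge=False)
        var = PeakSet("V", [iv("chr1", 250, 350, "p2x"),
                            iv("chr1", 700, 800, "p4")], merge=False)
        part = classify_targets(wt, var)
        assert [p.name for p in part.a_peaks] == ["p1", "p3"]
        assert [p.name for p in part.b_peaks] == ["p2"]
        assert [p.name for p in part.c_peaks] == ["p4"]
        assert [p.name for p in part.b_peaks_variant] == ["p2x"]

    def test_variant_equals_wt(self):
        ivs = [iv("chr1", 0, 100), iv("chr2", 10, 60)]
        part = classify_targets(PeakSet("WT", ivs), PeakSet("V", ivs))
        assert len(part.a_peaks) == 0 and len(part.c_peaks) == 0
        assert len(part.b_peaks) == 2

    def test_partition_invariants(self):
        rng = np.random.default_rng(5)
        wt = PeakSet("WT", [iv("chr1", int(s), int(s) + 50)
                            for s in rng.integers(0, 9000, 20) * 1])
        var = PeakSet("V", [iv("chr1", int(s), int(s) + 50)
                            for s in rng.integers(0, 9000, 20)])
        part = classify_targets(wt, var)
        assert len(part.a_peaks) + len(part.b_peaks) == len(wt)
        a_set = {(p.chrom, p.start, p.end) for p in part.a_peaks}
        b_set = {(p.chrom, p.start, p.end) for p in part.b_peaks}
        assert not a_set & b_set
        # reordering input intervals does not change the partition
        wt2 = PeakSet("WT", list(reversed(wt.intervals)), merge=False)
        wt2.intervals.sort()
        part2 = classify_targets(wt2, var)
        assert {p.name for p in part2.a_peaks} == {p.name for p in part.a_peaks}

    def test_min_overlap_validation(self):
        with pytest.raises(ValueError):
            classify_targets(PeakSet("a", [iv("chr1", 0, 10)]),
                             PeakSet("b", []), min_overlap_bp=0)

    def test_min_overlap_threshold_behavior(self):
        wt = PeakSet("WT", [iv("chr1", 0, 100)])
        var = PeakSet("V", [iv("chr1", 95, 200)])  # 5 bp overlap
        assert len(classify_targets(wt, var, min_overlap_bp=5).b_peaks) == 1
        assert len(classify_targets(wt, var, min_overlap_bp=6).b_peaks) == 0

    def test_recovers_planted_truth(self):
        uni = simulate_peak_universe(
            PeakSimConfig(n_shared=30, n_lost=10, n_gained=8, seed=42)
        )
        part = classify_targets(uni.wt, uni.variant)
        got = {p.name: "lost" for p in part.a_peaks}
        got.update({p.name: "shared" for p in part.b_peaks})
        got.update({p.name: "gained" for p in part.c_peaks})
        assert got == uni.truth


class TestAssignGenes:
    def test_basal_domain_arithmetic(self):
        genes = [GeneModel("g1", "chr1", 10000, "+")]
        peaks = PeakSet("p", [iv("chr1", 3900, 4100, "p1")], merge=False)
        assignment = assign_genes(peaks, genes)
        assert assignment[peaks.intervals[0]] == {"g1"}  # midpoint 4000 in basal

    def test_beyond_max_extension_unassigned(self):
        genes = [GeneModel("g1", "chr1", 10000, "+")]
        peaks = PeakSet("p", [iv("chr1", 209900, 210100, "p1")], merge=False)
        assignment = assign_genes(peaks, genes)
        assert assignment[peaks.intervals[0]] == set()

    def test_strand_flips_basal_asymmetry(self):
        # neighbour B's basal edge depends on its strand and caps A's extension
        a = GeneModel("a", "chr1", 50000, "+")
        dom_plus = regulatory_domains([a, GeneModel("b", "chr1", 60000, "+")])
        dom_minus = regulatory_domains([a, GeneModel("b", "chr1", 60000, "-")])
        assert dom_plus["a"][1] == 60000 - 6500  # B basal starts 6.5 kb upstream
        assert dom_minus["a"][1] == 60000 - 2500  # on '-', 2.5 kb is upstream side

    def test_matches_per_bp_domain_oracle(self):
        gene_tuples = [("g1", 20000, "+"), ("g2", 60000, "-"), ("g3", 64000, "+")]
        genes = [GeneModel(g, "chr1", t, s) for g, t, s in gene_tuples]
        oracle = gene_domains_per_bp(gene_tuples, 130000)
        rng = np.random.default_rng(8)
        mids = np.unique(rng.integers(50, 129950, size=300))
        peaks = PeakSet(
            "p",
            [iv("chr1", int(m) - 50, int(m) + 50, f"pk{j}")
             for j, m in enumerate(mids)],
            merge=False,
        )
        assignment = assign_genes(peaks, genes)
        for pk in peaks:
            assert assignment[pk] == oracle[pk.midpoint], pk.midpoint
        # every bp covered by at most 2 extensions plus overlapping basals
        assert max(len(s) for s in oracle) <= 3

    def test_unknown_chromosome_warns_and_skips(self):
        genes = [GeneModel("g1", "chrX", 1000, "+")]
        peaks = PeakSet("p", [iv("chr1", 0, 100, "p1")], merge=False)
        with pytest.warns(UserWarning, match="chrX"):
            assignment = assign_genes(peaks, genes)
        assert assignment[peaks.intervals[0]] == set()


class TestPartitionGeneSets:
    def test_all_unassigned_gives_empty_sets(self):
        wt = PeakSet("WT", [iv("chr1", 0, 100, "p1")], merge=False)
        var = PeakSet("V", [iv("chr1", 500, 600, "p2")], merge=False)
        part = classify_targets(wt, var)
        part = partition_gene_sets(part, {})
        assert part.a_genes == part.b_genes == part.c_genes == set()

    def test_one_gene_per_peak(self):
        wt = PeakSet("WT", [iv("chr1", 0, 100, "p1"), iv("chr1", 300, 400, "p2")],
                     merge=False)
        var = PeakSet("V", [iv("chr1", 320, 420, "p2x"),
                            iv("chr1", 800, 900, "p3")], merge=False)
        part = classify_targets(wt, var)
        assignment = {pk: {f"gene_{pk.name}"} for pk in
                      list(wt) + list(var)}
        part = partition_gene_sets(part, assignment)
        assert part.a_genes == {"gene_p1"}
        assert part.b_genes == {"gene_p2", "gene_p2x"}
        assert part.c_genes == {"gene_p3"}

    def test_gene_set_sizes_match_on_one_gene_per_planted_peak(self):
        uni = simulate_peak_universe(
            PeakSimConfig(n_shared=12, n_lost=6, n_gained=4, seed=7)
        )
        part = classify_targets(uni.wt, uni.variant)
        assignment = {
            pk: {f"gene_{pk.name}"} for pk in list(uni.wt) + list(uni.variant)
        }
        part = partition_gene_sets(part, assignment)
        assert len(part.a_genes) == len(part.a_peaks)
        assert len(part.c_genes) == len(part.c_peaks)
        # shared peaks are the same interval in both alleles
        assert len(part.b_genes) == len(part.b_peaks)


class TestBedIO:
    def test_roundtrip(self, tmp_path):
        ivs = [iv("chr1", 0, 100, "p1"), iv("chr2", 50, 80, "p2")]
        ps = PeakSet("WT", ivs, merge=False)
        path = tmp_path / "x.bed"
        ps.to_bed(path)
        back = read_bed(path)
        assert [(b.chrom, b.start, b.end, b.name) for b in back] == [
            ("chr1", 0, 100, "p1"), ("chr2", 50, 80, "p2")
        ]

    def test_adjacent_intervals_merge(self):
        ps = PeakSet("a", [iv("chr1", 0, 50), iv("chr1", 50, 100)])
        assert len(ps) == 1 and ps.intervals[0].end == 100
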