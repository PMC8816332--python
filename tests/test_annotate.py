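"""Peak-to-gene assignment rule, location classes, gene-set overlap test."""

import numpy as np
import pytest

from tadakit.annotate import (
    AnnotationConfig,
    assign_peaks_to_genes,
    classify_location,
    gene_set_overlap_test,
    location_summary,
    promoter_regions,
)
from tadakit.genome import GeneModel, GenomeIndex, GenomicInterval


def gene_plus(tss=10_000, tes=12_000, chrom="chr1", gene_id="g"):
    return GeneModel(gene_id, chrom, "+", tss, tes)


def gene_minus(tss=12_000, tes=10_000, chrom="chr1", gene_id="g"):
    return GeneModel(gene_id, chrom, "-", tss, tes)


class TestAssignment:
    @pytest.mark.parametrize(
        "center,expected",
        [
            (10_000 - 5_999, True),  # 5999 bp upstream: inside the 6 kb rule
            (10_000 - 6_001, False),  # 6001 bp upstream: outside
            (10_000 - 6_000, True),  # boundary inclusive (up to 6 kb)
            (12_000 + 1_000, True),  # 1 kb downstream of TES
            (12_000 + 1_001, False),
        ],
    )
    def test_distance_rule_boundaries(self, center, expected):
        peak = GenomicInterval("chr1", center - 10, center + 11)  # center as given
        assert peak.center == center
        assigned, unassigned = assign_peaks_to_genes([peak], [gene_plus()])
        assert bool(assigned) is expected
        assert bool(unassigned) is not expected

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(51)
        genes = []
        for i in range(20):
            s = int(rng.integers(10_000, 480_000))
            e = s + int(rng.integers(1_000, 5_000))
            strand = "+" if rng.random() < 0.5 else "-"
            tss, tes = (s, e) if strand == "+" else (e, s)
            genes.append(GeneModel(f"g{i}", "chr1", strand, tss, tes))
        peaks = []
        for i in range(50):
            s = int(rng.integers(0, 490_000))
            peaks.append(GenomicInterval("chr1", s, s + int(rng.integers(200, 2_000)),
                                         name=f"p{i}"))
        assigned, _ = assign_peaks_to_genes(peaks, genes)
        got = {(a.peak_name, a.gene_id) for a in assigned}
        expected = set()
        for p in peaks:
            c = (p.start + p.end) // 2
            for g in genes:
                if g.strand == "+":
                    ok = g.tss - 6000 <= c <= g.tes + 1000
                else:
                    ok = g.tes - 1000 <= c <= g.tss + 6000
                if ok:
                    expected.add((p.name, g.gene_id))
        assert got == expected

    def test_every_peak_assigned_or_unassigned_exactly_once(self):
        rng = np.random.default_rng(53)
        genes = [gene_plus(tss=50_000, tes=55_000)]
        peaks = [
            GenomicInterval("chr1", int(s), int(s) + 500, name=f"p{i}")
            for i, s in enumerate(rng.integers(0, 100_000, 40))
        ]
        assigned, unassigned = assign_peaks_to_genes(peaks, genes)
        assigned_names = {a.peak_name for a in assigned}
        unassigned_names = {p.name for p in unassigned}
        assert assigned_names | unassigned_names == {p.name for p in peaks}
        assert not (assigned_names & unassigned_names)

    def test_single_closest_gene_mode(self):
        g1 = gene_plus(tss=10_000, tes=12_000, gene_id="near")
        g2 = gene_plus(tss=13_000, tes=15_000, gene_id="far")
        peak = GenomicInterval("chr1", 9_400, 9_600, name="p")  # 500 up of g1
        cfg = AnnotationConfig(allow_multiple=False)
        assigned, _ = assign_peaks_to_genes([peak], [g1, g2], cfg)
        assert [a.gene_id for a in assigned] == ["near"]

    def test_strand_mirror_invariance(self):
        """Reverse-complementing the chromosome must preserve assignment
        counts and location classes."""
        length = 100_000
        rng = np.random.default_rng(55)
        genes, peaks = [], []
        for i in range(10):
            s = int(rng.integers(10_000, 80_000))
            e = s + int(rng.integers(1_000, 4_000))
            strand = "+" if rng.random() < 0.5 else "-"
            tss, tes = (s, e) if strand == "+" else (e, s)
            genes.append(GeneModel(f"g{i}", "chr1", strand, tss, tes))
        for i in range(30):
            s = int(rng.integers(0, 95_000))
            peaks.append(GenomicInterval("chr1", s, s + 800, name=f"p{i}"))

        def mirror_gene(g):
            strand = "-" if g.strand == "+" else "+"
            return GeneModel(g.gene_id, g.chrom, strand,
                             length - 1 - g.tss, length - 1 - g.tes)

        def mirror_peak(p):
            return GenomicInterval(p.chrom, length - p.end, length - p.start, name=p.name)

        a1, u1 = assign_peaks_to_genes(peaks, genes)
        a2, u2 = assign_peaks_to_genes([mirror_peak(p) for p in peaks],
                                       [mirror_gene(g) for g in genes])
        assert len(a1) == len(a2) and len(u1) == len(u2)
        c1 = sorted((a.peak_name, a.gene_id, a.location) for a in a1)
        c2 = sorted((a.peak_name, a.gene_id, a.location) for a in a2)
        assert c1 == c2


class TestClassifyLocation:
    def test_peak_inside_single_intron(self):
        g = GeneModel("g", "chr1", "+", 1000, 4999,
                      exons=((1000, 2000), (3000, 5000)))
        peak = GenomicInterval("chr1", 2200, 2800)
        assert classify_location(peak, g) == "intron_only"

    def test_peak_inside_exon(self):
        g = GeneModel("g", "chr1", "+", 1000, 4999,
                      exons=((1000, 2000), (3000, 5000)))
        assert classify_location(GenomicInterval("chr1", 1200, 1800), g) == "exon_only"

    def test_minus_strand_tss_overlap_and_sign(self):
        g = gene_minus()
        peak = GenomicInterval("chr1", 11_900, 12_100)  # spans TSS at 12000
        assert classify_location(peak, g) == "overlapping_TSS"
        assigned, _ = assign_peaks_to_genes([peak], [g])
        assert assigned[0].distance == 12_000 - peak.center

    def test_precedence_tss_over_tes_for_engulfing_peak(self):
        g = gene_plus(tss=10_000, tes=10_500)
        peak = GenomicInterval("chr1", 9_000, 12_000)
        assert classify_location(peak, g) == "overlapping_TSS"

    def test_matches_coordinate_arithmetic_oracle(self):
        rng = np.random.default_rng(57)
        for _ in range(200):
            gs = int(rng.integers(5_000, 20_000))
            ge = gs + int(rng.integers(2_000, 6_000))
            strand = "+" if rng.random() < 0.5 else "-"
            tss, tes = (gs, ge - 1) if strand == "+" else (ge - 1, gs)
            n_ex = int(rng.integers(1, 4))
            cuts = np.sort(rng.choice(np.arange(gs + 1, ge), 2 * n_ex - 2, replace=False))
            edges = np.concatenate([[gs], cuts, [ge]])
            exons = tuple((int(edges[2 * j]), int(edges[2 * j + 1])) for j in range(n_ex))
            g = GeneModel("g", "chr1", strand, tss, tes, exons)
            ps = int(rng.integers(0, 30_000))
            peak = GenomicInterval("chr1", ps, ps + int(rng.integers(100, 3_000)))
            got = classify_location(peak, g)
            # independent oracle on bp sets
            span = set(range(peak.start, peak.end))
            exon_bp = set()
            for s, e in exons:
                exon_bp |= set(range(s, e))
            body = set(range(gs, ge))
            if tss in span:
                want = "overlapping_TSS"
            elif tes in span:
                want = "overlapping_TES"
            elif span <= body:
                if span <= exon_bp:
                    want = "exon_only"
                elif span <= (body - exon_bp):
                    want = "intron_only"
                else:
                    want = "within_gene"
            else:
                c = peak.center
                before_tss = c < tss if strand == "+" else c > tss
                want = "upstream" if before_tss else "downstream"
            assert got == want, (peak, g)


class TestLocationSummary:
    def test_all_upstream(self):
        g = gene_plus()
        peaks = [GenomicInterval("chr1", 10_000 - d - 100, 10_000 - d + 100)
                 for d in (500, 1500, 3000)]
        assigned, _ = assign_peaks_to_genes(peaks, [g])
        props = location_summary(assigned)
        assert props["upstream"] == pytest.approx(1.0)
        assert props["upstream_within_2kb"] == pytest.approx(2 / 3)

    def test_six_class_fixture_equal_proportions(self):
        g = GeneModel("g", "chr1", "+", 10_000, 19_999,
                      exons=((10_000, 13_000), (16_000, 20_000)))
        peaks = [
            GenomicInterval("chr1", 8_000, 8_500),       # upstream
            GenomicInterval("chr1", 9_900, 10_100),      # overlapping_TSS
            GenomicInterval("chr1", 12_500, 16_500),     # within (exon+intron)
            GenomicInterval("chr1", 14_000, 15_000),     # intron_only
            GenomicInterval("chr1", 11_000, 12_000),     # exon_only
            GenomicInterval("chr1", 19_900, 20_100),     # overlapping_TES
        ]
        assigned, _ = assign_peaks_to_genes(peaks, [g])
        props = location_summary(assigned)
        for cls in ("upstream", "overlapping_TSS", "within_gene", "intron_only",
                    "exon_only", "overlapping_TES"):
            assert props[cls] == pytest.approx(1 / 6)
        classes = [
            "upstream",
            "overlapping_TSS",
            "within_gene",
            "intron_only",
            "exon_only",
            "overlapping_TES",
            "downstream",
        ]
        assert sum(props[c] for c in classes) == pytest.approx(1.0)


class TestPromoterRegions:
    def test_examples_and_clipping(self):
        genome = GenomeIndex.from_lengths({"chr1": 1_000_000})
        plus = gene_plus(tss=10_000, tes=20_000)
        (p,) = promoter_regions([plus], genome)
        assert (p.start, p.end) == (5_000, 10_500)
        minus = gene_minus(tss=10_000, tes=5_000)
        (m,) = promoter_regions([minus], genome)
        assert (m.start, m.end) == (9_500, 15_000)
        near_start = gene_plus(tss=2_000, tes=9_999)
        (c,) = promoter_regions([near_start], genome)
        assert c.start == 0


class TestGeneSetOverlap:
    def test_disjoint_singletons(self):
        # upper-tail P(X >= 0) is exactly 1 for any observed overlap of 0
        k, p = gene_set_overlap_test({"a"}, {"b"}, pool_size=100)
        assert k == 0 and p == pytest.approx(1.0)

    def test_identical_sets_extreme(self):
        genes = {f"g{i}" for i in range(5)}
        k, p = gene_set_overlap_test(genes, genes, pool_size=20_191)
        assert k == 5 and p < 1e-15

    def test_matches_exhaustive_enumeration(self):
        from math import comb

        pool, na, nb, k = 30, 10, 10, 5
        a = {f"g{i}" for i in range(na)}
        b = {f"g{i}" for i in range(na - k, na - k + nb)}
        got_k, got_p = gene_set_overlap_test(a, b, pool_size=pool)
        assert got_k == k
        want = sum(
            comb(na, j) * comb(pool - na, nb - j) for j in range(k, min(na, nb) + 1)
        ) / comb(pool, nb)
        assert got_p == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("pool,na,nb", [(20, 6, 9), (50, 20, 15), (35, 5, 30)])
    def test_enumeration_property_small_pools(self, pool, na, nb):
        from math import comb

        rng = np.random.default_rng(pool * 100 + na)
        universe = [f"g{i}" for i in range(pool)]
        a = set(rng.choice(universe, na, replace=False))
        b = set(rng.choice(universe, nb, replace=False))
        k, p = gene_set_overlap_test(a, b, pool_size=pool)
        want = sum(
            comb(na, j) * comb(pool - na, nb - j)
            for j in range(k, min(na, nb) + 1)
        ) / comb(pool, nb)
        assert p == pytest.approx(want, abs=1e-12)

    def test_fisher_agrees_with_hypergeometric_direction(self):
        a = {f"g{i}" for i in range(40)}
        b = {f"g{i}" for i in range(20, 70)}
        _, p_h = gene_set_overlap_test(a, b, pool_size=500)
        _, p_f = gene_set_overlap_test(a, b, pool_size=500, method="fisher")
        assert p_h == pytest.approx(p_f, rel=1e-6)

    def test_rejects_sets_larger_than_pool(self):
        with pytest.raises(ValueError):
            gene_set_overlap_test({str(i) for i in range(11)}, {"x"}, pool_size=10)
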