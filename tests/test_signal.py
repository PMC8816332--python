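"""Read counting, ratio normalization, replicate averaging, QC, and
sample-level summaries."""

import numpy as np
import pytest

from tadakit.genome import GenomeIndex, GenomicInterval
from tadakit.signal import (
    FragmentCountTrack,
    average_replicates,
    binned_coverage_matrix,
    count_reads_per_fragment,
    normalize_ratio,
    pairwise_ratio_profile,
    qc_reads,
    sample_correlation,
    sample_pca,
)


class TestCounting:
    def test_plus_strand_five_prime(self, toy_map):
        # read [5,40): only the 5' position must lie inside the chromosome
        track = count_reads_per_fragment(
            [GenomicInterval("chr1", 5, 40, strand="+")], toy_map
        )
        assert track.counts.tolist() == [0, 1, 0]

    def test_minus_strand_five_prime(self, toy_map):
        # read [5,12) on - strand: 5' = 11 -> fragment [10,14)
        track = count_reads_per_fragment(
            [GenomicInterval("chr1", 5, 12, strand="-")], toy_map
        )
        assert track.counts.tolist() == [0, 0, 1]

    def test_boundary_five_prime_goes_to_starting_fragment(self, toy_map):
        track = count_reads_per_fragment(
            [GenomicInterval("chr1", 4, 9, strand="+")], toy_map
        )
        assert track.counts.tolist() == [0, 1, 0]

    def test_rejects_out_of_range_reads_with_count(self, toy_map):
        reads = [
            GenomicInterval("chr1", 0, 3, strand="+"),
            GenomicInterval("chrZ", 0, 3, strand="+"),
        ]
        track = count_reads_per_fragment(reads, toy_map)
        assert track.n_rejected == 1
        assert track.library_size == 1

    def test_matches_brute_force_containment(self, uniform_map):
        rng = np.random.default_rng(19)
        fmap = uniform_map
        reads = []
        for _ in range(5000):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            s = int(rng.integers(0, 99_900))
            reads.append(
                GenomicInterval(chrom, s, s + 50, strand="+" if rng.random() < 0.5 else "-")
            )
        track = count_reads_per_fragment(reads, fmap)
        brute = np.zeros(fmap.n_fragments, dtype=int)
        for r in reads:
            p5 = r.five_prime()
            for i in range(fmap.n_fragments):
                if (
                    fmap.chrom_name(i) == r.chrom
                    and fmap.starts[i] <= p5 < fmap.ends[i]
                ):
                    brute[i] += 1
        assert track.counts.tolist() == brute.tolist()
        assert track.library_size == len(reads)  # conservation


class TestNormalizeRatio:
    def _tracks(self, rng, n=600, depth=40):
        counts = rng.poisson(depth, n)
        return counts

    def test_identical_tracks_give_zero(self):
        rng = np.random.default_rng(0)
        c = self._tracks(rng)
        t = FragmentCountTrack("tf", c)
        r = normalize_ratio(t, FragmentCountTrack("ctrl", c.copy()))
        assert np.allclose(r.scores, 0.0, atol=1e-9)

    def test_library_scale_invariance(self):
        rng = np.random.default_rng(1)
        tf, ctrl = self._tracks(rng), self._tracks(rng)
        r1 = normalize_ratio(FragmentCountTrack("a", tf), FragmentCountTrack("b", ctrl))
        r2 = normalize_ratio(FragmentCountTrack("a", tf * 4), FragmentCountTrack("b", ctrl))
        # invariance is exact up to the library-scaled pseudocount term
        assert np.allclose(r1.scores, r2.scores, atol=0.01)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(2)
        tf, ctrl = self._tracks(rng), self._tracks(rng)
        a = normalize_ratio(FragmentCountTrack("a", tf), FragmentCountTrack("b", ctrl))
        b = normalize_ratio(FragmentCountTrack("b", ctrl), FragmentCountTrack("a", tf))
        # swapping negates raw scores; the mode offset negates too
        assert np.allclose(a.scores, -b.scores, atol=0.05)

    def test_known_eightfold_enrichment_recovered(self):
        rng = np.random.default_rng(3)
        n = 4000
        enriched = np.zeros(n, dtype=bool)
        enriched[rng.choice(n, n // 20, replace=False)] = True
        base = rng.poisson(60, n)
        tf = rng.poisson(60 * np.where(enriched, 8.0, 1.0)).astype(int)
        r = normalize_ratio(FragmentCountTrack("tf", tf), FragmentCountTrack("c", base))
        assert abs(r.scores[enriched].mean() - 3.0) < 0.2
        # background mode centred at zero
        assert abs(np.median(r.scores[~enriched])) < 0.1

    def test_all_zero_control_rejected(self):
        with pytest.raises(ValueError):
            normalize_ratio(
                FragmentCountTrack("a", np.ones(10, dtype=int)),
                FragmentCountTrack("b", np.zeros(10, dtype=int)),
            )

    def test_centering_idempotent(self):
        rng = np.random.default_rng(4)
        tf, ctrl = self._tracks(rng), self._tracks(rng)
        r = normalize_ratio(FragmentCountTrack("a", tf), FragmentCountTrack("b", ctrl))
        from tadakit.signal import _score_mode

        assert abs(_score_mode(r.scores[(tf + ctrl) >= 10])) < 0.02


class TestAverageReplicates:
    def test_single_track_identity(self):
        r = average_replicates([_ratio([1.0, -2.0, 3.0])])
        assert r.scores.tolist() == [1.0, -2.0, 3.0]

    def test_linearity_cancellation(self):
        tracks = [_ratio([1, 2]), _ratio([-1, -2]), _ratio([0, 0]), _ratio([0, 0])]
        assert average_replicates(tracks).scores.tolist() == [0.0, 0.0]

    def test_equals_mean_of_explicit_pairwise_tracks(self):
        rng = np.random.default_rng(8)
        tfs = [FragmentCountTrack(f"tf{i}", rng.poisson(50, 500)) for i in range(2)]
        cts = [FragmentCountTrack(f"c{i}", rng.poisson(50, 500)) for i in range(2)]
        prof = pairwise_ratio_profile(tfs, cts)
        explicit = [normalize_ratio(t, c) for t in tfs for c in cts]
        assert np.allclose(prof.scores, np.mean([e.scores for e in explicit], axis=0))

    def test_averaging_reduces_background_variance(self):
        rng = np.random.default_rng(9)
        tfs = [FragmentCountTrack(f"tf{i}", rng.poisson(40, 2000)) for i in range(2)]
        cts = [FragmentCountTrack(f"c{i}", rng.poisson(40, 2000)) for i in range(2)]
        prof = pairwise_ratio_profile(tfs, cts)
        singles = [normalize_ratio(t, c) for t in tfs for c in cts]
        assert prof.scores.std() < min(s.scores.std() for s in singles)

    def test_mismatched_maps_rejected(self):
        with pytest.raises(ValueError):
            average_replicates([_ratio([1, 2]), _ratio([1, 2, 3])])


def _ratio(scores):
    from tadakit.signal import RatioTrack

    return RatioTrack(np.asarray(scores, dtype=float))


class TestQcReads:
    def test_all_starting_gatc(self):
        rep = qc_reads(["GATCAAAA", "GATCTTTT"])
        assert rep.fraction_start_gatc == 1.0
        assert rep.fraction_end_gatc == 0.0

    def test_no_adaptor_anywhere(self):
        rep = qc_reads(["ACGTACGTACGT"], adaptor="GGTCGCGGCCGAG")
        assert rep.fraction_adaptor == 0.0

    def test_planted_adaptor_fraction(self):
        rng = np.random.default_rng(21)
        adaptor = "GGTCGCGGCCGAGGA"
        reads = []
        for i in range(1000):
            body = "".join(rng.choice(list("ACGT"), size=40))
            reads.append(adaptor + body if i < 100 else body)
        rep = qc_reads(rng.permutation(reads).tolist(), adaptor=adaptor)
        assert abs(rep.fraction_adaptor - 0.10) < 0.02

    def test_empty_input_flagged(self):
        rep = qc_reads([])
        assert rep.n_reads == 0 and not rep.valid

    def test_internal_gatc_excludes_read_ends(self):
        rep = qc_reads(["GATCAAGATCAAGATC"])  # start, internal, end
        assert rep.mean_internal_gatc == 1.0


class TestBinnedCoverage:
    def test_identical_samples_identical_columns_and_conservation(self):
        genome = GenomeIndex.from_lengths({"chr1": 1000})
        rng = np.random.default_rng(31)
        reads = [
            GenomicInterval("chr1", int(s), int(s) + 30, strand="+")
            for s in rng.integers(0, 970, 200)
        ]
        mat, bins = binned_coverage_matrix([reads, reads], genome, bin_size=300)
        assert np.array_equal(mat[:, 0], mat[:, 1])
        assert mat.sum(axis=0).tolist() == [200, 200]
        assert bins[-1].end == 1000  # short last bin

    def test_matches_per_bin_brute_force(self):
        genome = GenomeIndex.from_lengths({"chr1": 2000})
        rng = np.random.default_rng(33)
        reads = [
            GenomicInterval("chr1", int(s), int(s) + 10,
                            strand="-" if rng.random() < 0.5 else "+")
            for s in rng.integers(0, 1980, 300)
        ]
        mat, bins = binned_coverage_matrix([reads], genome, bin_size=250)
        brute = np.zeros(len(bins), dtype=int)
        for r in reads:
            p5 = r.five_prime()
            for i, b in enumerate(bins):
                if b.start <= p5 < b.end:
                    brute[i] += 1
        assert mat[:, 0].tolist() == brute.tolist()


class TestCorrelationPca:
    def test_duplicated_and_negated_samples(self):
        rng = np.random.default_rng(41)
        x = rng.normal(0, 1, 500)
        mat = np.column_stack([x, x, -x])
        corr = sample_correlation(mat)
        assert corr[0, 1] == pytest.approx(1.0)
        assert corr[0, 2] == pytest.approx(-1.0)

    def test_zero_variance_sample_reported_missing(self):
        mat = np.column_stack([np.arange(10.0), np.ones(10)])
        corr = sample_correlation(mat)
        assert np.isnan(corr[0, 1])
        assert corr[0, 0] == 1.0

    def test_planted_clusters_separate(self):
        rng = np.random.default_rng(43)
        base1, base2 = rng.normal(0, 1, 400), rng.normal(0, 1, 400)
        cols = [base1 + rng.normal(0, 0.3, 400) for _ in range(3)] + [
            base2 + rng.normal(0, 0.3, 400) for _ in range(3)
        ]
        mat = np.column_stack(cols)
        corr = sample_correlation(mat)
        within = np.mean([corr[i, j] for i in range(3) for j in range(3) if i != j])
        between = np.mean([corr[i, j] for i in range(3) for j in range(3, 6)])
        assert within > between
        coords, evr = sample_pca(mat)
        pc1 = coords[:, 0]
        assert (pc1[:3] > 0).all() != (pc1[3:] > 0).all()  # clusters on opposite sides
        assert evr[0] >= evr[1]
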