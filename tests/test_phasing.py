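"""Bin building, minimum-recombinant phasing and NCO detection."""

import itertools

import numpy as np
import pytest

from dronemap.phasing import (
    Bin,
    build_bins,
    complement,
    contig_end_vectors,
    detect_nco_conversions,
    hamming,
    phase_contig,
)

M = -1  # missing


def vec(*codes):
    return np.array(codes, dtype=np.int8)


def bins_from(vectors, spans, contig="tig"):
    """Build Bin objects at given (first, last) SNP spans."""
    out = []
    for v, (first, last) in zip(vectors, spans):
        out.append(Bin(contig, first, last, max(1, last - first), vec(*v)))
    return out


class TestBuildBins:
    def test_identical_vectors_one_bin(self):
        pos = np.array([10, 20, 30])
        vecs = np.array([[0, 1, 0]] * 3, dtype=np.int8)
        (b,) = build_bins(pos, vecs, "t")
        assert (b.first_snp, b.last_snp, b.n_snps) == (10, 30, 3)

    def test_vector_change_splits_runs(self):
        # five sites with drone patterns AAABB -> bins of 3 and 2 SNPs
        pos = np.arange(5) * 10
        a, b = [0, 0, 1, 1], [0, 1, 0, 1]
        vecs = np.array([a, a, a, b, b], dtype=np.int8)
        bins = build_bins(pos, vecs, "t")
        assert [x.n_snps for x in bins] == [3, 2]
        assert bins[0].last_snp == 20 and bins[1].first_snp == 30

    def test_missing_entry_absorbed_by_wildcard(self):
        pos = np.arange(3) * 10
        vecs = np.array(
            [[0, 1, 0, 1], [0, M, 0, 1], [0, 1, 0, 1]], dtype=np.int8
        )
        bins = build_bins(pos, vecs, "t")
        assert len(bins) == 1 and bins[0].n_snps == 3

    def test_complementary_coding_is_same_observation(self):
        # allele labels are arbitrary per site: a complementary vector
        # still belongs to the same no-crossover segment
        pos = np.arange(2) * 10
        vecs = np.array([[0, 1, 0, 1], [1, 0, 1, 0]], dtype=np.int8)
        assert len(build_bins(pos, vecs, "t")) == 1

    def test_empty_input(self):
        assert build_bins(np.array([]), np.empty((0, 4), dtype=np.int8), "t") == []


def exhaustive_min(bins):
    """Minimum total recombination over all 2^(B-1) phase assignments."""
    best = None
    for flips in itertools.product([False, True], repeat=len(bins) - 1):
        vs = [bins[0].vector] + [
            complement(b.vector) if f else b.vector
            for b, f in zip(bins[1:], flips)
        ]
        total = sum(hamming(a, b) for a, b in zip(vs, vs[1:]))
        best = total if best is None else min(best, total)
    return best


class TestPhaseContig:
    def test_complement_identity(self):
        bins = bins_from([[0, 0, 0, 0], [1, 1, 1, 1]], [(0, 100), (200, 300)])
        pc = phase_contig(bins)
        assert pc.flips == [False, True]
        assert pc.junction_counts == [0]

    def test_three_bin_example(self):
        bins = bins_from(
            [[0, 0, 0, 0], [0, 0, 1, 1], [1, 1, 0, 0]],
            [(0, 100), (200, 300), (400, 500)],
        )
        pc = phase_contig(bins)
        assert [list(b.vector) for b in pc.bins] == [
            [0, 0, 0, 0],
            [0, 0, 1, 1],
            [0, 0, 1, 1],
        ]
        assert pc.junction_counts == [2, 0]
        assert pc.total_recombinations == exhaustive_min(bins)

    def test_greedy_equals_exhaustive_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n_bins = int(rng.integers(1, 11))
            vectors = rng.integers(0, 2, size=(n_bins, 8))
            bins = bins_from(vectors.tolist(), [(i * 10, i * 10 + 5) for i in range(n_bins)])
            pc = phase_contig(bins)
            if n_bins > 1:
                assert pc.total_recombinations == exhaustive_min(bins)

    def test_global_complement_leaves_junction_counts_unchanged(self):
        rng = np.random.default_rng(2)
        vectors = rng.integers(0, 2, size=(6, 10)).tolist()
        spans = [(i * 10, i * 10 + 5) for i in range(6)]
        pc = phase_contig(bins_from(vectors, spans))
        flipped = bins_from(
            [list(complement(vec(*v))) for v in vectors], spans
        )
        pc2 = phase_contig(flipped)
        assert pc.junction_counts == pc2.junction_counts


class TestNcoDetection:
    def test_identical_flanks_merged(self):
        a = [0, 0, 0, 0]
        b = [0, 1, 1, 0]
        bins = bins_from([a, b, a], [(0, 5000), (6000, 7000), (9000, 14000)])
        pc = phase_contig(bins)
        before = pc.total_recombinations
        flagged, merged = detect_nco_conversions(pc)
        assert len(flagged) == 1 and list(flagged[0].vector) == b
        assert len(merged.bins) == 1
        assert merged.bins[0].first_snp == 0 and merged.bins[0].last_snp == 14000
        # junction events drop by 2 x H(A, B)
        assert before - merged.total_recombinations == 2 * hamming(vec(*a), vec(*b))

    def test_excess_event_bin_removed_without_merging(self):
        a, b, c = [0, 0, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1]
        bins = bins_from([a, b, c], [(0, 5000), (6000, 7500), (9000, 14000)])
        pc = phase_contig(bins)
        assert hamming(vec(*a), vec(*b)) + hamming(vec(*b), vec(*c)) > hamming(
            vec(*a), vec(*c)
        )
        flagged, merged = detect_nco_conversions(pc)
        assert len(flagged) == 1
        assert [list(x.vector) for x in merged.bins] == [a, c]

    def test_long_bin_between_identical_flanks_kept(self):
        a, b = [0, 0, 0, 0], [0, 1, 1, 0]
        bins = bins_from([a, b, a], [(0, 5000), (6000, 11000), (12000, 17000)])
        flagged, merged = detect_nco_conversions(phase_contig(bins))
        assert flagged == [] and len(merged.bins) == 3

    def test_terminal_bins_never_flagged(self):
        a, b = [0, 0, 0, 0], [1, 0, 0, 0]
        bins = bins_from([a, b], [(0, 100), (200, 300)])
        flagged, merged = detect_nco_conversions(phase_contig(bins))
        assert flagged == [] and len(merged.bins) == 2

    def test_filtering_never_increases_recombination(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(2, 9))
            vectors = rng.integers(0, 2, size=(n, 6)).tolist()
            spans = []
            p = 0
            for _ in range(n):
                width = int(rng.choice([500, 1500, 5000]))
                spans.append((p, p + width))
                p += width + 100
            pc = phase_contig(bins_from(vectors, spans))
            _, merged = detect_nco_conversions(pc)
            assert merged.total_recombinations <= pc.total_recombinations


class TestEndVectors:
    def test_single_bin_not_orientable(self):
        pc = phase_contig(bins_from([[0, 1, 0]], [(0, 100)]))
        left, right, orientable = contig_end_vectors(pc)
        assert list(left) == list(right) == [0, 1, 0]
        assert not orientable

    def test_two_bins_orientable(self):
        pc = phase_contig(
            bins_from([[0, 1, 0], [0, 0, 0]], [(0, 100), (200, 300)])
        )
        left, right, orientable = contig_end_vectors(pc)
        assert orientable and hamming(left, right) >= 1

    def test_empty_contig_errors(self):
        from dronemap.phasing import PhasedContig

        with pytest.raises(ValueError):
            contig_end_vectors(PhasedContig("t", [], [], []))


def test_orientable_iff_internal_crossover():
    """Error-free check: a contig is orientable exactly when >=1 true
    crossover falls inside it for some drone of the colony."""
    from dronemap.pipeline import run_pipeline
    from dronemap.simulate import SimConfig

    res = run_pipeline(
        SimConfig(
            seed=5,
            genotyping_error_rate=0.0,
            nco_rate=0.0,
            chromosome_lengths=(3_000_000, 3_000_000),
            colonies=((10, 0),),
        )
    )
    layout = res.truth.contig_layout
    for r in layout.itertuples():
        has_truth_co = any(
            ((xo > r.start) & (xo <= r.end)).any()
            for drones in res.truth.crossovers.values()
            for per_chrom in drones.values()
            for chrom, xo in per_chrom.items()
            if chrom == r.chrom
        )
        pc = res.phased.get("colony1", {}).get(r.contig)
        if pc is None:
            continue
        orientable = len(pc.bins) >= 2
        # truth crossovers between the contig's terminal SNPs only
        if orientable:
            assert has_truth_co
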