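"""Junction costs, greedy chaining vs exact solver, placement status and
boundary-repeat orientation."""

import numpy as np
import pytest

from dronemap.io import GenomicInterval, TrfArrayRecord
from dronemap.phasing import complement, hamming
from dronemap.pipeline import (
    adjacency_recovery,
    layout_from_truth,
    run_pipeline,
)
from dronemap.scaffold import (
    ContigEnds,
    ScaffoldLayout,
    classify_placement,
    exhaustive_layout_cost,
    junction_cost,
    layout_total_cost,
    order_and_orient,
    orient_by_boundary_repeats,
    terminal_arrays,
)
from dronemap.simulate import SimConfig, fragment_into_contigs, simulate_colonies


def ends(contig, per_colony, orientable=True, length=1000):
    return ContigEnds(
        contig,
        {c: (np.array(l, dtype=np.int8), np.array(r, dtype=np.int8)) for c, (l, r) in per_colony.items()},
        orientable,
        length,
    )


class TestJunctionCost:
    def test_identical_vectors_zero_cost(self):
        v = [0, 1, 0, 1, 1]
        a = ends("a", {f"c{k}": (v, v) for k in range(3)})
        b = ends("b", {f"c{k}": (v, v) for k in range(3)})
        assert junction_cost(a, "R", b, "L").cost == 0

    def test_complement_symmetry(self):
        a = ends("a", {"c1": ([0, 0, 1, 1, 0], [0, 0, 1, 1, 0])})
        b = ends("b", {"c1": ([1, 1, 0, 0, 1], [1, 1, 0, 0, 1])})
        jc = junction_cost(a, "R", b, "L")
        assert jc.cost == 0 and jc.per_colony["c1"] == (0, True)

    def test_matches_bruteforce_over_orientations(self, rng):
        for _ in range(100):
            va = rng.integers(0, 2, 8).astype(np.int8)
            vb = rng.integers(0, 2, 8).astype(np.int8)
            a = ends("a", {"c1": (va.tolist(), va.tolist())})
            b = ends("b", {"c1": (vb.tolist(), vb.tolist())})
            jc = junction_cost(a, "L", b, "L")
            assert jc.cost == min(hamming(va, vb), hamming(va, complement(vb)))

    def test_no_shared_colony_undefined(self):
        a = ends("a", {"c1": ([0, 1], [0, 1])})
        b = ends("b", {"c2": ([0, 1], [0, 1])})
        assert junction_cost(a, "R", b, "L") is None


def random_instance(rng, n_contigs, n_colonies=3, n_drones=10):
    """Random multi-bin contigs with independent end vectors."""
    out = {}
    for i in range(n_contigs):
        per_colony = {}
        for c in range(n_colonies):
            per_colony[f"c{c}"] = (
                rng.integers(0, 2, n_drones).tolist(),
                rng.integers(0, 2, n_drones).tolist(),
            )
        out[f"tig{i:02d}"] = ends(f"tig{i:02d}", per_colony)
    return out


def linked_instance(rng, n_contigs, n_colonies=3, n_drones=12):
    """Contig end vectors with meiotic linkage structure: adjacent ends
    differ by few crossovers, distant ends drift apart."""
    current = {
        f"c{c}": rng.integers(0, 2, n_drones).astype(np.int8)
        for c in range(n_colonies)
    }

    def step(v, k):
        out = v.copy()
        if k:
            idx = rng.choice(len(v), size=min(k, len(v)), replace=False)
            out[idx] = 1 - out[idx]
        return out

    out = {}
    for i in range(n_contigs):
        per_colony = {}
        for c in current:
            left = current[c].copy()
            right = step(left, 1 + int(rng.poisson(1.0)))  # internal COs
            per_colony[c] = (left.tolist(), right.tolist())
            current[c] = step(right, int(rng.poisson(0.3)))  # junction events
        out[f"tig{i:02d}"] = ends(f"tig{i:02d}", per_colony)
    return out


class TestOrderAndOrient:
    def test_error_free_truth_adjacency(self, default_result):
        res = default_result
        assert adjacency_recovery(res.layout, res.truth) >= 0.95

    def test_greedy_equals_exhaustive_small_groups(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 6))
            contig_ends = linked_instance(rng, n)
            assignment = {c: "chr1" for c in contig_ends}
            layout = order_and_orient(contig_ends, assignment)
            greedy_cost = layout_total_cost(layout, contig_ends)
            best, _ = exhaustive_layout_cost(list(contig_ends.values()))
            assert greedy_cost == best

    def test_whole_path_reversal_invariant(self, rng):
        contig_ends = random_instance(rng, 5)
        assignment = {c: "chr1" for c in contig_ends}
        layout = order_and_orient(contig_ends, assignment)
        flip = {"+": "-", "-": "+", "unknown": "unknown"}
        reversed_layout = ScaffoldLayout(
            {
                chrom: [(c, flip[o]) for c, o in reversed(path)]
                for chrom, path in layout.paths.items()
            },
            {},
            dict(layout.contig_lengths),
        )
        assert layout_total_cost(layout, contig_ends) == layout_total_cost(
            reversed_layout, contig_ends
        )

    def test_adjacency_recovery_monotone_in_drone_count(self):
        scores = []
        for n_drones in (15, 45):
            res = run_pipeline(
                SimConfig(
                    seed=11,
                    colonies=((n_drones, 0),),
                    chromosome_lengths=(5_000_000, 5_000_000),
                )
            )
            scores.append(adjacency_recovery(res.layout, res.truth))
        assert scores[1] >= scores[0]


class TestClassifyPlacement:
    def test_status_rules(self):
        layout = ScaffoldLayout({"chr1": [("a", "+"), ("b", "unknown")]})
        status = classify_placement(
            layout,
            assignment={"a": "chr1", "c": "chr2"},
            informative={"a": True, "b": True, "c": False},
        )
        assert status["a"] == "placed"         # both evidence sources
        assert status["b"] == "unlocalised"    # genotype linkage only
        assert status["c"] == "unlocalised"    # alignment only, no SNPs
        layout2 = ScaffoldLayout({"chr1": []})
        status2 = classify_placement(layout2, {}, {"d": True})
        assert status2["d"] == "unplaced"

    def test_withheld_contigs_recovered_on_correct_chromosome(self, default_result):
        res = default_result
        withheld = set(res.truth.contig_layout.contig) - set(res.assignment)
        truth_chrom = dict(
            zip(res.truth.contig_layout.contig, res.truth.contig_layout.chrom)
        )
        assert withheld  # the default conditions withhold some contigs
        placed = 0
        correct = 0
        for contig in withheld:
            chrom = res.layout.chromosome_of(contig)
            if chrom is not None:
                placed += 1
                correct += chrom == truth_chrom[contig]
        assert placed and correct / placed >= 0.9
        status = classify_placement(
            res.layout, res.assignment, {c: True for c in res.contig_ends}
        )
        for contig in withheld:
            if res.layout.chromosome_of(contig):
                assert status[contig] == "unlocalised"


def rec(chrom, start, period, consensus, copies=20.0):
    return TrfArrayRecord(
        GenomicInterval(chrom, start, start + int(period * copies)),
        period,
        copies,
        consensus,
    )


class TestBoundaryRepeats:
    def test_distinct_periods_give_unique_orientation(self):
        # contig ends carry arrays of period 258 and 1296 matching the
        # facing neighbour arrays -> unique orientation
        a258 = rec("tig", 0, 258, "A" * 200 + "C" * 58)
        a1296 = rec("tig", 90_000, 1296, "G" * 1000 + "T" * 296)
        prev = rec("prev", 50_000, 258, "A" * 200 + "C" * 58)
        nxt = rec("next", 0, 1296, "G" * 1000 + "T" * 296)
        assert orient_by_boundary_repeats((a258, a1296), prev, nxt) == "+"
        assert orient_by_boundary_repeats((a1296, a258), prev, nxt) == "-"

    def test_equal_periods_ambiguous(self):
        both = rec("tig", 0, 371, "ACGT" * 92 + "ACG")
        prev = rec("prev", 0, 371, "ACGT" * 92 + "ACG")
        nxt = rec("next", 0, 371, "ACGT" * 92 + "ACG")
        assert orient_by_boundary_repeats((both, both), prev, nxt) == "unknown"

    def test_no_terminal_arrays_unknown(self):
        assert orient_by_boundary_repeats((None, None), None, None) == "unknown"

    def test_simulator_boundary_arrays_resolve_truth_orientation(self):
        cfg = SimConfig(
            seed=9,
            chromosome_lengths=(4_000_000, 4_000_000),
            distinct_boundary_periods=True,
            withhold_assignment_fraction=0.0,
        )
        _, truth = simulate_colonies(cfg)
        fragment_into_contigs(cfg, truth)
        layout = truth.contig_layout

        def contig_arrays(row):
            clen = row.end - row.start
            out = []
            for a in truth.repeat_arrays:
                iv = a.interval
                if iv.chrom != row.chrom or iv.end <= row.start or iv.start >= row.end:
                    continue
                s = max(iv.start, row.start) - row.start
                e = min(iv.end, row.end) - row.start
                if row.orientation == "-":
                    s, e = clen - e, clen - s
                out.append(
                    TrfArrayRecord(
                        GenomicInterval(row.contig, s, e), a.period, max(1.0, (e - s) / a.period), a.consensus
                    )
                )
            return out, clen

        checked = 0
        for chrom, grp in layout.groupby("chrom"):
            ordered = list(grp.sort_values("order").itertuples())
            for prev_row, row, next_row in zip(ordered, ordered[1:], ordered[2:]):
                arrays, clen = contig_arrays(row)
                terms = terminal_arrays(arrays, clen)
                p_arrays, p_len = contig_arrays(prev_row)
                n_arrays, n_len = contig_arrays(next_row)
                # the facing end of a neighbour depends on its placement
                p_terms = terminal_arrays(p_arrays, p_len)
                n_terms = terminal_arrays(n_arrays, n_len)
                prev_facing = p_terms[1] if prev_row.orientation == "+" else p_terms[0]
                next_facing = n_terms[0] if next_row.orientation == "+" else n_terms[1]
                got = orient_by_boundary_repeats(terms, prev_facing, next_facing)
                assert got == row.orientation
                checked += 1
        assert checked >= 4
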