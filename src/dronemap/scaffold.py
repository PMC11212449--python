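"""Order and orient contigs along chromosomes from crossover data.

Each phased contig exposes a genotype vector at each extremity, per
colony.  Joining two contig ends costs the number of recombination
events implied between their end vectors (minimised over the unknown
relative phase, i.e. over complementing one vector); summing over the
colonies that are informative for both contigs gives the junction cost.
Within each a-priori chromosome group, contigs are chained greedily by
repeatedly joining the cheapest available pair of free ends
(Kruskal-style path building), which is how "iteratively minimising the
number of recombination events" is realised here; an exact solver over
all signed orders is provided for small groups to validate the greedy
layout.  Contigs without an a-priori assignment join a chromosome only
when their best junction is cheap in every informative colony.
Single-bin contigs have identical end vectors and therefore cannot be
oriented by the map; terminal tandem-repeat arrays can resolve them by
matching period size and consensus identity with the facing neighbour
ends.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .io import TrfArrayRecord
from .phasing import PhasedContig, complement, contig_end_vectors, hamming

logger = logging.getLogger(__name__)

Side = str  # "L" or "R"


@dataclass
class ContigEnds:
    """Per-colony end vectors of one phased contig."""

    contig: str
    # colony -> (left vector, right vector)
    ends: dict[str, tuple[np.ndarray, np.ndarray]]
    orientable: bool
    length: int = 0

    def vector(self, colony: str, side: Side) -> np.ndarray:
        left, right = self.ends[colony]
        return left if side == "L" else right


def contig_end_vectors_of(
    phased: dict[str, dict[str, PhasedContig]],
    contig_lengths: dict[str, int] | None = None,
) -> dict[str, ContigEnds]:
    """Collect per-colony contig end vectors from phased contigs.

    A contig is orientable when at least one colony observed two or more
    bins within it.
    """
    out: dict[str, ContigEnds] = {}
    for colony, per_contig in phased.items():
        for contig, pc in per_contig.items():
            if not pc.bins:
                continue
            left, right, orientable = contig_end_vectors(pc)
            ce = out.setdefault(
                contig,
                ContigEnds(contig, {}, False, (contig_lengths or {}).get(contig, 0)),
            )
            ce.ends[colony] = (left, right)
            ce.orientable = ce.orientable or orientable
    return out


@dataclass
class JunctionCost:
    """Cost of joining two specific contig ends."""

    contig_a: str
    side_a: Side
    contig_b: str
    side_b: Side
    per_colony: dict[str, tuple[int, bool]]  # colony -> (cost, phase-flip)
    cost: int
    n_informative: int

    def sort_key(self):
        return (
            self.cost,
            -self.n_informative,
            self.contig_a,
            self.side_a,
            self.contig_b,
            self.side_b,
        )


def junction_cost(a: ContigEnds, side_a: Side, b: ContigEnds, side_b: Side) -> JunctionCost | None:
    """Recombination cost of joining end ``side_a`` of a to ``side_b`` of b.

    Per shared colony the cost is ``min(H(vA, vB), H(vA, ~vB))`` with the
    minimising phase recorded; costs sum over shared colonies.  Returns
    None when the contigs share no informative colony.
    """
    shared = sorted(set(a.ends) & set(b.ends))
    if not shared:
        return None
    per_colony: dict[str, tuple[int, bool]] = {}
    total = 0
    n_informative = 0
    for colony in shared:
        va = a.vector(colony, side_a)
        vb = b.vector(colony, side_b)
        d_keep = hamming(va, vb)
        d_flip = hamming(va, complement(vb))
        per_colony[colony] = min((d_keep, False), (d_flip, True))
        total += per_colony[colony][0]
        n_informative += int(np.count_nonzero((va >= 0) & (vb >= 0)))
    return JunctionCost(a.contig, side_a, b.contig, side_b, per_colony, total, n_informative)


@dataclass
class ScaffoldLayout:
    """Ordered, oriented, status-annotated contigs per chromosome."""

    # chromosome -> ordered list of (contig, orientation in {+,-,unknown})
    paths: dict[str, list[tuple[str, str]]]
    status: dict[str, str] = field(default_factory=dict)  # contig -> placed/unlocalised/unplaced
    contig_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.paths)

    def ordered_contigs(self, chrom: str) -> list[tuple[str, str]]:
        return self.paths.get(chrom, [])

    def contig_length(self, contig: str) -> int:
        return self.contig_lengths.get(contig, 0)

    def chromosome_of(self, contig: str) -> str | None:
        for chrom, path in self.paths.items():
            if any(c == contig for c, _ in path):
                return chrom
        return None

    def with_inverted(self, contig: str) -> "ScaffoldLayout":
        """Copy of the layout with one contig's orientation reversed."""
        paths = {
            chrom: [
                (c, {"+": "-", "-": "+"}.get(o, o) if c == contig else o)
                for c, o in path
            ]
            for chrom, path in self.paths.items()
        }
        return ScaffoldLayout(paths, dict(self.status), dict(self.contig_lengths))


class _DSU:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


def _chain_group(
    members: list[ContigEnds],
    floating: list[ContigEnds],
    accept_threshold: int | None,
) -> tuple[list[list[tuple[str, str]]], set[str]]:
    """Greedy best-pair chaining of one chromosome group.

    Floating contigs may join, but only through junctions whose cost is
    within ``accept_threshold`` in every informative colony.  Returns the
    resulting paths (ordered (contig, orientation) lists) and the set of
    floating contigs that were absorbed.
    """
    pool = {c.contig: c for c in members}
    float_ids = {c.contig for c in floating}
    for c in floating:
        pool[c.contig] = c
    candidates: list[JunctionCost] = []
    ids = sorted(pool)
    for ia, ib in itertools.combinations(ids, 2):
        for sa in "LR":
            for sb in "LR":
                jc = junction_cost(pool[ia], sa, pool[ib], sb)
                if jc is not None:
                    candidates.append(jc)
    candidates.sort(key=JunctionCost.sort_key)

    used_ends: set[tuple[str, Side]] = set()
    joined: dict[tuple[str, Side], tuple[str, Side]] = {}
    dsu = _DSU(ids)
    absorbed: set[str] = set()
    # anchored components: contain at least one a-priori member
    anchored = {dsu.find(c.contig) for c in members}

    def is_anchored(cid: str) -> bool:
        return dsu.find(cid) in {dsu.find(a) for a in anchored}

    for jc in candidates:
        ea, eb = (jc.contig_a, jc.side_a), (jc.contig_b, jc.side_b)
        if ea in used_ends or eb in used_ends:
            continue
        if dsu.find(jc.contig_a) == dsu.find(jc.contig_b):
            continue  # would close a cycle
        floating_join = (jc.contig_a in float_ids and not is_anchored(jc.contig_a)) or (
            jc.contig_b in float_ids and not is_anchored(jc.contig_b)
        )
        if floating_join and accept_threshold is not None:
            if any(cost > accept_threshold for cost, _ in jc.per_colony.values()):
                continue
        used_ends.update((ea, eb))
        joined[ea] = eb
        joined[eb] = ea
        dsu.union(jc.contig_a, jc.contig_b)
        if jc.contig_a in float_ids:
            absorbed.add(jc.contig_a)
        if jc.contig_b in float_ids:
            absorbed.add(jc.contig_b)

    # extract paths from join graph
    in_group = [c for c in ids if c not in float_ids or c in absorbed]
    seen: set[str] = set()
    paths: list[list[tuple[str, str]]] = []
    # deterministic: start from free left-most end of each component
    endpoints = []
    for cid in in_group:
        free = [s for s in "LR" if (cid, s) not in used_ends]
        if free:
            endpoints.append((cid, free[0]))
    for cid, start_side in sorted(endpoints):
        if cid in seen:
            continue
        path: list[tuple[str, str]] = []
        cur, entry = cid, {"L": "R", "R": "L"}[start_side]
        # entry = the end by which we "leave" toward the chain; we walk
        # from the free end through the component
        cur_side_in = start_side
        while True:
            seen.add(cur)
            out_side = {"L": "R", "R": "L"}[cur_side_in]
            ends = pool[cur]
            if ends.orientable:
                orientation = "+" if cur_side_in == "L" else "-"
            else:
                orientation = "unknown"
            path.append((cur, orientation))
            nxt = joined.get((cur, out_side))
            if nxt is None:
                break
            cur, cur_side_in = nxt
        paths.append(path)
    # isolated contigs with both ends used cannot occur; but contigs with
    # no endpoints at all (never joined, both ends free) were handled above.
    # canonical direction: first contig id <= last contig id
    canon = []
    for path in paths:
        if path[-1][0] < path[0][0]:
            path = [(c, {"+": "-", "-": "+"}.get(o, o)) for c, o in reversed(path)]
        canon.append(path)
    canon.sort(key=lambda p: p[0][0])
    return canon, absorbed


def order_and_orient(
    contig_ends: dict[str, ContigEnds],
    assignment: dict[str, str],
    accept_threshold: int | None = 1,
) -> ScaffoldLayout:
    """Build the scaffold layout from contig end vectors.

    ``assignment`` maps contigs to their a-priori chromosome; contigs
    absent from it form a floating pool offered to every chromosome
    group but only joined through junctions costing at most
    ``accept_threshold`` recombinations in every informative colony.
    """
    groups: dict[str, list[ContigEnds]] = {}
    for contig, ends in contig_ends.items():
        chrom = assignment.get(contig)
        if chrom is not None:
            groups.setdefault(chrom, []).append(ends)
    floating = [e for c, e in sorted(contig_ends.items()) if c not in assignment]

    paths: dict[str, list[tuple[str, str]]] = {}
    taken: set[str] = set()
    for chrom in sorted(groups):
        avail = [e for e in floating if e.contig not in taken]
        chrom_paths, absorbed = _chain_group(groups[chrom], avail, accept_threshold)
        taken |= absorbed
        merged: list[tuple[str, str]] = []
        for p in chrom_paths:
            merged.extend(p)
        paths[chrom] = merged
    lengths = {c: e.length for c, e in contig_ends.items()}
    layout = ScaffoldLayout(paths, {}, lengths)
    return layout


def classify_placement(
    layout: ScaffoldLayout,
    assignment: dict[str, str],
    informative: dict[str, bool],
) -> dict[str, str]:
    """Placement status per contig.

    placed: ordered by crossover data *and* carrying an a-priori
    assignment; unlocalised: chromosome known from exactly one evidence
    source (alignment only, or genotype linkage only); unplaced: neither.
    """
    status: dict[str, str] = {}
    in_layout: dict[str, str] = {}
    for chrom, path in layout.paths.items():
        for contig, _ in path:
            in_layout[contig] = chrom
    contigs = set(assignment) | set(in_layout) | set(informative)
    for contig in sorted(contigs):
        has_align = contig in assignment
        has_geno = bool(informative.get(contig, False)) and contig in in_layout
        if has_align and has_geno:
            status[contig] = "placed"
        elif has_align or contig in in_layout:
            status[contig] = "unlocalised"
        else:
            status[contig] = "unplaced"
    layout.status.update(status)
    return status


# ---------------------------------------------------------------------------
# exact solver (validation for small groups)


def exhaustive_layout_cost(members: list[ContigEnds]) -> tuple[int, list[tuple[str, str]]]:
    """Minimum total junction cost over all signed orders (n! * 2^n / 2).

    Intended for groups of at most ~8 contigs; used to validate the
    greedy chaining.
    """
    ids = sorted(c.contig for c in members)
    pool = {c.contig: c for c in members}
    best = None
    best_path = None
    first = ids[0]
    for perm in itertools.permutations(ids):
        if perm.index(first) > len(ids) // 2:
            continue  # halve the reversal symmetry
        for signs in itertools.product("+-", repeat=len(ids)):
            total = 0
            ok = True
            for (ca, sa), (cb, sb) in zip(zip(perm, signs), zip(perm[1:], signs[1:])):
                end_a = "R" if sa == "+" else "L"
                end_b = "L" if sb == "+" else "R"
                jc = junction_cost(pool[ca], end_a, pool[cb], end_b)
                if jc is None:
                    ok = False
                    break
                total += jc.cost
            if ok and (best is None or total < best):
                best = total
                best_path = list(zip(perm, signs))
    return best, best_path


def layout_total_cost(layout: ScaffoldLayout, contig_ends: dict[str, ContigEnds]) -> int:
    """Total junction cost of a layout (orientation 'unknown' read as '+')."""
    total = 0
    for path in layout.paths.values():
        for (ca, oa), (cb, ob) in zip(path, path[1:]):
            end_a = "R" if oa != "-" else "L"
            end_b = "L" if ob != "-" else "R"
            jc = junction_cost(contig_ends[ca], end_a, contig_ends[cb], end_b)
            if jc is not None:
                total += jc.cost
    return total


# ---------------------------------------------------------------------------
# boundary tandem repeats


_COMP_TABLE = str.maketrans("ACGTN", "TGCAN")


def _rotation_identity(a: str, b: str) -> float:
    """Best identity between two monomers over circular rotations of
    either strand (a terminal array on a flipped contig is reported
    reverse-complemented)."""
    import edlib

    if not a or not b:
        return 0.0
    best = len(a)
    for query in (a, a.translate(_COMP_TABLE)[::-1]):
        res = edlib.align(query, b + b, mode="HW", task="distance")
        if res["editDistance"] >= 0:
            best = min(best, res["editDistance"])
    return 1.0 - best / len(a)


def arrays_match(
    a: TrfArrayRecord | None,
    b: TrfArrayRecord | None,
    identity_threshold: float = 0.95,
) -> bool:
    """Two terminal arrays match when periods are equal and consensus
    identity (rotation-aware) reaches the threshold."""
    if a is None or b is None:
        return False
    if a.period != b.period:
        return False
    return _rotation_identity(a.consensus, b.consensus) >= identity_threshold


def terminal_arrays(
    arrays: list[TrfArrayRecord], contig_length: int, end_window: int = 25_000
) -> tuple[TrfArrayRecord | None, TrfArrayRecord | None]:
    """The repeat arrays at a contig's two extremities, if any."""
    left = [a for a in arrays if a.interval.start < end_window]
    right = [a for a in arrays if a.interval.end > contig_length - end_window]
    left_pick = min(left, key=lambda a: a.interval.start) if left else None
    right_pick = max(right, key=lambda a: a.interval.end) if right else None
    return left_pick, right_pick


def orient_by_boundary_repeats(
    contig_terminals: tuple[TrfArrayRecord | None, TrfArrayRecord | None],
    prev_facing: TrfArrayRecord | None,
    next_facing: TrfArrayRecord | None,
    identity_threshold: float = 0.95,
) -> str:
    """Orient a contig by matching its terminal arrays to the facing
    neighbour arrays (period equality + consensus identity).

    Returns '+', '-' or 'unknown' (when neither or both orientations
    match).
    """
    left, right = contig_terminals

    def valid(l, r) -> bool:
        # every pair with both arrays present must match, and at least
        # one pair must match
        hits = 0
        for mine, facing in ((l, prev_facing), (r, next_facing)):
            if mine is not None and facing is not None:
                if arrays_match(mine, facing, identity_threshold):
                    hits += 1
                else:
                    return False
        return hits >= 1

    fwd = valid(left, right)
    rev = valid(right, left)
    if fwd and not rev:
        return "+"
    if rev and not fwd:
        return "-"
    return "unknown"
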