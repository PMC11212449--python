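"""Genotype-vector bins, minimum-recombinant phasing and NCO filtering.

At each informative SNP of a colony, the pattern of which queen
haplotype every drone inherited forms a genotype vector.  Runs of
identical vectors along a contig are segments with no observed crossover
and collapse into bins.  Between successive bins the phase (vector vs
its complement) is unknown; choosing per bin whichever of the two
minimises the Hamming distance to the previous phased vector yields the
minimum-recombinant phasing, because each junction is minimised
independently.  Short bins (< 2 kb) whose entering-plus-leaving events
exceed what is needed to go from the preceding to the following bin are
non-crossover gene-conversion tracts and are removed, merging identical
flanks, so that conversion tracts do not inflate the genetic map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import MISSING, GenomicInterval
from .qc import ColonyGenotypes

MISSING_CODE = np.int8(-1)


def complement(vec: np.ndarray) -> np.ndarray:
    """Flip every non-missing entry of a haplotype-inheritance vector."""
    out = vec.copy()
    out[vec >= 0] = 1 - out[vec >= 0]
    return out


def canonicalize(vec: np.ndarray) -> np.ndarray:
    """Orient a site vector so its first non-missing entry is 0.

    Allele labels at a SNP are arbitrary with respect to the queen's
    haplotypes, so a site vector and its complement are the same
    observation; canonicalising makes run detection well defined.
    """
    nz = np.flatnonzero(vec >= 0)
    if nz.size and vec[nz[0]] == 1:
        return complement(vec)
    return vec.copy()


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance over entries non-missing in both vectors."""
    both = (a >= 0) & (b >= 0)
    return int(np.count_nonzero(a[both] != b[both]))


def compatible(a: np.ndarray, b: np.ndarray) -> bool:
    """True when vectors agree wherever both are non-missing."""
    return hamming(a, b) == 0


@dataclass
class Bin:
    """Maximal run of consecutive SNPs sharing one genotype vector."""

    contig: str
    first_snp: int  # position of first member SNP
    last_snp: int   # position of last member SNP
    n_snps: int
    vector: np.ndarray  # per-drone 0/1 with MISSING_CODE wildcards

    @property
    def length(self) -> int:
        # span from first to last member SNP; single-SNP bins have length 0
        return self.last_snp - self.first_snp

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.first_snp, self.last_snp)


@dataclass
class PhasedContig:
    """Ordered bins of one contig with phase flips and junction counts."""

    contig: str
    bins: list[Bin]
    flips: list[bool]
    junction_counts: list[int]

    @property
    def total_recombinations(self) -> int:
        return sum(self.junction_counts)


def site_vectors(
    colony: ColonyGenotypes, drop_replicates: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Per-site haplotype-inheritance codes (0/1/missing) for each drone.

    A drone's allele is coded 0 when it equals the lexicographically
    smaller of the queen's two alleles; het or missing drone calls code
    missing.  Replicate columns are dropped by default (a replicate is
    the same meiosis).
    """
    drones = colony.non_replicate_drones() if drop_replicates else colony.drone_names
    idx = [colony.drone_names.index(d) for d in drones]
    d = colony.drones[:, idx]
    q = np.sort(colony.queen, axis=1)
    codes = np.full(d.shape, MISSING_CODE, dtype=np.int8)
    codes[d == q[:, [0]]] = 0
    codes[d == q[:, [1]]] = 1
    return codes, drones


def build_bins(
    positions: np.ndarray, vectors: np.ndarray, contig: str
) -> list[Bin]:
    """Group consecutive sites with identical (canonical) vectors into bins.

    Missing entries are wildcard-compatible: a site joins the current bin
    when its canonical vector agrees with the bin consensus wherever both
    are non-missing, and fills in consensus entries it newly observes.
    """
    if len(positions) == 0:
        return []
    order = np.argsort(positions)
    positions = np.asarray(positions)[order]
    vectors = vectors[order]
    bins: list[Bin] = []
    cons = canonicalize(vectors[0].astype(np.int8))
    first = last = int(positions[0])
    count = 1
    for i in range(1, len(positions)):
        v = canonicalize(vectors[i].astype(np.int8))
        # a vector that is all-missing stays compatible with anything
        if compatible(cons, v) or compatible(cons, complement(v)):
            if not compatible(cons, v):
                v = complement(v)
            fill = (cons < 0) & (v >= 0)
            cons[fill] = v[fill]
            last = int(positions[i])
            count += 1
        else:
            bins.append(Bin(contig, first, last, count, cons))
            cons = v
            first = last = int(positions[i])
            count = 1
    bins.append(Bin(contig, first, last, count, cons))
    return bins


def phase_contig(bins: list[Bin]) -> PhasedContig:
    """Greedy left-to-right minimum-recombinant phasing.

    For each bin after the first, keep the vector or its complement,
    whichever is closer (Hamming) to the previous phased vector; ties
    keep the unflipped vector.  Because each junction is minimised
    independently this equals the exhaustive minimum over all 2^(B-1)
    phase assignments.
    """
    if not bins:
        raise ValueError("phase_contig requires at least one bin")
    phased = [replace(bins[0], vector=bins[0].vector.copy())]
    flips = [False]
    counts: list[int] = []
    for b in bins[1:]:
        prev = phased[-1].vector
        d_keep = hamming(prev, b.vector)
        d_flip = hamming(prev, complement(b.vector))
        if d_flip < d_keep:
            phased.append(replace(b, vector=complement(b.vector)))
            flips.append(True)
            counts.append(d_flip)
        else:
            phased.append(replace(b, vector=b.vector.copy()))
            flips.append(False)
            counts.append(d_keep)
    return PhasedContig(bins[0].contig, phased, flips, counts)


def _recount(bins: list[Bin]) -> list[int]:
    return [hamming(a.vector, b.vector) for a, b in zip(bins, bins[1:])]


def _merge_three(a: Bin, b: Bin, c: Bin) -> Bin:
    """Merge identical flanks A and C (dropping conversion bin B)."""
    vec = a.vector.copy()
    fill = (vec < 0) & (c.vector >= 0)
    vec[fill] = c.vector[fill]
    return Bin(a.contig, a.first_snp, c.last_snp, a.n_snps + c.n_snps, vec)


def detect_nco_conversions(
    pc: PhasedContig, threshold: int = 2000
) -> tuple[list[Bin], PhasedContig]:
    """Flag and remove gene-conversion bins, iterating to a fixed point.

    A bin B shorter than ``threshold`` (SNP span < 2 kb) flanked by bins
    A and C is flagged when (i) A and C carry identical phased vectors
    (B is then removed and A, C merged into one bin), or (ii) the events
    entering plus leaving B exceed the events needed to go from A to C
    (B removed, A and C left adjacent).  First and last bins are never
    flagged.

    Among simultaneously flaggable bins the shortest (by SNP span, then
    by SNP count, then leftmost) is removed first and the scan repeats
    to a fixed point.  Shortest-first matters when an isolated-error
    singleton sits next to a genuine short inter-crossover segment:
    removing the error bin first restores identical flanks around it,
    whereas a positional scan can flag the genuine segment and erase a
    real crossover.
    """
    bins = [replace(b, vector=b.vector.copy()) for b in pc.bins]
    flagged: list[Bin] = []
    while True:
        candidates = []
        for i in range(1, len(bins) - 1):
            b = bins[i]
            if b.length >= threshold:
                continue
            a, c = bins[i - 1], bins[i + 1]
            if compatible(a.vector, c.vector):
                candidates.append((b.length, b.n_snps, i, "identical_flanks"))
            elif hamming(a.vector, b.vector) + hamming(b.vector, c.vector) > hamming(
                a.vector, c.vector
            ):
                candidates.append((b.length, b.n_snps, i, "excess_events"))
        if not candidates:
            break
        _, _, i, rule = min(candidates)
        flagged.append(bins[i])
        if rule == "identical_flanks":
            bins[i - 1 : i + 2] = [_merge_three(bins[i - 1], bins[i], bins[i + 1])]
        else:
            del bins[i]
    merged = PhasedContig(pc.contig, bins, [False] * len(bins), _recount(bins))
    return flagged, merged


def contig_end_vectors(
    pc: PhasedContig,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """First and last phased bin vectors and whether the contig is orientable.

    A contig is orientable from crossover data when it holds at least two
    bins (i.e. at least one internal crossover was observed).
    """
    if not pc.bins:
        raise ValueError("contig has no bins")
    return pc.bins[0].vector, pc.bins[-1].vector, len(pc.bins) >= 2


def phase_colony_contig(
    colony: ColonyGenotypes,
    contig: str,
    positions: np.ndarray,
    site_index: np.ndarray,
    nco_threshold: int = 2000,
) -> tuple[PhasedContig, list[Bin]]:
    """Convenience: vectors -> bins -> phase -> NCO filter for one contig.

    ``site_index`` selects the colony's master-site rows on this contig;
    ``positions`` are their contig coordinates.
    """
    codes, _ = site_vectors(colony)
    bins = build_bins(np.asarray(positions), codes[site_index], contig)
    if not bins:
        return PhasedContig(contig, [], [], []), []
    pc = phase_contig(bins)
    flagged, merged = detect_nco_conversions(pc, nco_threshold)
    return merged, flagged
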