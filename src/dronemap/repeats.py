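"""Tandem-repeat array analytics: family classification, monomer
rotation canonicalisation, hit grouping, telomere and marker mapping.

The two major tandem families in the honey bee genome are classified by
monomer period (91-93 bp and 367-371 bp); arrays carrying strictly more
than ten copies are the "selected" set used for consensus analysis.
Tandem monomers reported from different genomic loci start at arbitrary
rotations of the same circular sequence, so consensus comparison first
maps every monomer to its lexicographically least rotation (Booth's
algorithm).  BLAST hits of a monomer consensus that follow one another
closer than the period collapse into one array locus.  Telomeres are
called from short-period arrays matching the Hymenoptera TTAGG motif
(rotation- and reverse-complement-aware) near chromosome ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenomicInterval, TrfArrayRecord

FAMILY_WINDOWS = {"91": (91, 93), "371": (367, 371)}


@dataclass
class RepeatArray:
    """A TRF array with its family label and chromosome-end distance."""

    record: TrfArrayRecord
    family: str  # "91", "371" or "other"
    selected: bool  # strictly more than `copy_threshold` copies
    end_distance: int | None = None


def classify_period_families(
    arrays: list[TrfArrayRecord],
    copy_threshold: float = 10.0,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[list[RepeatArray], pd.DataFrame]:
    """Label arrays by period family and flag the selected set.

    Family "91" covers periods 91-93 bp, family "371" covers 367-371 bp;
    the windows are disjoint so labels partition the arrays.  An array
    is selected when its copy number is strictly greater than
    ``copy_threshold`` (default 10).  Returns labelled arrays and a
    per-family count table with and without the copy filter.
    """
    labelled = []
    for rec in arrays:
        family = "other"
        for name, (lo, hi) in FAMILY_WINDOWS.items():
            if lo <= rec.period <= hi:
                family = name
                break
        end_distance = None
        if chrom_lengths and rec.interval.chrom in chrom_lengths:
            clen = chrom_lengths[rec.interval.chrom]
            end_distance = min(rec.interval.start, clen - rec.interval.end)
        labelled.append(
            RepeatArray(rec, family, rec.copies > copy_threshold, end_distance)
        )
    rows = []
    for name in [*FAMILY_WINDOWS, "other"]:
        mine = [a for a in labelled if a.family == name]
        rows.append((name, len(mine), sum(a.selected for a in mine)))
    counts = pd.DataFrame(rows, columns=["family", "n_total", "n_selected"])
    return labelled, counts


def canonical_rotation(seq: str) -> str:
    """Lexicographically least rotation (Booth's algorithm, O(n)).

    All rotations of the same circular sequence map to the same output,
    providing the identical arbitrary start point needed to compare
    monomers reported from different loci.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq + seq
    n = len(s)
    f = [-1] * n  # failure function
    k = 0  # least rotation start
    for j in range(1, n):
        sj = s[j]
        i = f[j - k - 1]
        while i != -1 and sj != s[k + i + 1]:
            if sj < s[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s[k + i + 1]:
            if sj < s[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return s[k : k + len(seq)]


def group_hits(
    hits: list[GenomicInterval], period: int
) -> list[tuple[GenomicInterval, int]]:
    """Single-linkage clustering of monomer hits into array loci.

    Hits on the same chromosome whose gap (next start minus previous
    cluster end) is strictly shorter than the repeat period join the
    same cluster.  Returns (cluster interval, member count) pairs; the
    result is independent of input order.
    """
    out: list[tuple[GenomicInterval, int]] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end, n = ivs[0].start, ivs[0].end, 1
        for iv in ivs[1:]:
            if iv.start - cur_end < period:
                cur_end = max(cur_end, iv.end)
                n += 1
            else:
                out.append((GenomicInterval(chrom, cur_start, cur_end), n))
                cur_start, cur_end, n = iv.start, iv.end, 1
        out.append((GenomicInterval(chrom, cur_start, cur_end), n))
    return out


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def motif_matches(consensus: str, motif: str) -> bool:
    """Rotation- and strand-aware motif identity (TTAGG == CCTAA etc.)."""
    if len(consensus) != len(motif):
        return False
    canon = canonical_rotation(motif)
    return canonical_rotation(consensus) == canon or canonical_rotation(
        _revcomp(consensus)
    ) == canon


@dataclass
class TelomereCall:
    """A short-period array evaluated as a telomere candidate."""

    chrom: str
    end: str  # "proximal" / "distal" / "internal"
    interval: GenomicInterval
    copies: float
    classification: str  # "terminal" or "interstitial"
    motif_match: bool


def call_telomeres(
    arrays: list[TrfArrayRecord],
    chrom_lengths: dict[str, int],
    motif: str = "TTAGG",
    end_window: int = 10_000,
    min_period: int = 2,
    max_period: int = 7,
) -> list[TelomereCall]:
    """Classify short-period arrays as terminal or interstitial.

    Arrays whose interval lies within ``end_window`` of a chromosome end
    are terminal; matching of the telomere motif is rotation- and
    reverse-complement-aware.  Non-motif short-period arrays at
    chromosome ends are still reported (as non-motif terminal
    candidates).
    """
    calls = []
    for rec in arrays:
        if not min_period <= rec.period <= max_period:
            continue
        clen = chrom_lengths.get(rec.interval.chrom)
        if clen is None:
            continue
        near_start = rec.interval.start < end_window
        near_end = rec.interval.end > clen - end_window
        if near_start:
            end = "proximal"
        elif near_end:
            end = "distal"
        else:
            end = "internal"
        calls.append(
            TelomereCall(
                rec.interval.chrom,
                end,
                rec.interval,
                rec.copies,
                "terminal" if (near_start or near_end) else "interstitial",
                motif_matches(rec.consensus.upper(), motif.upper()),
            )
        )
    return calls


def map_marker_repeats(
    hits_by_marker: dict[str, list[GenomicInterval]],
    marker_periods: dict[str, int],
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Marker-repeat loci (e.g. AluI/AvaI) from externally supplied hits.

    Hits per marker are grouped with :func:`group_hits` at that marker's
    period; each locus reports its copy count and distance to the
    nearest chromosome end when lengths are known.
    """
    rows = []
    for marker in sorted(hits_by_marker):
        period = marker_periods[marker]
        for iv, n in group_hits(hits_by_marker[marker], period):
            end_distance = None
            if chrom_lengths and iv.chrom in chrom_lengths:
                clen = chrom_lengths[iv.chrom]
                end_distance = min(iv.start, clen - iv.end)
            rows.append((marker, iv.chrom, iv.start, iv.end, n, end_distance))
    return pd.DataFrame(
        rows, columns=["marker", "chrom", "start", "end", "copies", "end_distance"]
    )
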