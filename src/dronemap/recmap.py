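"""Crossover calling on a scaffold layout, genetic-map summaries,
windowed recombination/GC tracks and hotspot flagging.

Once contigs are laid out along chromosomes, each drone's phased bin
sequence is projected onto scaffold coordinates and every junction where
the drone's phased allele changes yields one crossover event, localised
to the interval between the two flanking informative SNPs -- including
junctions between adjacent contigs, which is where a mis-oriented
contig manufactures artefactual events.  Genetic length in Morgans is
event count divided by the number of meioses; cM/Mb = 100 x Morgans /
Mb.  Recombination-rate tracks spread each event's unit mass uniformly
over its localisation interval in fixed windows; hotspot flagging marks
inter-SNP intervals carrying strictly more than five pooled events,
the diagnostic used to expose assembly breakpoints masquerading as
recombination hotspots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phasing import PhasedContig, complement, hamming
from .scaffold import ScaffoldLayout


@dataclass
class ProjectedBin:
    """A phased bin mapped onto scaffold coordinates."""

    chrom: str
    start: int  # first SNP (scaffold coordinate, orientation applied)
    end: int    # last SNP
    vector: np.ndarray
    contig: str


def layout_coordinates(
    layout: ScaffoldLayout, gap_length: int = 100
) -> dict[str, tuple[int, int, str, str]]:
    """Contig -> (offset, length, orientation, chromosome) on the scaffold."""
    coords = {}
    for chrom, path in layout.paths.items():
        pos = 0
        for k, (contig, orientation) in enumerate(path):
            if k > 0:
                pos += gap_length
            clen = layout.contig_length(contig)
            coords[contig] = (pos, clen, orientation, chrom)
            pos += clen
    return coords


def project_bins(
    layout: ScaffoldLayout,
    phased: dict[str, PhasedContig],
    gap_length: int = 100,
) -> dict[str, list[ProjectedBin]]:
    """Project one colony's phased contigs onto scaffold coordinates.

    Orientation '-' reverses bin order and mirrors SNP positions;
    orientation 'unknown' is projected as '+'.  Across each contig
    junction the whole next contig's phase is complemented when that
    reduces the junction distance (contig phase is a free choice and
    greedy per-junction minimisation is exact here).
    """
    out: dict[str, list[ProjectedBin]] = {}
    coords = layout_coordinates(layout, gap_length)
    for chrom, path in layout.paths.items():
        bins: list[ProjectedBin] = []
        for contig, orientation in path:
            pc = phased.get(contig)
            if pc is None or not pc.bins:
                continue
            offset, clen, _, _ = coords[contig]
            proj = []
            for b in pc.bins:
                if orientation == "-":
                    s = offset + (clen - 1 - b.last_snp)
                    e = offset + (clen - 1 - b.first_snp)
                else:
                    s = offset + b.first_snp
                    e = offset + b.last_snp
                proj.append(ProjectedBin(chrom, s, e, b.vector, contig))
            if orientation == "-":
                proj.reverse()
            # phase the contig against the running chain
            if bins:
                prev = bins[-1].vector
                d_keep = hamming(prev, proj[0].vector)
                d_flip = hamming(prev, complement(proj[0].vector))
                if d_flip < d_keep:
                    for p in proj:
                        p.vector = complement(p.vector)
            bins.extend(proj)
        out[chrom] = bins
    return out


def call_crossovers(
    projected: dict[str, dict[str, list[ProjectedBin]]],
    drone_names: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-drone crossover events from projected bins.

    ``projected`` maps colony -> chromosome -> ordered projected bins;
    one event is emitted per drone per adjacent bin pair whose phased
    alleles differ (both non-missing), on the interval from the last SNP
    of the left bin to the first SNP of the right bin.
    """
    rows = []
    for colony, per_chrom in projected.items():
        names = drone_names[colony]
        for chrom, bins in per_chrom.items():
            for left, right in zip(bins, bins[1:]):
                a, b = left.vector, right.vector
                diff = np.flatnonzero((a >= 0) & (b >= 0) & (a != b))
                for di in diff:
                    rows.append(
                        (
                            colony,
                            names[di],
                            chrom,
                            left.end,
                            right.start,
                            left.contig,
                            right.contig,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=["colony", "drone", "chrom", "start", "end", "left_contig", "right_contig"],
    )


def map_length(
    events: pd.DataFrame,
    n_meioses: int,
    physical_sizes: dict[str, int],
) -> pd.DataFrame:
    """Genetic-map summary: per chromosome and total.

    Morgans = events / meioses; cM/Mb = 100 x Morgans / Mb; the total
    row also reports crossovers per chromosome per meiosis (total
    Morgans / number of chromosomes).
    """
    if n_meioses <= 0:
        raise ValueError("n_meioses must be positive")
    rows = []
    for chrom in sorted(physical_sizes):
        n_events = int((events.chrom == chrom).sum()) if len(events) else 0
        mb = physical_sizes[chrom] / 1e6
        morgans = n_events / n_meioses
        rows.append(
            (chrom, mb, morgans, morgans, 100 * morgans / mb if mb else np.nan)
        )
    total_mb = sum(physical_sizes.values()) / 1e6
    total_m = sum(r[2] for r in rows)
    n_chrom = len(physical_sizes)
    rows.append(
        (
            "total",
            total_mb,
            total_m,
            total_m / n_chrom if n_chrom else np.nan,
            100 * total_m / total_mb if total_mb else np.nan,
        )
    )
    return pd.DataFrame(
        rows, columns=["chrom", "physical_mb", "genetic_morgans", "co_per_chromosome", "cm_per_mb"]
    )


def genome_rate_cm_mb(morgans: float, mb: float) -> float:
    """Genome-wide recombination rate, 100 x Morgans / Mb."""
    return 100.0 * morgans / mb


def co_per_chromosome(morgans: float, n_chromosomes: int) -> float:
    """Mean crossovers per chromosome per meiosis."""
    return morgans / n_chromosomes


def windowed_recombination_rate(
    events: pd.DataFrame,
    chrom_lengths: dict[str, int],
    n_meioses: int,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """cM/Mb in fixed windows, spreading each event uniformly over its
    localisation interval.

    Window value = (mass in window / meioses) x 100 / window size in Mb;
    the last window of a chromosome may be short and uses its actual
    size.  Zero-length intervals put their whole mass in the containing
    window.
    """
    rows = []
    for chrom, length in sorted(chrom_lengths.items()):
        edges = np.arange(0, length, window)
        ends = np.minimum(edges + window, length)
        mass = np.zeros(len(edges))
        sub = events[events.chrom == chrom]
        for ev in sub.itertuples():
            s, e = ev.start, ev.end
            if e <= s:  # zero-length: containing window
                mass[min(int(s // window), len(mass) - 1)] += 1.0
                continue
            lo = int(s // window)
            hi = int((e - 1) // window)
            for w in range(lo, min(hi, len(mass) - 1) + 1):
                ov = min(e, ends[w]) - max(s, edges[w])
                mass[w] += ov / (e - s)
        for w in range(len(edges)):
            mb = (ends[w] - edges[w]) / 1e6
            rows.append(
                (chrom, int(edges[w]), int(ends[w]), 100 * mass[w] / n_meioses / mb, mass[w])
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "cm_per_mb", "event_mass"])


def gc_content_windows(
    sequences: dict[str, str], window: int = 500_000
) -> pd.DataFrame:
    """GC fraction in fixed windows; ambiguity codes are excluded from the
    denominator and an all-ambiguous window is NaN-flagged."""
    rows = []
    for chrom, seq in sorted(sequences.items()):
        arr = np.frombuffer(seq.upper().encode(), dtype="S1")
        gc = (arr == b"G") | (arr == b"C")
        acgt = gc | (arr == b"A") | (arr == b"T")
        for start in range(0, len(seq), window):
            end = min(start + window, len(seq))
            denom = int(acgt[start:end].sum())
            val = float(gc[start:end].sum()) / denom if denom else np.nan
            rows.append((chrom, start, end, val))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gc"])


def detect_hotspots(events: pd.DataFrame, threshold: int = 5) -> pd.DataFrame:
    """Inter-SNP intervals with strictly more than ``threshold`` pooled
    events.

    Events are already localised to the interval between adjacent
    informative SNPs, so pooling is a group-by over identical intervals.
    """
    if len(events) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_events"])
    counts = (
        events.groupby(["chrom", "start", "end"]).size().reset_index(name="n_events")
    )
    hot = counts[counts.n_events > threshold].reset_index(drop=True)
    return hot.sort_values(["chrom", "start"]).reset_index(drop=True)
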