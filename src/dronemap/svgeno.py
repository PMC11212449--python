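"""Depth-ratio genotyping of presence/absence variants in haploid
samples, indel size spectra and exon-overlap reporting.

For an indel that is present in one assembly and absent in the other,
a haploid sample carrying the insertion shows read depth over the indel
interval comparable to its flanks (ratio near 1) while a sample lacking
it shows depth near zero there.  Normalising by the flanking depth
removes per-sample coverage differences; two-class K-means over the
per-sample ratios (solved exactly in one dimension by enumerating split
points over the sorted ratios) separates carriers from non-carriers,
the higher-centre cluster being "present".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenomicInterval, intervals_overlap


@dataclass
class IndelVariant:
    """A presence/absence indel on the assembly that carries it."""

    variant_id: str
    genome: str  # assembly in which the indel is present
    interval: GenomicInterval
    flank: int | None = None  # bp each side; defaults from length

    def __post_init__(self) -> None:
        if self.flank is None:
            # flank tracks the indel size, capped at 5 kb, floored at 500 bp
            self.flank = min(max(self.interval.length, 500), 5000)


@dataclass
class DepthProfile:
    """Per-sample normalised depth over one indel."""

    sample: str
    indel_depth: float
    flank_depth: float

    @property
    def ratio(self) -> float | None:
        if self.flank_depth == 0:
            return None
        return self.indel_depth / self.flank_depth


@dataclass
class PresenceCall:
    sample: str
    call: str  # "present" / "absent" / "no-call"
    cluster: int | None
    centres: tuple[float, float] | None


def depth_ratio(
    depth: np.ndarray,
    region_start: int,
    variant: IndelVariant,
    sample: str = "",
) -> DepthProfile:
    """Mean depth over the indel and over both flanks combined.

    ``depth`` is a per-base track starting at ``region_start`` on the
    variant's genome; it must cover the indel and both flanks (flanks
    are truncated at the track boundaries if needed).  A zero flank
    depth leaves the ratio undefined and the sample becomes a no-call
    downstream.
    """
    iv = variant.interval
    off = iv.start - region_start
    if off < 0 or iv.end - region_start > len(depth):
        raise ValueError("depth track does not cover the indel interval")
    left = depth[max(0, off - variant.flank) : off]
    right = depth[iv.end - region_start : iv.end - region_start + variant.flank]
    inside = depth[off : iv.end - region_start]
    flanks = np.concatenate([left, right])
    if flanks.size == 0:
        raise ValueError("no flanking bases in depth track")
    return DepthProfile(sample, float(inside.mean()), float(flanks.mean()))


def exact_kmeans_1d(x: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Exact two-cluster K-means in one dimension.

    The optimal 2-means partition of points on a line is a split of the
    sorted order, so enumerating the n-1 split points and scoring each
    by within-cluster sum of squares is exact and deterministic (no
    Lloyd initialisation).  Returns labels (0 = lower cluster) and the
    two centres.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two points")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    csum = np.cumsum(xs)
    csq = np.cumsum(xs**2)
    best, best_k = np.inf, 1
    for k in range(1, n):
        left_sse = csq[k - 1] - csum[k - 1] ** 2 / k
        right_n = n - k
        rsum = csum[-1] - csum[k - 1]
        right_sse = (csq[-1] - csq[k - 1]) - rsum**2 / right_n
        sse = left_sse + right_sse
        if sse < best:
            best, best_k = sse, k
    labels = np.zeros(n, dtype=int)
    labels[order[best_k:]] = 1
    c0 = float(xs[:best_k].mean())
    c1 = float(xs[best_k:].mean())
    return labels, (c0, c1)


def kmeans2_call(
    profiles: list[DepthProfile],
    separation_floor: float = 0.3,
    no_call_band: float | None = None,
) -> list[PresenceCall]:
    """Presence/absence calls from depth ratios via exact 1-D 2-means.

    The higher-centre cluster maps to "present".  When the relative
    centre separation ``(c1 - c0) / max(|c0|, |c1|)`` falls below the
    floor the clustering is degenerate (all samples alike) and every
    defined sample receives the call of the single dominant cluster
    (present when the pooled mean ratio is >= 0.5).  Samples with
    undefined ratios are no-calls; an optional band around the cluster
    midpoint (off by default) also yields no-calls.
    """
    ratios = [p.ratio for p in profiles]
    defined = [i for i, r in enumerate(ratios) if r is not None]
    if len(defined) < 2:
        raise ValueError("need at least two samples with defined ratios")
    x = np.array([ratios[i] for i in defined])
    labels, (c0, c1) = exact_kmeans_1d(x)
    calls: list[PresenceCall] = [
        PresenceCall(p.sample, "no-call", None, None) for p in profiles
    ]
    scale = max(abs(c0), abs(c1))
    if scale == 0 or (c1 - c0) / scale < separation_floor:
        pooled = "present" if x.mean() >= 0.5 else "absent"
        for i in defined:
            calls[i] = PresenceCall(profiles[i].sample, pooled, 0, (c0, c1))
        return calls
    midpoint = (c0 + c1) / 2
    for j, i in enumerate(defined):
        if no_call_band is not None and abs(x[j] - midpoint) < no_call_band:
            calls[i] = PresenceCall(profiles[i].sample, "no-call", None, (c0, c1))
            continue
        call = "present" if labels[j] == 1 else "absent"
        calls[i] = PresenceCall(profiles[i].sample, call, int(labels[j]), (c0, c1))
    return calls


def indel_size_spectrum(
    indels: pd.DataFrame,
    boundary_intervals: list[GenomicInterval] | None = None,
    min_size: int = 40,
    thresholds: tuple[int, ...] = (1000, 10_000),
) -> tuple[pd.DataFrame, dict]:
    """Size spectrum of indels strictly larger than ``min_size``.

    ``indels`` needs columns chrom/start/end/length (length may be
    signed; the magnitude is used).  Indels overlapping any contig
    boundary interval are excluded.  Returns the retained frame and a
    summary with the counts above each threshold.
    """
    df = indels.copy()
    df["abs_length"] = df["length"].abs()
    keep = df["abs_length"] > min_size
    if boundary_intervals:
        ivs = [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in df.itertuples()
        ]
        overlapping = {i for i, _, _ in intervals_overlap(ivs, boundary_intervals)}
        keep &= ~df.index.isin(
            [df.index[i] for i in overlapping]
        )
    retained = df[keep].reset_index(drop=True)
    summary = {
        "n_retained": int(len(retained)),
        **{
            f"n_gt_{t}": int((retained.abs_length > t).sum()) for t in thresholds
        },
    }
    return retained, summary


def exon_overlap_report(
    indels: pd.DataFrame, exons: list[GenomicInterval]
) -> pd.DataFrame:
    """Per-indel exon overlaps with total/partial flags."""
    ivs = [
        GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in indels.itertuples()
    ]
    rows = []
    for i, j, total in intervals_overlap(ivs, exons):
        rows.append(
            (
                indels.index[i],
                exons[j].chrom,
                exons[j].start,
                exons[j].end,
                "total" if total else "partial",
            )
        )
    return pd.DataFrame(
        rows, columns=["indel_index", "exon_chrom", "exon_start", "exon_end", "overlap"]
    )
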