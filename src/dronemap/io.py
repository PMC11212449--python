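"""Readers/writers for the standard formats the pipeline touches.

All coordinates in the package are 0-based, half-open ``[start, end)``,
so that ``length == end - start``.  1-based inclusive inputs (VCF POS,
TRF .dat, GFF3) are converted on read and back on write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

# genotype allele sentinels used throughout
MISSING = -1    # missing allele call
NO_ALLELE = -2  # second slot of a haploid call


class CoordinateError(ValueError):
    """A genomic interval violates the 0-based half-open convention."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval on a chromosome or contig."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start > self.end:
            raise CoordinateError(
                f"malformed interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp of a half-open interval (``end - start``)."""
    return iv.length


@dataclass
class VcfSiteTable:
    """Per-site genotypes for a fixed, shared sample ordering.

    ``genotypes`` has shape (n_sites, n_samples, 2); the second allele
    slot is ``NO_ALLELE`` for haploid calls and ``MISSING`` entries mark
    missing calls.  Site annotations (QUAL/FS/MQ/SOR) are NaN when the
    VCF does not provide them.
    """

    sites: pd.DataFrame  # columns: chrom, pos (0-based), ref, alts (tuple)
    samples: list[str]
    genotypes: np.ndarray
    annotations: pd.DataFrame  # columns: qual, fs, mq, sor
    ref_depth: np.ndarray | None = None  # (n_sites, n_samples), NaN if absent

    def __post_init__(self) -> None:
        n = len(self.sites)
        if self.genotypes.shape != (n, len(self.samples), 2):
            raise ValueError("genotype array shape does not match sites/samples")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"sample {name!r} not in table") from None

    def is_het(self) -> np.ndarray:
        """(n_sites, n_samples) bool: diploid heterozygous calls."""
        a, b = self.genotypes[..., 0], self.genotypes[..., 1]
        return (a >= 0) & (b >= 0) & (a != b)

    def is_missing(self) -> np.ndarray:
        return self.genotypes[..., 0] == MISSING

    def haploid_allele(self) -> np.ndarray:
        """First allele slot; the haploid call where calls are haploid."""
        return self.genotypes[..., 0]

    def subset_sites(self, mask: np.ndarray) -> "VcfSiteTable":
        idx = np.asarray(mask)
        return replace(
            self,
            sites=self.sites.loc[idx].reset_index(drop=True),
            genotypes=self.genotypes[idx],
            annotations=self.annotations.loc[idx].reset_index(drop=True),
            ref_depth=None if self.ref_depth is None else self.ref_depth[idx],
        )

    def subset_samples(self, names: list[str]) -> "VcfSiteTable":
        idx = [self.sample_index(n) for n in names]
        return replace(
            self,
            samples=list(names),
            genotypes=self.genotypes[:, idx],
            ref_depth=None if self.ref_depth is None else self.ref_depth[:, idx],
        )


def read_vcf_genotypes(path: str, samples: list[str] | None = None) -> VcfSiteTable:
    """Read a VCF 4.x file into a :class:`VcfSiteTable`.

    Diploid ``0/1`` is kept as a distinct heterozygous pair, ``./.`` maps
    to missing; FS/MQ/SOR INFO annotations and the AD ref-depth FORMAT
    field are parsed when present.
    """
    with pysam.VariantFile(path) as vf:
        all_samples = list(vf.header.samples)
        if samples is None:
            samples = all_samples
        else:
            for s in samples:
                if s not in all_samples:
                    raise KeyError(f"sample {s!r} not present in {path}")
        if "GT" not in vf.header.formats:
            raise ValueError(f"{path} has no GT FORMAT field")
        rows, anns, gts, rds = [], [], [], []
        has_ad = "AD" in vf.header.formats
        for rec in vf:
            rows.append(
                (rec.chrom, rec.pos - 1, rec.ref, tuple(rec.alts or ()))
            )
            info = rec.info
            anns.append(
                (
                    np.nan if rec.qual is None else float(rec.qual),
                    float(info["FS"]) if "FS" in info else np.nan,
                    float(info["MQ"]) if "MQ" in info else np.nan,
                    float(info["SOR"]) if "SOR" in info else np.nan,
                )
            )
            site_gt = np.full((len(samples), 2), NO_ALLELE, dtype=np.int16)
            site_rd = np.full(len(samples), np.nan)
            for j, name in enumerate(samples):
                call = rec.samples[name]
                gt = call.get("GT", (None,))
                alleles = [MISSING if a is None else a for a in gt]
                if len(alleles) == 0:
                    alleles = [MISSING]
                site_gt[j, : min(2, len(alleles))] = alleles[:2]
                if has_ad:
                    ad = call.get("AD")
                    if ad is not None and ad[0] is not None:
                        site_rd[j] = ad[0]
            gts.append(site_gt)
            rds.append(site_rd)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alts"])
    annotations = pd.DataFrame(anns, columns=["qual", "fs", "mq", "sor"])
    genotypes = (
        np.stack(gts) if gts else np.empty((0, len(samples), 2), dtype=np.int16)
    )
    ref_depth = np.stack(rds) if rds and has_ad else None
    return VcfSiteTable(sites, list(samples), genotypes, annotations, ref_depth)


def write_vcf(table: VcfSiteTable, path: str, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a :class:`VcfSiteTable` as an uncompressed VCF 4.2 file."""
    lines = ["##fileformat=VCFv4.2"]
    if contig_lengths is None:
        contig_lengths = {
            c: int(table.sites.loc[table.sites.chrom == c, "pos"].max()) + 1_000
            for c in table.sites.chrom.unique()
        }
    for c, ln in contig_lengths.items():
        lines.append(f"##contig=<ID={c},length={ln}>")
    lines += [
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Strand bias (Fisher)">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##INFO=<ID=SOR,Number=1,Type=Float,Description="Symmetric odds ratio">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(table.samples),
    ]
    ann = table.annotations
    for i in range(table.n_sites):
        chrom, pos, ref, alts = table.sites.iloc[i]
        info = []
        for key, col in (("FS", "fs"), ("MQ", "mq"), ("SOR", "sor")):
            v = ann[col].iloc[i]
            if not np.isnan(v):
                info.append(f"{key}={v:g}")
        qual = ann["qual"].iloc[i]
        gt_strs = []
        for j in range(len(table.samples)):
            a, b = table.genotypes[i, j]
            sa = "." if a == MISSING else str(a)
            if b == NO_ALLELE:
                gt_strs.append(sa)
            else:
                gt_strs.append(f"{sa}/{'.' if b == MISSING else b}")
        lines.append(
            "\t".join(
                [
                    chrom,
                    str(pos + 1),
                    ".",
                    ref,
                    ",".join(alts) if alts else ".",
                    "." if np.isnan(qual) else f"{qual:g}",
                    ".",
                    ";".join(info) or ".",
                    "GT",
                ]
                + gt_strs
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


@dataclass
class TrfArrayRecord:
    """One tandem-repeat array as reported in the TRF .dat dialect."""

    interval: GenomicInterval
    period: int
    copies: float
    consensus: str
    percent_match: float = 100.0
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.period < 1:
            raise ValueError("period must be >= 1")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")


class TrfParseError(ValueError):
    pass


def read_trf_dat(path: str) -> list[TrfArrayRecord]:
    """Parse a Tandem Repeats Finder .dat file.

    Record lines are whitespace-separated with 1-based inclusive start/end
    in the first two fields; they are converted to the shared 0-based
    half-open convention.  Header lines (``Sequence:`` etc.) set the
    current sequence name.
    """
    records: list[TrfArrayRecord] = []
    seqname = ""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("Sequence:"):
                seqname = line.split(None, 1)[1].split()[0]
                continue
            if line.startswith(("Tandem", "Program", "Version", "Parameters")):
                continue
            fields = line.split()
            if len(fields) < 14 or not fields[0].isdigit():
                continue  # other TRF banner content
            try:
                start1, end1 = int(fields[0]), int(fields[1])
                period = int(fields[2])
                copies = float(fields[3])
                percent_match = float(fields[5])
                score = float(fields[7])
                consensus = fields[13]
            except (ValueError, IndexError) as exc:
                raise TrfParseError(f"{path}:{lineno}: bad record line") from exc
            records.append(
                TrfArrayRecord(
                    GenomicInterval(seqname, start1 - 1, end1),
                    period,
                    copies,
                    consensus,
                    percent_match,
                    score,
                )
            )
    return records


def write_trf_dat(records: list[TrfArrayRecord], path: str) -> None:
    """Emit records in the TRF .dat dialect (grouped by sequence)."""
    with open(path, "w") as fh:
        fh.write("Tandem Repeats Finder Program written by Gary Benson\n\n")
        current = None
        for rec in records:
            if rec.interval.chrom != current:
                current = rec.interval.chrom
                fh.write(f"Sequence: {current}\n\n")
                fh.write("Parameters: 2 7 7 80 10 50 2000\n\n")
            iv = rec.interval
            n = len(rec.consensus)
            base_frac = {
                b: (100 * rec.consensus.count(b)) // max(n, 1) for b in "ACGT"
            }
            fh.write(
                f"{iv.start + 1} {iv.end} {rec.period} {rec.copies:g} "
                f"{len(rec.consensus)} {rec.percent_match:g} 0 {rec.score:g} "
                f"{base_frac['A']} {base_frac['C']} {base_frac['G']} {base_frac['T']} "
                f"1.9 {rec.consensus} {rec.consensus}\n"
            )


def write_agp(layout, path: str | None = None, gap_length: int = 100,
              contig_lengths: dict[str, int] | None = None) -> str:
    """Serialise a :class:`~dronemap.scaffold.ScaffoldLayout` as AGP 2.1.

    Gap rows use component type ``N`` / gap type ``scaffold`` with linkage
    evidence ``map`` and a fixed declared gap length (default 100 bp).
    Unoriented contigs are written with orientation ``?``.
    """
    rows = []
    for chrom in sorted(layout.chromosomes):
        pos = 0
        part = 0
        placed = layout.ordered_contigs(chrom)
        for k, (contig, orientation) in enumerate(placed):
            clen = (contig_lengths or {}).get(contig, layout.contig_length(contig))
            if k > 0:
                part += 1
                rows.append(
                    f"{chrom}\t{pos + 1}\t{pos + gap_length}\t{part}\tN\t"
                    f"{gap_length}\tscaffold\tyes\tmap"
                )
                pos += gap_length
            part += 1
            strand = {"+": "+", "-": "-", "unknown": "?"}[orientation]
            rows.append(
                f"{chrom}\t{pos + 1}\t{pos + clen}\t{part}\tW\t"
                f"{contig}\t1\t{clen}\t{strand}"
            )
            pos += clen
    text = "##agp-version\t2.1\n" + "\n".join(rows) + ("\n" if rows else "")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def intervals_overlap(
    a: list[GenomicInterval], b: list[GenomicInterval]
) -> list[tuple[int, int, bool]]:
    """All pairs (i, j, total) with end-exclusive overlap of >= 1 bp.

    ``total`` is True when one interval fully contains the other.  Uses a
    per-chromosome sort/sweep; equivalent to the quadratic scan.
    """
    out: list[tuple[int, int, bool]] = []
    by_chrom_b: dict[str, list[tuple[int, int, int]]] = {}
    for j, iv in enumerate(b):
        by_chrom_b.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    for lst in by_chrom_b.values():
        lst.sort()
    for i, iv in enumerate(a):
        cands = by_chrom_b.get(iv.chrom, [])
        starts = [c[0] for c in cands]
        hi = np.searchsorted(starts, iv.end)  # b.start < a.end
        for start, end, j in cands[:hi]:
            if end > iv.start:
                total = (start <= iv.start and iv.end <= end) or (
                    iv.start <= start and end <= iv.end
                )
                out.append((i, j, total))
    out.sort()
    return out


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff3_exons(path: str) -> list[GenomicInterval]:
    """Exon features of a GFF3 file on the 0-based half-open convention."""
    import pyranges as pr

    gr = pr.read_gff3(path)
    df = gr.df
    df = df[df.Feature == "exon"]
    return [
        GenomicInterval(str(r.Chromosome), int(r.Start), int(r.End))
        for r in df.itertuples()
    ]
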