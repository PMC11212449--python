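"""Synthetic colonies, meioses, contigs, repeat arrays and depth tracks.

The generator emulates the structure of a haploid-drone crossover-mapping
experiment: three colonies of 15/15/13 drones (three drones of colony 1
sequenced in duplicate), queen-heterozygous biallelic SNPs, Poisson
crossovers at 23 cM/Mb, short gene-conversion tracts (geometric length,
mean 500 bp), genotyping error and missingness, chromosomes broken into
contigs at long tandem-repeat arrays, and haploid sequencing-depth
profiles over present/absent indel variants.  Every stage records a truth
set so downstream inferences can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    MISSING,
    NO_ALLELE,
    GenomicInterval,
    TrfArrayRecord,
    VcfSiteTable,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults reproduce the mapping experiment's scale at desk size: a
    20 Mb genome in four 5 Mb chromosomes, 1 heterozygous SNP per kb,
    colonies of 15/15/13 drones (43 meioses; colony 1 has 3 replicate
    drones), crossovers at 23 cM/Mb, one conversion tract per meiosis
    per chromosome with mean length 500 bp, 0.2% genotyping error.
    Repeat-array counts mirror the two major tandem families: 131
    arrays of the 371 bp family (74 with > 10 copies) and 345 of the
    91 bp family (43 with > 10 copies); arrays longer than the
    10 kb read-length proxy break the assembly into contigs.
    """

    seed: int = 42
    chromosome_lengths: tuple[int, ...] = (5_000_000,) * 4
    snp_density: float = 0.001  # queen-het SNPs per bp
    colonies: tuple[tuple[int, int], ...] = ((15, 3), (15, 0), (13, 0))
    recombination_rate_cm_mb: float = 23.0
    nco_rate: float = 1.0  # conversion tracts per meiosis per chromosome
    nco_tract_mean_bp: float = 500.0
    genotyping_error_rate: float = 0.002
    missing_rate: float = 0.0
    # tandem repeat landscape
    n_371_total: int = 131
    n_371_selected: int = 74  # strictly > 10 copies
    n_91_total: int = 345
    n_91_selected: int = 43
    boundary_arrays_per_chromosome: int = 4
    read_length_bp: int = 10_000  # contig break threshold
    distinct_boundary_periods: bool = False
    repeat_mutation_rate: float = 0.01
    # contig assignment table
    withhold_assignment_fraction: float = 0.1
    # depth / indel panel
    depth_lambda: float = 30.0
    background_mismap: float = 0.02
    populations: tuple[int, ...] = (35, 30, 15)
    # (length bp, per-population presence frequency)
    indel_panel: tuple[tuple[int, tuple[float, ...]], ...] = (
        (745, (1.0, 2 / 30, 0.0)),
        (576, (0.0, 29 / 30, 4 / 15)),
    )

    def __post_init__(self) -> None:
        for p in (
            self.genotyping_error_rate,
            self.missing_rate,
            self.withhold_assignment_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(l <= 0 for l in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.depth_lambda <= 0:
            raise ValueError("depth_lambda must be positive")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chromosome_lengths))]

    @property
    def n_meioses(self) -> int:
        return sum(n for n, _ in self.colonies)


@dataclass
class TruthSet:
    """Ground truth recorded by the simulator."""

    site_positions: dict[str, np.ndarray]  # chrom -> sorted SNP positions
    # colony -> chrom -> (n_sites, 2) allele index carried by queen hap 0/1
    queen_haplotypes: dict[str, dict[str, np.ndarray]]
    # colony -> drone -> chrom -> sorted crossover positions
    crossovers: dict[str, dict[str, dict[str, np.ndarray]]]
    # colony -> drone -> chrom -> list of (start, end) conversion tracts
    conversion_tracts: dict[str, dict[str, dict[str, list[tuple[int, int]]]]]
    # colony -> drone -> chrom -> per-site inherited haplotype (0/1)
    drone_haplotypes: dict[str, dict[str, dict[str, np.ndarray]]]
    replicate_pairs: dict[str, dict[str, str]]  # colony -> drone -> replicate
    # filled by fragment_into_contigs
    contig_layout: pd.DataFrame | None = None  # chrom-ordered contig truth
    repeat_arrays: list[TrfArrayRecord] = field(default_factory=list)
    # filled by simulate_depth_profiles
    indel_presence: pd.DataFrame | None = None


def _drone_mosaic(rng, length, morgans, nco_rate, tract_mean):
    """One meiotic product: start haplotype, crossovers, conversion tracts."""
    start_hap = int(rng.integers(2))
    n_co = rng.poisson(morgans)
    xovers = np.sort(rng.integers(1, length, size=n_co))
    n_nco = rng.poisson(nco_rate)
    tracts = []
    for _ in range(n_nco):
        s = int(rng.integers(0, length))
        ln = int(rng.geometric(1.0 / tract_mean))
        tracts.append((s, min(s + ln, length)))
    return start_hap, xovers, tracts


def _hap_at(positions, start_hap, xovers, tracts):
    """Inherited haplotype at each site from the crossover/conversion mosaic."""
    hap = (start_hap + np.searchsorted(xovers, positions, side="right")) % 2
    for s, e in tracts:
        inside = (positions >= s) & (positions < e)
        hap[inside] = 1 - hap[inside]
    return hap


def simulate_colonies(cfg: SimConfig) -> tuple[dict[str, VcfSiteTable], TruthSet]:
    """Simulate queen + drone genotypes per colony and the truth set.

    Returns one :class:`VcfSiteTable` per colony (queen first, then
    drones, then replicate drones) over a master site list shared across
    colonies; all queens are heterozygous at every site.
    """
    rng = np.random.default_rng(cfg.seed)
    positions: dict[str, np.ndarray] = {}
    for chrom, length in zip(cfg.chrom_names, cfg.chromosome_lengths):
        n = rng.poisson(cfg.snp_density * length)
        if n == 0:
            raise ValueError(
                f"snp_density {cfg.snp_density} yields 0 sites on {chrom}"
            )
        positions[chrom] = np.sort(
            rng.choice(length, size=n, replace=False)
        ).astype(np.int64)
    n_sites_per_chrom = {c: len(p) for c, p in positions.items()}
    total_sites = sum(n_sites_per_chrom.values())

    # biallelic ref/alt per master site
    site_rows = []
    for chrom in cfg.chrom_names:
        for pos in positions[chrom]:
            r, a = rng.choice(4, size=2, replace=False)
            site_rows.append((chrom, int(pos), chr(BASES[r][0]), (chr(BASES[a][0]),)))
    sites_df = pd.DataFrame(site_rows, columns=["chrom", "pos", "ref", "alts"])

    tables: dict[str, VcfSiteTable] = {}
    truth = TruthSet({c: p for c, p in positions.items()}, {}, {}, {}, {}, {})
    for ci, (n_drones, n_reps) in enumerate(cfg.colonies):
        colony = f"colony{ci + 1}"
        crng = np.random.default_rng(rng.integers(2**31))
        # which allele (0=ref, 1=alt) each queen haplotype carries, per site
        qhap = {
            chrom: np.stack(
                [h := crng.integers(2, size=n_sites_per_chrom[chrom]).astype(np.int16),
                 1 - h],
                axis=1,
            )
            for chrom in cfg.chrom_names
        }
        truth.queen_haplotypes[colony] = qhap
        truth.crossovers[colony] = {}
        truth.conversion_tracts[colony] = {}
        truth.drone_haplotypes[colony] = {}
        drones = [f"{colony}_d{k + 1:02d}" for k in range(n_drones)]
        truth.replicate_pairs[colony] = {
            drones[k]: f"{drones[k]}_rep" for k in range(n_reps)
        }

        clean_alleles = {}  # drone -> per-chrom allele codes before error
        for drone in drones:
            drng = np.random.default_rng(crng.integers(2**31))
            truth.crossovers[colony][drone] = {}
            truth.conversion_tracts[colony][drone] = {}
            truth.drone_haplotypes[colony][drone] = {}
            per_chrom = {}
            for chrom, length in zip(cfg.chrom_names, cfg.chromosome_lengths):
                morgans = cfg.recombination_rate_cm_mb * length / 1e8
                start_hap, xo, tracts = _drone_mosaic(
                    drng, length, morgans, cfg.nco_rate, cfg.nco_tract_mean_bp
                )
                hap = _hap_at(positions[chrom], start_hap, xo, tracts)
                truth.crossovers[colony][drone][chrom] = xo
                truth.conversion_tracts[colony][drone][chrom] = tracts
                truth.drone_haplotypes[colony][drone][chrom] = hap
                per_chrom[chrom] = qhap[chrom][np.arange(len(hap)), hap]
            clean_alleles[drone] = per_chrom

        sample_names = [f"{colony}_queen"] + drones + [
            truth.replicate_pairs[colony][d] for d in drones[:n_reps]
        ]
        gt = np.full((total_sites, len(sample_names), 2), NO_ALLELE, dtype=np.int16)
        # queen: diploid heterozygous 0/1 at every site
        gt[:, 0, 0] = 0
        gt[:, 0, 1] = 1

        def observed(clean: np.ndarray, erng) -> np.ndarray:
            obs = clean.copy()
            flips = erng.random(obs.shape) < cfg.genotyping_error_rate
            obs[flips] = 1 - obs[flips]
            obs[erng.random(obs.shape) < cfg.missing_rate] = MISSING
            return obs

        for j, name in enumerate(sample_names[1:], start=1):
            source = name[:-4] if name.endswith("_rep") else name
            clean = np.concatenate(
                [clean_alleles[source][c] for c in cfg.chrom_names]
            )
            erng = np.random.default_rng(crng.integers(2**31))
            gt[:, j, 0] = observed(clean, erng)

        annotations = pd.DataFrame(
            {
                "qual": np.full(total_sites, 1000.0),
                "fs": np.zeros(total_sites),
                "mq": np.full(total_sites, 60.0),
                "sor": np.ones(total_sites),
            }
        )
        tables[colony] = VcfSiteTable(
            sites_df.copy(), sample_names, gt, annotations
        )
    return tables, truth


# ---------------------------------------------------------------------------
# sequence, repeat arrays and contig fragmentation


def _random_seq(rng, n: int) -> np.ndarray:
    return BASES[rng.integers(4, size=n)]


def _tandem_array(rng, monomer: str, copies: float, mutation_rate: float) -> str:
    """Head-to-tail copies of ``monomer`` with per-copy point mutations."""
    period = len(monomer)
    full = int(copies)
    out = []
    for _ in range(full):
        copy = np.frombuffer(monomer.encode(), dtype="S1").copy()
        nmut = rng.binomial(period, mutation_rate)
        if nmut:
            idx = rng.choice(period, size=nmut, replace=False)
            copy[idx] = BASES[rng.integers(4, size=nmut)]
        out.append(copy)
    rem = int(round((copies - full) * period))
    if rem:
        out.append(np.frombuffer(monomer.encode(), dtype="S1")[:rem])
    return b"".join(x.tobytes() for x in out).decode()


def fragment_into_contigs(
    cfg: SimConfig, truth: TruthSet
) -> tuple[dict[str, str], pd.DataFrame]:
    """Plant repeat arrays, build chromosome sequences and break contigs.

    Chromosomes are broken at the midpoint of every array longer than the
    read-length proxy, so each resulting contig boundary carries half of
    the interrupting array on each side (period and consensus shared by
    the two facing ends).  Contigs are renamed, shuffled and randomly
    reverse-complemented; the truth layout (with applied flips) is stored
    in ``truth.contig_layout``.  Returns the contig sequences and the
    a-priori chromosome-assignment table with a configurable fraction of
    contigs withheld.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n_chrom = len(cfg.chromosome_lengths)
    n_boundary = cfg.boundary_arrays_per_chromosome * n_chrom
    if n_boundary > cfg.n_371_selected:
        raise ValueError("boundary arrays exceed selected 371-family count")

    # plan arrays: (family period range, copies range, boundary flag)
    plans: list[tuple[int, float, bool]] = []
    for k in range(n_boundary):  # long, assembly-breaking
        if cfg.distinct_boundary_periods:
            period = 150 + 37 * k  # unique periods across the genome
            copies = float(int(np.ceil(cfg.read_length_bp / period)) + rng.integers(2, 10))
        else:
            period = int(rng.integers(367, 372))
            copies = float(rng.integers(30, 61))
        plans.append((period, copies, True))
    for _ in range(cfg.n_371_selected - n_boundary):  # selected, short
        plans.append((int(rng.integers(367, 372)), float(rng.integers(11, 27)), False))
    for _ in range(cfg.n_371_total - cfg.n_371_selected):
        plans.append((int(rng.integers(367, 372)), float(rng.integers(2, 11)), False))
    for _ in range(cfg.n_91_selected):
        plans.append((int(rng.integers(91, 94)), float(rng.integers(11, 101)), False))
    for _ in range(cfg.n_91_total - cfg.n_91_selected):
        plans.append((int(rng.integers(91, 94)), float(rng.integers(2, 11)), False))

    # spread arrays over chromosomes proportionally to length, boundary
    # arrays evenly within each chromosome
    order = rng.permutation(len(plans))
    weights = np.asarray(cfg.chromosome_lengths, dtype=float)
    assignment = rng.choice(n_chrom, size=len(plans), p=weights / weights.sum())
    boundary_idx = [i for i, p in enumerate(plans) if p[2]]
    for k, i in enumerate(boundary_idx):  # force even boundary spread
        assignment[i] = k % n_chrom

    chrom_seqs: dict[str, str] = {}
    truth.repeat_arrays = []
    break_points: dict[str, list[int]] = {c: [] for c in cfg.chrom_names}
    for ci, (chrom, length) in enumerate(zip(cfg.chrom_names, cfg.chromosome_lengths)):
        mine = [plans[i] for i in order if assignment[i] == ci]
        arrays = []
        for period, copies, boundary in mine:
            monomer = _random_seq(rng, period).tobytes().decode()
            seq = _tandem_array(rng, monomer, copies, cfg.repeat_mutation_rate)
            arrays.append((period, copies, boundary, monomer, seq))
        # non-overlapping placement away from chromosome ends
        total_rep = sum(len(a[4]) for a in arrays)
        free = length - total_rep
        if free <= 2_500 * (len(arrays) + 1):
            raise ValueError("repeat arrays do not fit on chromosome")
        gaps = rng.dirichlet(np.ones(len(arrays) + 1)) * (free - 2000 * (len(arrays) + 1))
        gaps = gaps.astype(int) + 2000
        pieces, pos = [], 0
        for (period, copies, boundary, monomer, seq), gap in zip(arrays, gaps):
            pieces.append(_random_seq(rng, gap).tobytes().decode())
            pos += gap
            iv = GenomicInterval(chrom, pos, pos + len(seq))
            truth.repeat_arrays.append(
                TrfArrayRecord(iv, period, copies, monomer, 100.0 * (1 - cfg.repeat_mutation_rate))
            )
            if len(seq) > cfg.read_length_bp and boundary:
                break_points[chrom].append(pos + len(seq) // 2)
            pieces.append(seq)
            pos += len(seq)
        pieces.append(_random_seq(rng, length - pos).tobytes().decode())
        chrom_seqs[chrom] = "".join(pieces)

    # cut into contigs, shuffle, flip
    contig_rows = []
    contigs: dict[str, str] = {}
    serial = 0
    for chrom, length in zip(cfg.chrom_names, cfg.chromosome_lengths):
        cuts = [0] + sorted(break_points[chrom]) + [length]
        for k in range(len(cuts) - 1):
            start, end = cuts[k], cuts[k + 1]
            if end <= start:
                raise ValueError("contig break policy produced zero-length contig")
            serial += 1
            contig_rows.append((chrom, k, start, end, serial))
    perm = rng.permutation(len(contig_rows))
    names = [f"tig{serial:05d}" for serial in range(1, len(contig_rows) + 1)]
    rows = []
    for new_idx, row_idx in enumerate(perm):
        chrom, order_idx, start, end, _ = contig_rows[row_idx]
        name = names[new_idx]
        flipped = bool(rng.integers(2))
        seq = chrom_seqs[chrom][start:end]
        contigs[name] = _revcomp(seq) if flipped else seq
        rows.append((name, chrom, order_idx, start, end, "-" if flipped else "+"))
    layout = (
        pd.DataFrame(
            rows, columns=["contig", "chrom", "order", "start", "end", "orientation"]
        )
        .sort_values(["chrom", "order"])
        .reset_index(drop=True)
    )
    truth.contig_layout = layout

    keep = rng.random(len(layout)) >= cfg.withhold_assignment_fraction
    assignment_table = layout.loc[keep, ["contig", "chrom"]].reset_index(drop=True)
    return contigs, assignment_table


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def sites_on_contigs(cfg: SimConfig, truth: TruthSet) -> pd.DataFrame:
    """Map master SNP sites onto contig coordinates under the truth layout.

    Returns a frame with one row per master site: its global index, the
    contig it falls on and its position along that contig (orientation
    applied).  Sites inside repeat arrays survive unchanged; the mapping
    is purely coordinate arithmetic.
    """
    layout = truth.contig_layout
    if layout is None:
        raise ValueError("run fragment_into_contigs first")
    rows = []
    global_idx = 0
    offsets = {}
    for chrom in cfg.chrom_names:
        offsets[chrom] = global_idx
        global_idx += len(truth.site_positions[chrom])
    for rec in layout.itertuples():
        pos = truth.site_positions[rec.chrom]
        lo, hi = np.searchsorted(pos, [rec.start, rec.end])
        for i in range(lo, hi):
            p = pos[i] - rec.start
            if rec.orientation == "-":
                p = (rec.end - rec.start - 1) - p
            rows.append((offsets[rec.chrom] + i, rec.contig, int(p)))
    return pd.DataFrame(rows, columns=["site_index", "contig", "contig_pos"])


# ---------------------------------------------------------------------------
# depth profiles over indel variants


def simulate_depth_profiles(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, dict[str, np.ndarray]], TruthSet | pd.DataFrame]:
    """Per-sample per-base depth tracks over each indel and its flanks.

    Depth is Poisson(``depth_lambda``) over flanks; over the indel
    interval it is Poisson(``depth_lambda``) when the sample carries the
    insertion and Poisson(``depth_lambda * background_mismap``) when it
    does not.  Returns ``tracks[variant][sample]`` (flank + indel +
    flank concatenated per base) and the truth presence table.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    samples = []
    for pi, n in enumerate(cfg.populations):
        samples += [f"pop{pi + 1}_s{k + 1:02d}" for k in range(n)]
    presence_rows = []
    tracks: dict[str, dict[str, np.ndarray]] = {}
    for vi, (length, freqs) in enumerate(cfg.indel_panel):
        vid = f"indel{vi + 1}"
        flank = min(max(length, 500), 5000)
        tracks[vid] = {}
        k = 0
        for pi, n in enumerate(cfg.populations):
            for _ in range(n):
                sample = samples[k]
                k += 1
                present = bool(rng.random() < freqs[pi])
                lam_in = cfg.depth_lambda if present else cfg.depth_lambda * cfg.background_mismap
                track = np.concatenate(
                    [
                        rng.poisson(cfg.depth_lambda, size=flank),
                        rng.poisson(lam_in, size=length),
                        rng.poisson(cfg.depth_lambda, size=flank),
                    ]
                ).astype(float)
                tracks[vid][sample] = track
                presence_rows.append((vid, sample, f"pop{pi + 1}", present, length, flank))
    presence = pd.DataFrame(
        presence_rows,
        columns=["variant", "sample", "population", "present", "length", "flank"],
    )
    return tracks, presence


def find_exact_tandem_arrays(
    seq: str, min_period: int = 2, max_period: int = 2000, min_copies: float = 2.0
) -> list[TrfArrayRecord]:
    """Minimal exact-tandem annotator for fixture-scale sequences.

    Brute-force search for maximal runs of exact head-to-tail monomer
    copies; reports the smallest period of each run.  Quadratic in the
    sequence length -- intended only for building small test fixtures,
    not a substitute for a real tandem-repeat finder.
    """
    n = len(seq)
    records: list[TrfArrayRecord] = []
    covered = np.zeros(n, dtype=bool)
    for period in range(min_period, min(max_period, n // 2) + 1):
        i = 0
        while i + 2 * period <= n:
            if covered[i]:
                i += 1
                continue
            # extend exact match seq[j] == seq[j-period]
            j = i + period
            while j < n and seq[j] == seq[j - period]:
                j += 1
            run = j - i
            copies = run / period
            if copies >= min_copies and run >= 2 * period:
                records.append(
                    TrfArrayRecord(
                        GenomicInterval("seq", i, j),
                        period,
                        round(copies, 1),
                        seq[i : i + period],
                        100.0,
                    )
                )
                covered[i:j] = True
                i = j
            else:
                i += 1
    records.sort(key=lambda r: (r.interval.start, r.period))
    return records
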