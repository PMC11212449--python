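"""Site-quality hard filtering and colony-level biological SNP filters.

Two layers of quality control precede phasing: GATK-style hard filters
on site annotations (FS > 60, MQ < 50, SOR > 3, plus removal of any site
with a missing genotype), then five biological discard rules applied per
colony -- (i) lack of polymorphism across the colonies, (ii) queen
homozygous, (iii) heterozygous drone call, (iv) inconsistent with the
observations in the other colonies, (v) drone allele absent from the
queen's two alleles -- with replicate-drone concordance checked between
(iii) and (iv).  Each discarded site is attributed to its first-failing
rule so the per-category report is a partition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, VcfSiteTable

logger = logging.getLogger(__name__)

RULES = [
    "non_polymorphic",      # (i)
    "queen_homozygous",     # (ii)
    "drone_heterozygous",   # (iii)
    "replicate_discordant",
    "cross_colony",         # (iv)
    "allele_not_in_queen",  # (v)
]


@dataclass
class ColonyGenotypes:
    """Queen and drone genotypes of one colony on a shared site list."""

    colony_id: str
    sites: pd.DataFrame  # chrom, pos, ref, alts
    queen: np.ndarray  # (n_sites, 2) allele indices
    drones: np.ndarray  # (n_sites, n_drones) haploid codes; HET for diploid het
    drone_names: list[str]
    replicate_pairs: dict[str, str] = field(default_factory=dict)

    HET = -3  # drone called heterozygous-diploid

    def __post_init__(self) -> None:
        if self.drones.shape != (len(self.sites), len(self.drone_names)):
            raise ValueError("drone matrix shape mismatch")
        known = set(self.drone_names)
        for a, b in self.replicate_pairs.items():
            if a not in known or b not in known:
                raise ValueError(f"replicate pair ({a}, {b}) references unknown drone")

    @classmethod
    def from_site_table(
        cls,
        table: VcfSiteTable,
        colony_id: str,
        queen: str,
        drones: list[str],
        replicate_pairs: dict[str, str] | None = None,
    ) -> "ColonyGenotypes":
        qi = table.sample_index(queen)
        q = table.genotypes[:, qi, :].copy()
        di = [table.sample_index(d) for d in drones]
        g = table.genotypes[:, di, :]
        haploid = g[..., 0].astype(np.int16).copy()
        het = (g[..., 1] >= 0) & (g[..., 0] >= 0) & (g[..., 0] != g[..., 1])
        hom_dip = (g[..., 1] >= 0) & (g[..., 0] == g[..., 1])
        haploid[het] = cls.HET
        # diploid homozygous drone call collapses to its haploid allele
        haploid[hom_dip] = g[..., 0][hom_dip]
        return cls(
            colony_id,
            table.sites.copy(),
            q,
            haploid,
            list(drones),
            dict(replicate_pairs or {}),
        )

    def subset(self, mask: np.ndarray) -> "ColonyGenotypes":
        return ColonyGenotypes(
            self.colony_id,
            self.sites.loc[mask].reset_index(drop=True),
            self.queen[mask],
            self.drones[mask],
            list(self.drone_names),
            dict(self.replicate_pairs),
        )

    def non_replicate_drones(self) -> list[str]:
        reps = set(self.replicate_pairs.values())
        return [d for d in self.drone_names if d not in reps]

    def site_key(self) -> pd.Index:
        return pd.Index(zip(self.sites.chrom, self.sites.pos))


@dataclass
class QcReport:
    """Per-rule discard counts; categories partition the discarded sites."""

    colony_id: str
    n_input: int
    discarded: dict[str, int]
    n_retained: int

    def as_frame(self) -> pd.DataFrame:
        rows = [
            (rule, n, n / self.n_input if self.n_input else 0.0)
            for rule, n in self.discarded.items()
        ]
        rows.append(
            ("retained", self.n_retained, self.n_retained / self.n_input if self.n_input else 0.0)
        )
        return pd.DataFrame(rows, columns=["category", "count", "fraction"])


def filter_site_quality(
    table: VcfSiteTable, strict: bool = False
) -> VcfSiteTable:
    """Hard filters: FS > 60 or MQ < 50 or SOR > 3, and missing genotypes.

    Annotation thresholds are strict inequalities as printed; absent
    annotations pass their check (logged) unless ``strict`` is set, in
    which case they raise.
    """
    ann = table.annotations
    absent = ann[["fs", "mq", "sor"]].isna().any(axis=1).to_numpy()
    if absent.any():
        msg = f"{absent.sum()} sites lack FS/MQ/SOR annotations"
        if strict:
            raise ValueError(msg)
        logger.warning("%s; they pass the annotation checks", msg)
    fail = (
        (ann.fs.to_numpy() > 60)
        | (ann.mq.to_numpy() < 50)
        | (ann.sor.to_numpy() > 3)
    )
    fail |= table.is_missing().any(axis=1)
    return table.subset_sites(~fail)


def _observed_alleles(colony: ColonyGenotypes) -> list[set[int]]:
    """Per-site set of alleles observed in a colony (queen + drones)."""
    out = []
    for i in range(len(colony.sites)):
        s = {int(a) for a in colony.queen[i] if a >= 0}
        s.update(int(a) for a in colony.drones[i] if a >= 0)
        out.append(s)
    return out


def _rule_matrix(
    colony: ColonyGenotypes,
    all_colony_alleles: list[set[int]],
    other_queen_alleles: list[set[int]] | None,
) -> np.ndarray:
    """(n_sites, len(RULES)) boolean rule-failure matrix for one colony."""
    n = len(colony.sites)
    q = colony.queen
    d = colony.drones
    het = d == ColonyGenotypes.HET
    obs = np.where((d >= 0), d, -100)  # callable haploid alleles only

    fails = np.zeros((n, len(RULES)), dtype=bool)

    # (i) lack of polymorphism across the colonies (all observed alleles)
    fails[:, 0] = np.array([len(s) <= 1 for s in all_colony_alleles])

    # (ii) queen homozygous
    fails[:, 1] = q[:, 0] == q[:, 1]

    # (iii) heterozygous drone call
    fails[:, 2] = het.any(axis=1)

    # replicate discordance
    if colony.replicate_pairs:
        rep = np.zeros(n, dtype=bool)
        for a, b in colony.replicate_pairs.items():
            ia = colony.drone_names.index(a)
            ib = colony.drone_names.index(b)
            va, vb = d[:, ia], d[:, ib]
            rep |= (va >= 0) & (vb >= 0) & (va != vb)
        fails[:, 3] = rep

    # (iv) colony allele set incompatible with other colonies' queens
    if other_queen_alleles is not None:
        for i in range(n):
            union = other_queen_alleles[i]
            if not union:
                continue
            colony_set = {int(q[i, 0]), int(q[i, 1])} | {
                int(a) for a in obs[i] if a >= 0
            }
            if colony_set.isdisjoint(union) or not colony_set <= union:
                fails[i, 4] = True

    # (v) drone allele absent from the queen's two alleles
    in_queen = (obs == q[:, [0]]) | (obs == q[:, [1]]) | (obs < 0)
    fails[:, 5] = ~in_queen.all(axis=1)
    return fails


def filter_biological(
    colonies: list[ColonyGenotypes],
) -> tuple[list[ColonyGenotypes], list[QcReport]]:
    """Apply the five biological discard rules (plus replicate concordance).

    Rules run per colony in listed order with first-failing attribution;
    rule (iv) compares each colony's allele set at a site against the
    union of queen alleles observed at that site in the other colonies
    and is skipped (with a warning) when only one colony is supplied.
    """
    if not colonies:
        raise ValueError("no colonies supplied")
    single = len(colonies) == 1
    if single:
        warnings.warn("single colony: cross-colony rule (iv) skipped")

    keys = [c.site_key() for c in colonies]
    observed = [_observed_alleles(c) for c in colonies]
    pooled: dict = {}
    for cj in range(len(colonies)):
        for k, s in zip(keys[cj], observed[cj]):
            pooled.setdefault(k, set()).update(s)
    retained, reports = [], []
    for ci, colony in enumerate(colonies):
        my_key = keys[ci]
        all_alleles = [pooled[k] for k in my_key]
        if single:
            others = None
        else:
            lookup: dict = {}
            for cj, other in enumerate(colonies):
                if cj == ci:
                    continue
                for k, (a, b) in zip(keys[cj], other.queen):
                    lookup.setdefault(k, set()).update(
                        int(x) for x in (a, b) if x >= 0
                    )
            others = [lookup.get(k, set()) for k in my_key]
        fails = _rule_matrix(colony, all_alleles, others)
        any_fail = fails.any(axis=1)
        first = np.where(any_fail, fails.argmax(axis=1), -1)
        counts = {rule: int((first == r).sum()) for r, rule in enumerate(RULES)}
        retained.append(colony.subset(~any_fail))
        reports.append(
            QcReport(colony.colony_id, len(colony.sites), counts, int((~any_fail).sum()))
        )
    return retained, reports


def polishing_variant_filter(table: VcfSiteTable) -> np.ndarray:
    """Assembly-polishing candidate mask for single-sample diploid calls.

    Retains variants with QUAL >= 20 that are homozygous-alt, or
    heterozygous with zero reads supporting the reference allele.
    Heterozygous sites without an AD field are skipped with a warning.
    """
    if len(table.samples) != 1:
        raise ValueError("polishing filter expects a single-sample call set")
    g = table.genotypes[:, 0, :]
    qual_ok = table.annotations.qual.to_numpy() >= 20
    hom_alt = (g[:, 0] >= 1) & ((g[:, 1] == g[:, 0]) | (g[:, 1] < 0))
    het = (g[:, 0] >= 0) & (g[:, 1] >= 0) & (g[:, 0] != g[:, 1])
    if table.ref_depth is None:
        rd = np.full(len(table.sites), np.nan)
    else:
        rd = table.ref_depth[:, 0]
    no_ad = het & np.isnan(rd)
    if no_ad.any():
        logger.warning(
            "%d heterozygous sites lack AD and are skipped", int(no_ad.sum())
        )
    het_ok = het & (rd == 0)
    return qual_ok & (hom_alt | het_ok)
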