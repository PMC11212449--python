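"""End-to-end runs on simulated colonies and truth-based scoring.

Chains the stages -- simulate, QC, per-contig phasing with NCO
filtering, scaffolding, crossover calling -- and scores each inference
against the simulator's truth set: adjacency and orientation recovery
of the layout, detection rate of planted conversion tracts, genome-wide
recombination-rate recovery, and the mis-assembly hotspot diagnostic
obtained by deliberately inverting one contig of the evaluation layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import VcfSiteTable
from .phasing import (
    Bin,
    PhasedContig,
    build_bins,
    detect_nco_conversions,
    phase_contig,
    site_vectors,
)
from .qc import ColonyGenotypes, QcReport, filter_biological, filter_site_quality
from .recmap import (
    call_crossovers,
    detect_hotspots,
    map_length,
    project_bins,
)
from .scaffold import ContigEnds, ScaffoldLayout, contig_end_vectors_of, order_and_orient
from .simulate import SimConfig, TruthSet, fragment_into_contigs, simulate_colonies, sites_on_contigs


@dataclass
class PipelineResult:
    cfg: SimConfig
    truth: TruthSet
    colonies: list[ColonyGenotypes]
    qc_reports: list[QcReport]
    site_map: pd.DataFrame
    # colony -> contig -> phased (NCO-filtered) contig
    phased: dict[str, dict[str, PhasedContig]]
    unfiltered: dict[str, dict[str, PhasedContig]]
    flagged: dict[str, dict[str, list[Bin]]]
    contig_ends: dict[str, ContigEnds]
    assignment: dict[str, str]
    layout: ScaffoldLayout
    drone_names: dict[str, list[str]]
    events: pd.DataFrame
    map_summary: pd.DataFrame


def _phase_colonies(
    colonies: list[ColonyGenotypes],
    site_map: pd.DataFrame,
    nco_threshold: int = 2000,
):
    """Per colony and contig: vectors -> bins -> phase -> NCO filter."""
    phased: dict[str, dict[str, PhasedContig]] = {}
    unfiltered: dict[str, dict[str, PhasedContig]] = {}
    flagged: dict[str, dict[str, list[Bin]]] = {}
    drone_names: dict[str, list[str]] = {}
    for colony in colonies:
        codes, drones = site_vectors(colony)
        drone_names[colony.colony_id] = drones
        row_of = {
            k: i
            for i, k in enumerate(zip(colony.sites.chrom, colony.sites.pos))
        }
        phased[colony.colony_id] = {}
        unfiltered[colony.colony_id] = {}
        flagged[colony.colony_id] = {}
        for contig, grp in site_map.groupby("contig", sort=True):
            gkey = list(zip(grp.chrom, grp.pos))
            present = np.array([k in row_of for k in gkey])
            if not present.any():
                continue
            rows = np.array([row_of[k] for k, p in zip(gkey, present) if p])
            positions = grp.contig_pos.to_numpy()[present]
            bins = build_bins(positions, codes[rows], str(contig))
            if not bins:
                continue
            pc = phase_contig(bins)
            unfiltered[colony.colony_id][str(contig)] = pc
            fl, merged = detect_nco_conversions(pc, nco_threshold)
            phased[colony.colony_id][str(contig)] = merged
            flagged[colony.colony_id][str(contig)] = fl
    return phased, unfiltered, flagged, drone_names


def run_pipeline(cfg: SimConfig, nco_threshold: int = 2000) -> PipelineResult:
    """Simulate, QC, phase, scaffold and call crossovers; return everything."""
    tables, truth = simulate_colonies(cfg)
    contigs, assignment_table = fragment_into_contigs(cfg, truth)
    site_map = sites_on_contigs(cfg, truth)
    # attach master chrom/pos to the contig map
    master = pd.concat(
        [t.sites for t in tables.values()][:1], ignore_index=True
    )
    site_map = site_map.join(master[["chrom", "pos"]], on="site_index")

    colonies = []
    for name, table in tables.items():
        table = filter_site_quality(table)
        drones = [s for s in table.samples if s != f"{name}_queen"]
        reps = {
            d: f"{d}_rep" for d in drones if f"{d}_rep" in table.samples
        }
        drones = [d for d in drones]
        colonies.append(
            ColonyGenotypes.from_site_table(table, name, f"{name}_queen", drones, reps)
        )
    colonies, qc_reports = filter_biological(colonies)

    phased, unfiltered, flagged, drone_names = _phase_colonies(
        colonies, site_map, nco_threshold
    )

    contig_lengths = {
        r.contig: int(r.end - r.start) for r in truth.contig_layout.itertuples()
    }
    contig_ends = contig_end_vectors_of(phased, contig_lengths)
    assignment = dict(
        zip(assignment_table.contig, assignment_table.chrom)
    )
    layout = order_and_orient(contig_ends, assignment)

    events = _events_on_layout(layout, phased, drone_names)
    sizes = dict(zip(cfg.chrom_names, cfg.chromosome_lengths))
    summary = map_length(events, cfg.n_meioses, sizes)
    return PipelineResult(
        cfg,
        truth,
        colonies,
        qc_reports,
        site_map,
        phased,
        unfiltered,
        flagged,
        contig_ends,
        assignment,
        layout,
        drone_names,
        events,
        summary,
    )


def _events_on_layout(
    layout: ScaffoldLayout,
    phased: dict[str, dict[str, PhasedContig]],
    drone_names: dict[str, list[str]],
) -> pd.DataFrame:
    projected = {
        colony: project_bins(layout, phased[colony]) for colony in phased
    }
    return call_crossovers(projected, drone_names)


def events_and_map(
    res: PipelineResult, layout: ScaffoldLayout
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Crossover events and map summary under an arbitrary layout."""
    events = _events_on_layout(layout, res.phased, res.drone_names)
    sizes = dict(zip(res.cfg.chrom_names, res.cfg.chromosome_lengths))
    return events, map_length(events, res.cfg.n_meioses, sizes)


# ---------------------------------------------------------------------------
# truth-based scoring


def truth_adjacencies(truth: TruthSet) -> set[frozenset]:
    layout = truth.contig_layout
    pairs = set()
    for _, grp in layout.groupby("chrom"):
        ordered = grp.sort_values("order").contig.tolist()
        for a, b in zip(ordered, ordered[1:]):
            pairs.add(frozenset((a, b)))
    return pairs


def layout_adjacencies(layout: ScaffoldLayout) -> set[frozenset]:
    pairs = set()
    for path in layout.paths.values():
        for (a, _), (b, _) in zip(path, path[1:]):
            pairs.add(frozenset((a, b)))
    return pairs


def adjacency_recovery(layout: ScaffoldLayout, truth: TruthSet) -> float:
    """Fraction of truth contig adjacencies recovered by the layout."""
    want = truth_adjacencies(truth)
    got = layout_adjacencies(layout)
    return len(want & got) / len(want) if want else 1.0


def orientation_accuracy(layout: ScaffoldLayout, truth: TruthSet) -> float:
    """Fraction of oriented contigs matching truth, allowing whole-path
    reversal per chromosome (the map cannot see a global flip)."""
    truth_or = dict(zip(truth.contig_layout.contig, truth.contig_layout.orientation))
    flip = {"+": "-", "-": "+"}
    total, correct = 0, 0
    for path in layout.paths.values():
        oriented = [(c, o) for c, o in path if o in "+-"]
        if not oriented:
            continue
        same = sum(o == truth_or[c] for c, o in oriented)
        rev = sum(flip[o] == truth_or[c] for c, o in oriented)
        total += len(oriented)
        correct += max(same, rev)
    return correct / total if total else 1.0


def nco_detection_stats(res: PipelineResult, threshold: int = 2000) -> dict:
    """Detection rate of planted conversion tracts and crossover safety.

    A planted tract counts as detectable when it is shorter than the
    NCO length threshold and covers at least one informative SNP that
    survived QC; it counts as detected when a flagged bin on the right
    contig overlaps it (contig coordinates).  Crossover safety compares
    true-crossover recovery before and after NCO filtering.
    """
    truth = res.truth
    site_map = res.site_map
    layout = truth.contig_layout
    # contig placement lookup for converting chromosome to contig coords
    placement = {r.contig: r for r in layout.itertuples()}
    by_contig = {
        c: g for c, g in site_map.groupby("contig")
    }

    detectable = 0
    detected = 0
    for colony in res.colonies:
        cid = colony.colony_id
        retained = set(zip(colony.sites.chrom, colony.sites.pos))
        for drone, per_chrom in truth.conversion_tracts[cid].items():
            for chrom, tracts in per_chrom.items():
                for s, e in tracts:
                    if e - s >= threshold:
                        continue
                    # find the contig containing the tract
                    row = layout[(layout.chrom == chrom) & (layout.start <= s) & (layout.end >= e)]
                    if len(row) != 1:
                        continue  # tract spans a contig break
                    r = row.iloc[0]
                    grp = by_contig.get(r.contig)
                    if grp is None:
                        continue
                    inside = grp[(grp.pos >= s) & (grp.pos < e)]
                    inside = inside[
                        [
                            (c, p) in retained
                            for c, p in zip(inside.chrom, inside.pos)
                        ]
                    ]
                    if len(inside) == 0:
                        continue
                    detectable += 1
                    cps = set(inside.contig_pos)
                    hits = res.flagged.get(cid, {}).get(r.contig, [])
                    if any(
                        b.first_snp <= cp <= b.last_snp
                        for b in hits
                        for cp in cps
                    ):
                        detected += 1
    # crossover safety: recovered true crossovers before vs after filtering
    before = crossover_recovery(res, use_filtered=False)
    after = crossover_recovery(res, use_filtered=True)
    return {
        "detectable": detectable,
        "detected": detected,
        "detection_rate": detected / detectable if detectable else float("nan"),
        "true_crossovers_recovered_before": before["recovered"],
        "true_crossovers_recovered_after": after["recovered"],
        "crossovers_lost_by_filter": before["recovered"] - after["recovered"],
    }


def crossover_recovery(res: PipelineResult, use_filtered: bool = True) -> dict:
    """Match called events on the truth layout against true crossovers.

    Events are evaluated in true chromosome coordinates (truth layout,
    truth orientations), so every within-contig junction can be located
    exactly; an event matches when exactly one true crossover of that
    drone falls inside its localisation interval.
    """
    truth = res.truth
    phased = res.phased if use_filtered else res.unfiltered
    placement = {r.contig: r for r in truth.contig_layout.itertuples()}
    n_true = 0
    for cid in res.drone_names:
        for drone in res.drone_names[cid]:
            for chrom, xo in truth.crossovers[cid][drone].items():
                n_true += len(xo)
    recovered = 0
    called = 0
    for cid, per_contig in phased.items():
        names = res.drone_names[cid]
        for contig, pc in per_contig.items():
            r = placement[contig]
            for left, right in zip(pc.bins, pc.bins[1:]):
                a, b = left.vector, right.vector
                # contig coords -> chromosome coords
                if r.orientation == "-":
                    clen = r.end - r.start
                    lo = r.start + (clen - 1 - right.first_snp)
                    hi = r.start + (clen - 1 - left.last_snp)
                else:
                    lo = r.start + left.last_snp
                    hi = r.start + right.first_snp
                lo, hi = min(lo, hi), max(lo, hi)
                diff = np.flatnonzero((a >= 0) & (b >= 0) & (a != b))
                for di in diff:
                    called += 1
                    xo = truth.crossovers[cid][names[di]][r.chrom]
                    inside = np.count_nonzero((xo > lo) & (xo <= hi))
                    if inside >= 1:
                        recovered += 1
    return {"n_true": n_true, "called": called, "recovered": recovered}


def misassembly_experiment(res: PipelineResult) -> dict:
    """Invert one multi-crossover contig of the evaluation layout.

    Builds the truth layout, re-calls events, then inverts the contig
    with the most internal events and compares: the wrong layout should
    show pooled >5-event hotspots at the inversion breakpoints and a
    longer estimated map (the classic mis-assembly artefact).
    """
    truth_layout = layout_from_truth(res.truth)
    events_ok, map_ok = events_and_map(res, truth_layout)

    # most internally-recombinant contig that is not at a path end
    internal = {}
    for per_contig in res.phased.values():
        for contig, pc in per_contig.items():
            internal[contig] = internal.get(contig, 0) + pc.total_recombinations
    candidates = []
    for chrom, path in truth_layout.paths.items():
        for c, _ in path[1:-1]:
            candidates.append(c)
    target = max(candidates, key=lambda c: internal.get(c, 0))

    bad_layout = truth_layout.with_inverted(target)
    events_bad, map_bad = events_and_map(res, bad_layout)
    hot_ok = detect_hotspots(events_ok)
    hot_bad = detect_hotspots(events_bad)
    # hotspots at the junctions flanking the inverted contig
    breakpoint_hot = hot_bad.merge(
        events_bad[
            (events_bad.left_contig == target) | (events_bad.right_contig == target)
        ][["chrom", "start", "end"]].drop_duplicates(),
        on=["chrom", "start", "end"],
    )
    total_ok = map_ok.iloc[-1].genetic_morgans
    total_bad = map_bad.iloc[-1].genetic_morgans
    return {
        "inverted_contig": target,
        "map_morgans_correct": float(total_ok),
        "map_morgans_inverted": float(total_bad),
        "rate_correct_cm_mb": float(map_ok.iloc[-1].cm_per_mb),
        "rate_inverted_cm_mb": float(map_bad.iloc[-1].cm_per_mb),
        "n_hotspots_correct": int(len(hot_ok)),
        "n_breakpoint_hotspots": int(len(breakpoint_hot)),
    }


def layout_from_truth(truth: TruthSet) -> ScaffoldLayout:
    """The true contig order/orientation as a ScaffoldLayout."""
    paths = {}
    lengths = {}
    for chrom, grp in truth.contig_layout.groupby("chrom"):
        ordered = grp.sort_values("order")
        paths[chrom] = list(zip(ordered.contig, ordered.orientation))
        for r in ordered.itertuples():
            lengths[r.contig] = int(r.end - r.start)
    return ScaffoldLayout(paths, {}, lengths)
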