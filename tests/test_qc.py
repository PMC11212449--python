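"""Hard site filters and the five biological discard rules."""

import numpy as np
import pandas as pd
import pytest

from conftest import tiny_config
from dronemap.io import MISSING, NO_ALLELE, VcfSiteTable
from dronemap.qc import (
    RULES,
    ColonyGenotypes,
    filter_biological,
    filter_site_quality,
    polishing_variant_filter,
)
from dronemap.simulate import simulate_colonies

HET = ColonyGenotypes.HET


def make_table(rows, samples, quals=None):
    """rows: list of per-sample genotype pairs; annotations optional."""
    n = len(rows)
    sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * n,
            "pos": np.arange(n) * 100,
            "ref": ["A"] * n,
            "alts": [("T",)] * n,
        }
    )
    gts = np.array(rows, dtype=np.int16)
    ann = pd.DataFrame(
        {
            "qual": quals if quals is not None else [1000.0] * n,
            "fs": [1.0] * n,
            "mq": [60.0] * n,
            "sor": [1.0] * n,
        }
    )
    return VcfSiteTable(sites, samples, gts, ann)


class TestSiteQuality:
    @pytest.mark.parametrize(
        "fs,mq,sor,missing,kept",
        [
            (61, 60, 1, False, False),  # FS just over the printed threshold
            (60, 50, 3, False, True),   # boundary values pass (strict >/<)
            (1, 60, 1, True, False),    # one missing genotype discards the site
            (1, 49, 1, False, False),
            (1, 60, 3.1, False, False),
        ],
    )
    def test_hard_filters(self, fs, mq, sor, missing, kept):
        table = make_table(
            [[[0, 1], [MISSING if missing else 0, NO_ALLELE]]], ["queen", "d1"]
        )
        table.annotations.loc[0, ["fs", "mq", "sor"]] = [fs, mq, sor]
        out = filter_site_quality(table)
        assert (out.n_sites == 1) == kept


def colony(cid, queen_rows, drone_rows, drones, reps=None):
    n = len(queen_rows)
    sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * n,
            "pos": np.arange(n) * 100,
            "ref": ["A"] * n,
            "alts": [("T", "G")] * n,
        }
    )
    return ColonyGenotypes(
        cid,
        sites,
        np.array(queen_rows, dtype=np.int16),
        np.array(drone_rows, dtype=np.int16),
        drones,
        reps or {},
    )


def brute_force_rules(colonies):
    """Independent per-rule reimplementation on plain python sets."""
    results = []
    n = len(colonies[0].sites)
    for ci, col in enumerate(colonies):
        per_site = []
        for i in range(n):
            q = [int(a) for a in col.queen[i]]
            d = [int(a) for a in col.drones[i]]
            obs = [a for a in d if a >= 0]
            fails = {}
            pooled = set()
            for other in colonies:
                pooled |= {int(a) for a in other.queen[i] if a >= 0}
                pooled |= {int(a) for a in other.drones[i] if a >= 0}
            fails["non_polymorphic"] = len(pooled) <= 1
            fails["queen_homozygous"] = q[0] == q[1]
            fails["drone_heterozygous"] = any(a == HET for a in d)
            rep = False
            for a, b in col.replicate_pairs.items():
                va = d[col.drone_names.index(a)]
                vb = d[col.drone_names.index(b)]
                if va >= 0 and vb >= 0 and va != vb:
                    rep = True
            fails["replicate_discordant"] = rep
            union = set()
            for cj, other in enumerate(colonies):
                if cj != ci:
                    union |= {int(a) for a in other.queen[i] if a >= 0}
            mine = set(q) | set(obs)
            fails["cross_colony"] = bool(union) and (
                mine.isdisjoint(union) or not mine <= union
            )
            fails["allele_not_in_queen"] = any(a not in q for a in obs)
            first = next((r for r in RULES if fails[r]), None)
            per_site.append(first)
        results.append(per_site)
    return results


class TestBiologicalRules:
    def test_planted_violations_match_bruteforce_oracle(self):
        # 12 sites x 3 colonies with one planted violation per rule
        Q = [0, 1]
        # d4 is d1's replicate in c1, so default rows keep them equal
        rows_q = {f"c{k}": [list(Q) for _ in range(12)] for k in (1, 2, 3)}
        rows_d = {
            f"c{k}": [[0, 1, 0, 0] for _ in range(12)] for k in (1, 2, 3)
        }
        # site 0: non-polymorphic everywhere (all queens hom-0, drones 0)
        for k in (1, 2, 3):
            rows_q[f"c{k}"][0] = [0, 0]
            rows_d[f"c{k}"][0] = [0, 0, 0, 0]
        # site 1: queen of c1 homozygous (still polymorphic via others)
        rows_q["c1"][1] = [1, 1]
        rows_d["c1"][1] = [1, 1, 1, 1]
        # site 2: heterozygous drone call in c1
        rows_d["c1"][2] = [HET, 1, 0, 1]
        # site 3: replicate pair of c1 disagrees
        rows_d["c1"][3] = [1, 1, 0, 0]
        # site 4: c1 observes allele 2 unseen in other queens (cross-colony)
        rows_q["c1"][4] = [0, 2]
        rows_d["c1"][4] = [0, 2, 0, 0]
        # site 5: drone allele absent from own queen (but seen in others)
        rows_q["c2"][5] = [0, 2]
        rows_d["c1"][5] = [0, 2, 0, 0]
        # site 6: missing drone calls but otherwise fine
        rows_d["c3"][6] = [-1, 1, 0, -1]

        reps = {"d1": "d4"}
        cols = [
            colony(f"c{k}", rows_q[f"c{k}"], rows_d[f"c{k}"], ["d1", "d2", "d3", "d4"], reps if k == 1 else None)
            for k in (1, 2, 3)
        ]
        # plant the replicate discordance: d1 != d4 at site 3 of c1
        assert cols[0].drones[3, 0] != cols[0].drones[3, 3]

        retained, reports = filter_biological(cols)
        oracle = brute_force_rules(cols)
        for col, rep, expect in zip(cols, reports, oracle):
            got = {r: 0 for r in RULES}
            for first in expect:
                if first:
                    got[first] += 1
            assert rep.discarded == got
            keep = [i for i, f in enumerate(expect) if f is None]
            assert rep.n_retained == len(keep)

    def test_single_colony_skips_cross_colony_rule(self):
        c = colony("c1", [[0, 1]] * 2, [[0, 1], [1, 0]], ["d1", "d2"])
        with pytest.warns(UserWarning):
            retained, reports = filter_biological([c])
        assert reports[0].discarded["cross_colony"] == 0

    def test_idempotent_on_simulated_colonies(self):
        cfg = tiny_config(colonies=((6, 1), (6, 0)), genotyping_error_rate=0.01)
        tables, truth = simulate_colonies(cfg)
        cols = []
        for name, table in tables.items():
            drones = [s for s in table.samples if not s.endswith("_queen")]
            reps = {d: f"{d}_rep" for d in drones if f"{d}_rep" in table.samples}
            cols.append(
                ColonyGenotypes.from_site_table(table, name, f"{name}_queen", drones, reps)
            )
        once, _ = filter_biological(cols)
        twice, reports2 = filter_biological(once)
        for a, b, rep in zip(once, twice, reports2):
            assert len(a.sites) == len(b.sites)
            assert sum(rep.discarded.values()) == 0

    def test_clean_simulation_triggers_no_consistency_rules(self):
        cfg = tiny_config(genotyping_error_rate=0.0, colonies=((8, 1), (8, 0)))
        tables, _ = simulate_colonies(cfg)
        cols = []
        for name, table in tables.items():
            drones = [s for s in table.samples if not s.endswith("_queen")]
            reps = {d: f"{d}_rep" for d in drones if f"{d}_rep" in table.samples}
            cols.append(
                ColonyGenotypes.from_site_table(table, name, f"{name}_queen", drones, reps)
            )
        _, reports = filter_biological(cols)
        for rep in reports:
            for rule in RULES[2:]:
                assert rep.discarded[rule] == 0

    def test_report_fractions_sum_to_one(self):
        cfg = tiny_config(genotyping_error_rate=0.01)
        tables, _ = simulate_colonies(cfg)
        table = tables["colony1"]
        drones = [s for s in table.samples if not s.endswith("_queen")]
        reps = {d: f"{d}_rep" for d in drones if f"{d}_rep" in table.samples}
        col = ColonyGenotypes.from_site_table(table, "colony1", "colony1_queen", drones, reps)
        with pytest.warns(UserWarning):
            _, (rep,) = filter_biological([col])
        assert sum(rep.discarded.values()) + rep.n_retained == rep.n_input
        assert rep.as_frame().fraction.sum() == pytest.approx(1.0)


class TestPolishingFilter:
    @pytest.mark.parametrize(
        "qual,gt,ref_depth,kept",
        [
            (19, (1, 1), 5.0, False),   # below the quality threshold
            (20, (1, 1), 5.0, True),
            (30, (0, 1), 0.0, True),    # het with no ref-supporting read
            (30, (0, 1), 2.0, False),
            (30, (0, 0), 0.0, False),   # hom-ref never a correction
        ],
    )
    def test_retention_rule(self, qual, gt, ref_depth, kept):
        table = make_table([[list(gt)]], ["s"], quals=[qual])
        table.ref_depth = np.array([[ref_depth]])
        assert polishing_variant_filter(table)[0] == kept

    def test_het_without_ad_skipped(self):
        table = make_table([[[0, 1]]], ["s"], quals=[30])
        assert not polishing_variant_filter(table)[0]
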