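"""AIM/AIG catalogs, PGx enrichment, Δ statistics, cross-tabulation."""

import numpy as np
import pandas as pd
import pytest

from pgxancestry import synthetic_data as sd
from pgxancestry.catalogs import (
    aig_scan,
    aim_scan,
    delta_max,
    enrichment_from_counts,
    enrichment_test,
    pgx_crosstab,
    shared_within_continental_aims,
)
from pgxancestry.core_io import GenotypeMatrix, PGxTable
from pgxancestry.popstruct import GroupSpec, make_group_spec


def _gm(dosage, samples):
    dosage = np.asarray(dosage, dtype=np.int8)
    return GenotypeMatrix(
        samples, [f"v{j}" for j in range(dosage.shape[1])], dosage
    )


class TestDeltaMax:
    def test_published_continental_frequencies(self):
        """MTHFR C677T allele-T continental frequencies give delta 0.384."""
        assert delta_max([0.090, 0.119, 0.296, 0.365, 0.474]) == pytest.approx(0.384)

    def test_published_east_asian_frequencies(self):
        assert delta_max([0.134, 0.192, 0.286, 0.380, 0.466]) == pytest.approx(0.332)

    def test_equal_frequencies_zero(self):
        assert delta_max([0.25, 0.25, 0.25]) == 0.0

    def test_symmetric_under_allele_flip(self):
        f = np.array([0.1, 0.5, 0.7])
        assert delta_max(f) == pytest.approx(delta_max(1 - f))

    def test_undefined_below_two_values(self):
        assert np.isnan(delta_max([0.3, np.nan]))


class TestAimScan:
    def test_identical_counts_no_aims(self):
        """Two subgroups with identical allele counts at every variant."""
        rng = np.random.default_rng(0)
        block = rng.integers(0, 3, size=(50, 30)).astype(np.int8)
        dosage = np.vstack([block, block])
        samples = [f"a{i}" for i in range(50)] + [f"b{i}" for i in range(50)]
        gm = _gm(dosage, samples)
        spec = GroupSpec("G", {"A": samples[:50], "B": samples[50:]})
        res = aim_scan(gm, spec, families=("SNV",))
        assert res.records["p"].min() == pytest.approx(1.0)
        assert not res.records["is_aim"].any()
        assert res.summary.loc[0, "p_aim"] == 0.0

    def test_power_under_strong_differentiation(self):
        """F=0.15, 5 groups x 100, 500 common loci: P_AIM >= 0.5."""
        props = []
        for seed in range(3):
            cfg = sd.SimConfig(
                seed=seed,
                continents=tuple(
                    sd.ContinentSpec(code, 0.15, (sd.PopulationSpec(f"{code}1", 100, 0.0),))
                    for code in ("AFR", "AMR", "EAS", "EUR", "SAS")
                ),
                n_loci=500,
                w_common=1.0,
            )
            sim = sd.simulate_dataset(cfg)
            spec = make_group_spec(sim.samples, "ALL")
            res = aim_scan(sim.gm, spec, families=("SNV",), mc_reps=2000, seed=seed)
            props.append(res.summary.loc[0, "p_aim"])
        assert np.mean(props) >= 0.5

    def test_fdr_control_under_global_null(self):
        """F=0: adjusted p < 0.05 occurs in almost no seeds."""
        n_flagged = 0
        for seed in range(10):
            cfg = sd.SimConfig(
                seed=seed,
                continents=tuple(
                    sd.ContinentSpec(code, 0.0, (sd.PopulationSpec(f"{code}1", 40, 0.0),))
                    for code in ("AFR", "EAS", "EUR")
                ),
                n_loci=200,
                w_common=1.0,
            )
            sim = sd.simulate_dataset(cfg)
            spec = make_group_spec(sim.samples, "ALL")
            res = aim_scan(sim.gm, spec, families=("SNV",), mc_reps=2000, seed=seed)
            n_flagged += int(res.summary.loc[0, "n_aim"] > 0)
        assert n_flagged <= 1

    def test_invariant_to_subgroup_order_and_allele_flip(self):
        rng = np.random.default_rng(4)
        dosage = rng.integers(0, 3, size=(40, 20)).astype(np.int8)
        samples = [f"s{i}" for i in range(40)]
        gm = _gm(dosage, samples)
        spec_ab = GroupSpec("G", {"A": samples[:20], "B": samples[20:]})
        spec_ba = GroupSpec("G", {"B": samples[20:], "A": samples[:20]})
        flipped = _gm((2 - dosage).astype(np.int8), samples)
        p0 = aim_scan(gm, spec_ab, families=("SNV",), seed=1).records["p"]
        p1 = aim_scan(gm, spec_ba, families=("SNV",), seed=1).records["p"]
        p2 = aim_scan(flipped, spec_ab, families=("SNV",), seed=1).records["p"]
        assert p0.to_numpy() == pytest.approx(p1.to_numpy())
        assert p0.to_numpy() == pytest.approx(p2.to_numpy())

    def test_family_partition(self, small_sim):
        spec = make_group_spec(small_sim.samples, "ALL")
        sub = small_sim.gm.subset_variants(np.arange(400))
        res = aim_scan(sub, spec, mc_reps=500, seed=0)
        s = res.summary.set_index("family")
        assert (
            s.loc["SNP", "n_tested"] + s.loc["RV", "n_tested"] + s.loc["SNP_RV", "n_tested"]
            == s.loc["SNV", "n_tested"]
        )


class TestEnrichment:
    def test_published_table_proportions(self):
        """African-ancestry printed 2x2 counts reproduce P_AIM|PGx = 26.97%
        and P_AIM = 8.96%; the whole-continental counts give 98.04%."""
        afr = enrichment_from_counts(879, 3_830_817, 2_380, 38_934_065, "AFR")
        assert afr.p_aim_given_pgx * 100 == pytest.approx(26.97, abs=0.005)
        assert afr.p_aim * 100 == pytest.approx(8.96, abs=0.005)
        assert afr.counts.n_pgx == 3259
        world = enrichment_from_counts(3_195, 28_528_004, 64, 73_462_356, "ALL")
        assert world.p_aim_given_pgx * 100 == pytest.approx(98.04, abs=0.005)
        assert world.p_aim * 100 == pytest.approx(27.97, abs=0.005)

    def test_proportions_recompute_from_counts(self):
        res = enrichment_from_counts(10, 40, 20, 130)
        c = res.counts
        assert res.p_aim == (c.a + c.b) / c.total
        assert res.p_aim_given_pgx == c.a / (c.a + c.c)

    def test_everything_pgx_p_one(self):
        res = enrichment_test([True, False, True], [True, True, True])
        assert res.p == pytest.approx(1.0)
        assert res.p_aim == res.p_aim_given_pgx

    def test_zero_pgx_flagged_undefined(self):
        res = enrichment_test([True, False], [False, False])
        assert np.isnan(res.p_aim_given_pgx)

    def test_beta_above_one_enriches(self):
        """PGx loci simulated with elevated differentiation produce OR > 1
        in most seeds; beta = 1 stays calibrated."""
        def run(seed, beta):
            cfg = sd.SimConfig(
                seed=seed,
                continents=tuple(
                    sd.ContinentSpec(code, 0.05, (sd.PopulationSpec(f"{code}1", 30, 0.0),))
                    for code in ("AFR", "EAS", "EUR", "SAS", "AMR")
                ),
                n_loci=300,
                w_common=1.0,
                pgx=sd.PGxSpec(fraction_labeled=0.3, differentiation_multiplier=beta),
            )
            sim = sd.simulate_dataset(cfg)
            spec = make_group_spec(sim.samples, "ALL")
            res = aim_scan(sim.gm, spec, families=("SNV",), mc_reps=1000, seed=seed)
            rec = res.records
            aim_flags = rec["is_aim"].to_numpy()
            pgx_member = rec["variant"].isin(sim.pgx.loci).to_numpy()
            return enrichment_test(aim_flags, pgx_member)

        or_wins = sum(run(s, 4.0).odds_ratio > 1 for s in range(10))
        assert or_wins >= 9
        null_rejects = sum(run(100 + s, 1.0).p < 0.05 for s in range(20))
        assert null_rejects <= 3


class TestAigScan:
    def _intensities(self, a_vals, b_vals):
        n_a, n_b = len(a_vals), len(b_vals)
        idx = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
        spec = GroupSpec("G", {"A": idx[:n_a], "B": idx[n_a:]})
        df = pd.DataFrame({"g1": np.concatenate([a_vals, b_vals])}, index=idx)
        return df, spec

    def test_identical_distributions_no_aigs(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, 30)
        df, spec = self._intensities(vals, vals)
        out = aig_scan(df, spec)
        assert not out["is_aig"].any()

    def test_shifted_gene_detected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = np.clip(rng.normal(0.3, 0.1, 50), 0, 1)
            b = np.clip(rng.normal(0.7, 0.1, 50), 0, 1)
            df, spec = self._intensities(a, b)
            hits += bool(aig_scan(df, spec)["is_aig"].iloc[0])
        assert hits >= 9

    def test_single_gene_bh_identity(self):
        rng = np.random.default_rng(1)
        df, spec = self._intensities(rng.uniform(0, 1, 10), rng.uniform(0, 1, 10))
        out = aig_scan(df, spec)
        assert out["p_adj"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_insufficient_loci_gene_skipped(self):
        idx = [f"s{i}" for i in range(8)]
        df = pd.DataFrame({"g1": np.full(8, np.nan), "g2": np.linspace(0, 1, 8)}, index=idx)
        spec = GroupSpec("G", {"A": idx[:4], "B": idx[4:]})
        out = aig_scan(df, spec).set_index("gene")
        assert bool(out.loc["g1", "skipped"])
        assert not bool(out.loc["g2", "skipped"])


class TestCrosstab:
    def _pgx(self, rows):
        return PGxTable(pd.DataFrame(
            [{"locus": l, "source": "PharmGKB", "drug_category": c, "drugs": ""}
             for l, c in rows]
        ))

    def test_toy_counts_and_marginals(self):
        pgx = self._pgx([("r1", "PD"), ("r2", "PD"), ("r3", "PK")])
        ann = {"r1": "intron", "r2": "missense", "r3": "intron"}
        tab = pgx_crosstab(pgx, ann)
        assert tab.loc["PD", "All"] == 2 and tab.loc["PK", "All"] == 1
        assert tab.loc["All", "intron"] == 2 and tab.loc["All", "missense"] == 1
        inner = tab.drop(index="All", columns="All")
        assert inner.sum().sum() == tab.loc["All", "All"]

    def test_unmatched_loci_counted_unannotated(self):
        pgx = self._pgx([("r1", "PD")])
        tab = pgx_crosstab(pgx, {})
        assert tab.loc["PD", "unannotated"] == 1

    def test_empty_table_all_zero(self):
        pgx = PGxTable(pd.DataFrame(columns=["locus", "source", "drug_category", "drugs"]))
        tab = pgx_crosstab(pgx, {})
        assert tab.loc["All", "All"] == 0


class TestSharedAims:
    def test_set_algebra(self):
        cats = {"AFR": {"A", "B"}, "EAS": {"B", "C"}, "EUR": {"B"}}
        full, venn = shared_within_continental_aims(cats)
        assert full == {"B"}
        v = venn.set_index("groups")["n_exact"]
        assert v["AFR+EAS+EUR"] == 1   # B
        assert v["AFR"] == 1           # A only
        assert v["EAS"] == 1           # C only
        assert v["AFR+EAS"] == 0

    def test_disjoint_and_identical(self):
        full, _ = shared_within_continental_aims({"A": {"x"}, "B": {"y"}})
        assert full == set()
        full2, _ = shared_within_continental_aims({"A": {"x", "y"}, "B": {"x", "y"}})
        assert full2 == {"x", "y"}
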