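"""Homozygosity-intensity profiling, HD-region calling, group differences."""

import numpy as np
import pandas as pd
import pytest

from pgxancestry import synthetic_data as sd
from pgxancestry.core_io import GenotypeMatrix, GeneRegionSet, VariantRecord
from pgxancestry.hd import (
    HomozygosityProfile,
    WindowConfig,
    call_hd_regions,
    gene_intensity,
    gene_intensity_matrix,
    hd_group_difference,
    homozygosity_indicators,
    local_intensity,
    profile_genome,
)
from pgxancestry.popstruct import GroupSpec, allele_counts_by_group, make_group_spec


def _gm(dosage):
    dosage = np.asarray(dosage, dtype=np.int8)
    return GenotypeMatrix(
        [f"s{i}" for i in range(dosage.shape[0])],
        [f"v{j}" for j in range(dosage.shape[1])],
        dosage,
    )


class TestIndicators:
    def test_coding(self):
        gm = _gm([[0, 1, 2, -1]])
        ind = homozygosity_indicators(gm)
        assert ind[0, :3].tolist() == [1.0, 0.0, 1.0]
        assert np.isnan(ind[0, 3])

    def test_all_het_and_all_hom_rows(self):
        gm = _gm([[1, 1, 1], [0, 2, 0]])
        ind = homozygosity_indicators(gm)
        assert ind[0].tolist() == [0.0, 0.0, 0.0]
        assert ind[1].tolist() == [1.0, 1.0, 1.0]

    def test_invariant_under_allele_relabeling(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(5, 40)).astype(np.int8)
        flipped = (2 - d).astype(np.int8)
        assert np.array_equal(
            homozygosity_indicators(_gm(d)), homozygosity_indicators(_gm(flipped))
        )


class TestLocalIntensity:
    def test_constant_windows(self):
        pos = np.arange(100, 100 + 21 * 50, 50, dtype=float)
        mafs = np.full(21, 0.3)
        ones = np.ones(21)
        zeros = np.zeros(21)
        assert local_intensity(ones, pos, mafs, 10, half_window=10) == pytest.approx(1.0)
        assert local_intensity(zeros, pos, mafs, 10, half_window=10) == pytest.approx(0.0)

    def test_degree0_equal_weight_mean(self):
        """With all loci at the anchor position every weight is equal and the
        degree-0 fit is the plain mean: (1,1,1,0) -> 0.75."""
        pos = np.full(4, 500.0)
        val = local_intensity(
            np.array([1.0, 1.0, 1.0, 0.0]), pos, np.full(4, 0.3),
            anchor_index=1, half_window=3, degree=0, min_loci=2,
        )
        assert val == pytest.approx(0.75)

    def test_degree0_matches_weighted_mean_oracle(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.uniform(0, 1e5, 31))
        y = rng.integers(0, 2, 31).astype(float)
        mafs = rng.uniform(0.0, 0.5, 31)
        a = 15
        val = local_intensity(y, pos, mafs, a, half_window=15, degree=0, min_loci=2)
        t = pos - pos[a]
        h = np.abs(t).max()
        u = np.abs(t / h)
        kern = np.where(u <= 1, (1 - u**3) ** 3, 0.0)
        w = kern * np.where(mafs >= 0.05, 1.0, mafs / 0.05)
        assert val == pytest.approx(np.clip((w * y).sum() / w.sum(), 0, 1), abs=1e-12)

    def test_missing_get_zero_weight(self):
        pos = np.arange(10, dtype=float) * 100
        y = np.ones(10)
        y[3] = np.nan
        v = local_intensity(y, pos, np.full(10, 0.4), 5, half_window=5, min_loci=2)
        assert v == pytest.approx(1.0)

    def test_insufficient_loci_undefined(self):
        pos = np.arange(5, dtype=float)
        v = local_intensity(np.ones(5), pos, np.full(5, 0.3), 2, half_window=2, min_loci=10)
        assert np.isnan(v)

    def test_monotone_in_indicators_degree0(self):
        """Raising one indicator 0 -> 1 never decreases the degree-0 fit."""
        rng = np.random.default_rng(3)
        pos = np.sort(rng.uniform(0, 5e4, 21))
        mafs = rng.uniform(0.01, 0.5, 21)
        y = rng.integers(0, 2, 21).astype(float)
        base = local_intensity(y, pos, mafs, 10, half_window=10, degree=0, min_loci=2)
        for j in np.flatnonzero(y == 0):
            y2 = y.copy()
            y2[j] = 1.0
            v = local_intensity(y2, pos, mafs, 10, half_window=10, degree=0, min_loci=2)
            assert v >= base - 1e-12


class TestGeneIntensity:
    def test_all_homozygous_gene(self):
        ind = np.ones((2, 12))
        pos = np.arange(12) * 100 + 1000
        val = gene_intensity(ind, pos, np.full(12, 0.3), (1000, 2200))
        assert val == pytest.approx([1.0, 1.0])

    def test_half_hom_half_het_equal_weights(self):
        ind = np.array([[1.0] * 6 + [0.0] * 6])
        pos = np.arange(12) * 10 + 50
        val = gene_intensity(ind, pos, np.full(12, 0.2), (0, 500), min_loci=5)
        assert val[0] == pytest.approx(0.5)

    def test_rare_locus_downweighted_hand_example(self):
        """One homozygous common SNV (w=1) + one het rare SNV (w=0.1):
        intensity 1/(1.1)."""
        ind = np.array([[1.0, 0.0]])
        pos = np.array([100.0, 200.0])
        val = gene_intensity(ind, pos, np.array([0.3, 0.005]), (50, 250), min_loci=1)
        assert val[0] == pytest.approx(1 / 1.1, abs=1e-9)

    def test_insufficient_loci_flagged(self):
        ind = np.ones((1, 3))
        pos = np.array([10.0, 20.0, 5000.0])
        val = gene_intensity(ind, pos, np.full(3, 0.3), (0, 100), min_loci=5)
        assert np.isnan(val[0])


def _variants(positions, chrom="1"):
    return [
        VariantRecord(f"v{j}", chrom, int(p), "A", "G")
        for j, p in enumerate(positions)
    ]


class TestProfileGenome:
    def test_fully_homozygous_flat_at_one(self):
        n_loci = 300
        d = np.zeros((2, n_loci), dtype=np.int8)
        d[1, :] = 2
        gm = _gm(d)
        variants = _variants(np.arange(n_loci) * 1000 + 1)
        prof = profile_genome(gm, variants, np.full(n_loci, 0.3), WindowConfig())
        assert np.nanmin(prof.intensity["1"]) == pytest.approx(1.0)

    def test_alternating_het_hom_near_half(self):
        n_loci = 400
        d = np.tile(np.array([0, 1], dtype=np.int8), n_loci // 2)[None, :]
        gm = _gm(d)
        variants = _variants(np.arange(n_loci) * 500 + 1)
        prof = profile_genome(gm, variants, np.full(n_loci, 0.4), WindowConfig())
        inner = prof.intensity["1"][0, 8:-8]
        assert np.all(np.abs(inner - 0.5) < 0.05)

    def test_short_chromosome_skipped_with_warning(self):
        d = np.zeros((1, 5), dtype=np.int8)
        gm = _gm(d)
        variants = _variants([10, 20, 30, 40, 50])
        with pytest.warns(UserWarning, match="skipped"):
            prof = profile_genome(gm, variants, np.full(5, 0.3), WindowConfig())
        assert prof.anchors == {}

    def test_unsorted_positions_rejected(self):
        d = np.zeros((1, 20), dtype=np.int8)
        gm = _gm(d)
        pos = list(range(1, 21))
        pos[3], pos[4] = pos[4], pos[3]
        with pytest.raises(ValueError, match="sorted"):
            profile_genome(gm, _variants(pos), np.full(20, 0.3),
                           WindowConfig(min_loci=2))


class TestCallRegions:
    def _profile(self, values, positions):
        return HomozygosityProfile(
            samples=["s0"],
            anchors={"1": np.asarray(positions, dtype=float)},
            intensity={"1": np.asarray(values, dtype=float)[None, :]},
        )

    def test_single_run_with_length(self):
        prof = self._profile([0.95, 0.97, 0.99], [1_000_000, 1_500_000, 2_000_000])
        regions, summary = call_hd_regions(prof)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (1_000_000, 2_000_000)
        assert r.length == 1_000_001
        assert summary.n_regions["s0"] == 1
        assert summary.lengths["s0"] == [1_000_001]

    def test_no_region_below_threshold(self):
        prof = self._profile([0.9, 0.85, 0.2], [1, 2, 3])
        regions, summary = call_hd_regions(prof)
        assert regions == [] and summary.n_regions["s0"] == 0

    def test_split_runs(self):
        prof = self._profile([0.95, 0.5, 0.95], [10, 20, 30])
        regions, _ = call_hd_regions(prof)
        assert [(r.start, r.end) for r in regions] == [(10, 10), (30, 30)]

    def test_nan_breaks_runs(self):
        prof = self._profile([0.95, np.nan, 0.95], [10, 20, 30])
        regions, _ = call_hd_regions(prof)
        assert len(regions) == 2

    def test_false_positive_rate_on_hwe_genotypes(self):
        """Without injected ROH, common-variant HWE genotypes stay under HD
        threshold at nearly every anchor."""
        rng = np.random.default_rng(8)
        n_loci = 2000
        p = rng.uniform(0.2, 0.8, n_loci)
        d = rng.binomial(2, p, size=(20, n_loci)).astype(np.int8)
        gm = _gm(d)
        variants = _variants(np.arange(n_loci) * 2000 + 1)
        maf = np.minimum(p, 1 - p)
        prof = profile_genome(gm, variants, maf, WindowConfig())
        mat = prof.intensity["1"]
        frac_above = np.mean(np.nan_to_num(mat, nan=0.0) > 0.9)
        assert frac_above <= 0.02


class TestRohRecovery:
    def test_injected_roh_profile_above_threshold(self):
        """Profiles inside a long injected ROH sit above 0.9 over >= 80% of
        its span, and region calling recovers >= 90% of long segments."""
        cfg = sd.SimConfig(
            seed=5,
            continents=(
                sd.ContinentSpec("EUR", 0.05, (sd.PopulationSpec("P1", 12, 0.0),)),
            ),
            n_loci=6000,
            w_common=1.0,
            roh={"EUR": sd.ROHSpec(3.0, 4_000_000.0)},
            chrom_length_bp=60_000_000,
        )
        sim = sd.simulate_dataset(cfg)
        gs = make_group_spec(sim.samples, "EUR")
        maf = allele_counts_by_group(sim.gm, gs)
        prof = profile_genome(sim.gm, sim.variants, maf.pooled_maf, WindowConfig())
        regions, _ = call_hd_regions(prof)
        pos = prof.anchors["1"]
        sample_idx = {s: i for i, s in enumerate(prof.samples)}

        truth = sim.roh_truth
        truth = truth[truth["n_loci"] >= 50]
        assert len(truth) >= 10
        recovered = 0
        span_cov = []
        for t in truth.itertuples():
            i = sample_idx[t.sample]
            inside = (pos >= t.start) & (pos <= t.end)
            vals = prof.intensity["1"][i, inside]
            vals = vals[~np.isnan(vals)]
            if len(vals):
                span_cov.append(np.mean(vals > 0.9))
            # overlap >= 50% with any called region of this individual
            length = t.end - t.start + 1
            for r in regions:
                if r.sample != t.sample:
                    continue
                ov = min(r.end, t.end) - max(r.start, t.start) + 1
                if ov >= 0.5 * length:
                    recovered += 1
                    break
        assert recovered / len(truth) >= 0.9
        assert np.mean([c >= 0.8 for c in span_cov]) >= 0.8


class TestGroupDifference:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.3, 0.7, size=40)
        df = pd.DataFrame({"r1": vals, "r2": vals[::-1]},
                          index=[f"s{i}" for i in range(40)])
        spec = GroupSpec("G", {"a": [f"s{i}" for i in range(20)],
                               "b": [f"s{i}" for i in range(20, 40)]})
        res, prop = hd_group_difference(df.sample(frac=1, random_state=1), spec)
        assert (res["p"] > 0.05).all() or prop <= 0.5

    def test_constant_region_p_one(self):
        df = pd.DataFrame({"r1": np.full(20, 0.5)}, index=[f"s{i}" for i in range(20)])
        spec = GroupSpec("G", {"a": [f"s{i}" for i in range(10)],
                               "b": [f"s{i}" for i in range(10, 20)]})
        res, _ = hd_group_difference(df, spec)
        assert res["H"].iloc[0] == 0.0 and res["p"].iloc[0] == 1.0

    def test_shifted_medians_detected(self):
        """A 0.3 intensity shift with n=50/group is nearly always significant."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            a = np.clip(rng.normal(0.4, 0.1, 50), 0, 1)
            b = np.clip(rng.normal(0.7, 0.1, 50), 0, 1)
            df = pd.DataFrame({"r": np.concatenate([a, b])},
                              index=[f"s{i}" for i in range(100)])
            spec = GroupSpec("G", {"a": [f"s{i}" for i in range(50)],
                                   "b": [f"s{i}" for i in range(50, 100)]})
            res, _ = hd_group_difference(df, spec)
            hits += bool(res["significant"].iloc[0])
        assert hits >= 0.95 * n_seeds

    def test_single_subgroup_rejected(self):
        df = pd.DataFrame({"r": np.ones(4)}, index=list("abcd"))
        spec = GroupSpec("G", {"a": list("abcd")})
        with pytest.raises(ValueError):
            hd_group_difference(df, spec)


class TestGeneIntensityMatrix:
    def test_matrix_shape_and_flags(self, small_sim):
        gs = make_group_spec(small_sim.samples, "ALL")
        from pgxancestry.popstruct import allele_counts_by_group as acg
        maf = acg(small_sim.gm, gs)
        regions = GeneRegionSet(small_sim.genes.df.head(20))
        gi = gene_intensity_matrix(
            small_sim.gm, small_sim.variants, maf.pooled_maf, regions
        )
        assert gi.shape == (small_sim.gm.n_samples, 20)
        vals = gi.to_numpy()
        finite = vals[~np.isnan(vals)]
        assert ((finite >= 0) & (finite <= 1)).all()
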