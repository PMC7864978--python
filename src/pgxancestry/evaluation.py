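"""Reference recomputations and synthetic-recovery benchmarks.

Two kinds of quantity live here.  First, recomputations whose inputs are
printed reference values from the published whole-genome pharmacogenomics
analysis of the 1000 Genomes Phase 3 continental groups: the AIM x PGx
enrichment tables, genome-wide AIM totals, and the MTHFR rs1801133 allele-T
frequencies.  Those counts are data; every statistic derived from them (tail
p-values, proportions, Δ) is computed by this package at call time.

Second, parameter-recovery benchmarks on synthetic data: differentiation
recovery via Hudson's FST, detection of injected runs of homozygosity,
power and false-discovery control of the AIM scan, calibration of the
PGx-enrichment test, and held-out accuracy of the ancestry panel.  Each
accepts a seed and is deterministic given it.
"""

from __future__ import annotations

import numpy as np

from . import catalogs, hd, panel as panel_mod, popstruct, synthetic_data as sd
from .core_io import apply_variant_filters

#: AIM x PGx 2x2 counts (PGx&AIM, nonPGx&AIM, PGx&nonAIM, nonPGx&nonAIM) per
#: analysis group, as published for the 1000 Genomes continental groups.
REFERENCE_ENRICHMENT_COUNTS = {
    "ALL": (3_195, 28_528_004, 64, 73_462_356),
    "AFR": (879, 3_830_817, 2_380, 38_934_065),
    "AMR": (1_300, 3_600_715, 1_959, 25_454_504),
    "EAS": (543, 1_500_465, 2_716, 21_779_390),
    "EUR": (303, 834_028, 2_956, 22_118_305),
    "SAS": (67, 172_029, 3_192, 24_585_458),
}

#: (number of AIMs, number of tested SNVs) for selected published rows of the
#: genome-wide AIM catalog.
REFERENCE_AIM_TOTALS = {
    "AFR_SNP": (2_530_827, 10_326_460),
    "ALL_TOTAL_SNV": (28_531_199, 77_572_721),
}

#: rs1801133 (MTHFR C677T) allele-T frequencies.
REFERENCE_RS1801133 = {
    # AFR, SAS, EAS, EUR, AMR
    "continental": (0.090, 0.119, 0.296, 0.365, 0.474),
    # CDX, KHV, CHS, JPT, CHB
    "EAS": (0.134, 0.192, 0.286, 0.380, 0.466),
}


def reference_enrichment() -> dict[str, catalogs.EnrichmentResult]:
    """One-sided Fisher enrichment recomputed from the reference tables."""
    return {
        g: catalogs.enrichment_from_counts(*c, group=g)
        for g, c in REFERENCE_ENRICHMENT_COUNTS.items()
    }


def reference_aim_proportions() -> dict[str, float]:
    """P_AIM percentages recomputed from the reference catalog totals."""
    return {
        key: 100.0 * n_aim / n_tested
        for key, (n_aim, n_tested) in REFERENCE_AIM_TOTALS.items()
    }


def reference_deltas() -> dict[str, float]:
    """Δ (maximum allele-frequency difference) for rs1801133."""
    return {k: catalogs.delta_max(v) for k, v in REFERENCE_RS1801133.items()}


# ---------------------------------------------------------------------------
# synthetic-recovery benchmarks
# ---------------------------------------------------------------------------

def _seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def fst_recovery(seed: int = 0, F: float = 0.1, n: int = 200, n_loci: int = 5000) -> float:
    """Hudson FST between two populations simulated at differentiation F."""
    cfg = sd.SimConfig(
        seed=seed,
        continents=(
            sd.ContinentSpec("EUR", F, (sd.PopulationSpec("P1", n, 0.0),)),
            sd.ContinentSpec("EAS", F, (sd.PopulationSpec("P2", n, 0.0),)),
        ),
        n_loci=n_loci,
        w_common=1.0,
    )
    freqs = sd.draw_allele_frequencies(cfg)
    gm, _, _ = sd.draw_genotypes(freqs, cfg)
    return popstruct.hudson_fst(gm.dosage[:n], gm.dosage[n:])


def roh_recovery(seed: int = 0, min_snvs: int = 50) -> float:
    """Fraction of injected ROH >= ``min_snvs`` loci recovered by HD-region
    calling at >= 50% length overlap, on default windows."""
    cfg = sd.SimConfig(
        seed=seed,
        continents=(
            sd.ContinentSpec("EUR", 0.05, (sd.PopulationSpec("P1", 12, 0.0),)),
        ),
        n_loci=6000,
        w_common=1.0,
        roh={"EUR": sd.ROHSpec(3.0, 4_000_000.0)},
        chrom_length_bp=60_000_000,
    )
    sim = sd.simulate_dataset(cfg)
    gs = popstruct.make_group_spec(sim.samples, "EUR")
    maf = popstruct.allele_counts_by_group(sim.gm, gs)
    prof = hd.profile_genome(sim.gm, sim.variants, maf.pooled_maf, hd.WindowConfig())
    regions, _ = hd.call_hd_regions(prof)
    truth = sim.roh_truth[sim.roh_truth["n_loci"] >= min_snvs]
    if truth.empty:
        return float("nan")
    recovered = 0
    for t in truth.itertuples():
        length = t.end - t.start + 1
        for r in regions:
            if r.sample != t.sample:
                continue
            overlap = min(r.end, t.end) - max(r.start, t.start) + 1
            if overlap >= 0.5 * length:
                recovered += 1
                break
    return recovered / len(truth)


def _five_group_config(seed: int, F: float, n_per_group: int, n_loci: int,
                       fraction_pgx: float = 0.0, beta: float = 1.0) -> sd.SimConfig:
    return sd.SimConfig(
        seed=seed,
        continents=tuple(
            sd.ContinentSpec(code, F, (sd.PopulationSpec(f"{code}1", n_per_group, 0.0),))
            for code in ("AFR", "AMR", "EAS", "EUR", "SAS")
        ),
        n_loci=n_loci,
        w_common=1.0,
        pgx=sd.PGxSpec(fraction_labeled=fraction_pgx, differentiation_multiplier=beta),
    )


def aim_power(seed: int = 0, n_seeds: int = 5) -> float:
    """Mean P_AIM over replicate datasets at strong differentiation
    (F = 0.15, 5 groups x 100 individuals, 500 common loci)."""
    props = []
    for s in _seeds(seed, n_seeds):
        cfg = _five_group_config(s, 0.15, 100, 500)
        sim = sd.simulate_dataset(cfg)
        spec = popstruct.make_group_spec(sim.samples, "ALL")
        res = catalogs.aim_scan(sim.gm, spec, families=("SNV",), mc_reps=2000, seed=s)
        props.append(res.summary.loc[0, "p_aim"])
    return float(np.mean(props))


def aim_null_fdr(seed: int = 0, n_seeds: int = 10) -> float:
    """Fraction of undifferentiated (F = 0) replicate datasets in which the
    AIM scan flags any marker after BH adjustment."""
    flagged = 0
    for s in _seeds(seed, n_seeds):
        cfg = sd.SimConfig(
            seed=s,
            continents=tuple(
                sd.ContinentSpec(code, 0.0, (sd.PopulationSpec(f"{code}1", 40, 0.0),))
                for code in ("AFR", "EAS", "EUR")
            ),
            n_loci=150,
            w_common=1.0,
        )
        sim = sd.simulate_dataset(cfg)
        spec = popstruct.make_group_spec(sim.samples, "ALL")
        res = catalogs.aim_scan(sim.gm, spec, families=("SNV",), mc_reps=1000, seed=s)
        flagged += int(res.summary.loc[0, "n_aim"] > 0)
    return flagged / n_seeds


def _enrichment_run(s: int, beta: float) -> catalogs.EnrichmentResult:
    cfg = _five_group_config(s, 0.05, 30, 300, fraction_pgx=0.3, beta=beta)
    sim = sd.simulate_dataset(cfg)
    spec = popstruct.make_group_spec(sim.samples, "ALL")
    res = catalogs.aim_scan(sim.gm, spec, families=("SNV",), mc_reps=1000, seed=s)
    rec = res.records
    return catalogs.enrichment_test(
        rec["is_aim"].to_numpy(),
        rec["variant"].isin(sim.pgx.loci).to_numpy(),
    )


def enrichment_beta_detection(seed: int = 0, n_seeds: int = 10) -> float:
    """Fraction of replicates with odds ratio > 1 when PGx loci carry
    elevated differentiation (beta = 4)."""
    return float(np.mean([
        _enrichment_run(s, 4.0).odds_ratio > 1 for s in _seeds(seed, n_seeds)
    ]))


def enrichment_null_rejection(seed: int = 0, n_seeds: int = 20, alpha: float = 0.05) -> float:
    """One-sided rejection rate at ``alpha`` when beta = 1 (no PGx bias)."""
    return float(np.mean([
        _enrichment_run(s, 1.0).p < alpha for s in _seeds(seed + 1, n_seeds)
    ]))


def panel_benchmark(seed: int = 0):
    """Ancestry panel on the default desk-scale study conditions.

    Builds the 10-fold CV forward-selection panel from the 200 most
    differentiated common variants of the default 5-continent dataset
    (F_c = 0.1, 2 populations x 60 individuals per continent, admixed
    Americas) and returns (PanelModel, CVReport).  Held-out folds of 60
    individuals keep the testing-accuracy estimate stable.
    """
    cfg = sd.default_config(seed=seed, n_per_population=60, n_loci=10_000)
    sim = sd.simulate_dataset(cfg)
    gm, variants, _ = apply_variant_filters(sim.gm, sim.variants)
    spec = popstruct.make_group_spec(sim.samples, "ALL")
    maf = popstruct.allele_counts_by_group(gm, spec)
    freqs = maf.subgroup_freq()
    delta = np.nanmax(freqs, axis=1) - np.nanmin(freqs, axis=1)
    common = maf.pooled_maf > 0.05
    order = np.argsort(-np.where(common, delta, -1))[:200]
    X = gm.dosage[:, order].astype(float)
    X[X < 0] = np.nan
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean[None, :], X)
    labels = sim.samples.df.set_index("sample").loc[gm.samples, "continent"].to_numpy()
    ids = [gm.variants[j] for j in order]
    return panel_mod.build_panel(
        X, labels, panel_mod.PanelConfig(k_folds=10, seed=seed), feature_ids=ids
    )
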