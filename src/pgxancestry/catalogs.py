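"""Ancestry-informative catalogs: AIMs, AIGs, PGx enrichment, Δ statistics.

An AIM (ancestry-informative marker) is a variant whose allele frequency
differs significantly (BH-adjusted two-sided Fisher p < 0.05) among the
subgroups of an analysis group; an AIG is a gene whose homozygosity-
intensity distribution differs (Kruskal-Wallis).  Multiple-testing families
are one per (analysis group x variant category) for AIMs and one per
analysis group for AIGs.  The enrichment of AIMs among pharmacogenetic (PGx)
loci is the one-sided Fisher test on the 2x2 AIM x PGx table over the
group's tested-variant universe.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .core_io import GenotypeMatrix, PGxTable
from .popstruct import (
    GroupSpec,
    MAFTable,
    VariantCategory,
    allele_counts_by_group,
    categorize_variants,
)

__all__ = [
    "AIMScanResult",
    "EnrichmentResult",
    "aim_scan",
    "enrichment_test",
    "aig_scan",
    "delta_max",
    "pgx_crosstab",
    "shared_within_continental_aims",
]

ALPHA = 0.05

#: the four variant-category analysis families; "SNV" pools every
#: polymorphic variant (SNP + RV + SNP_RV)
CATEGORY_FAMILIES = ("SNV", "SNP", "RV", "SNP_RV")


@dataclass
class AIMScanResult:
    """Per-variant test results and per-family summaries for one group."""

    group: str
    records: pd.DataFrame   # variant, category, family, p, p_adj, is_aim, delta_max, freqs
    summary: pd.DataFrame   # family, n_tested, n_aim, p_aim
    maf_table: MAFTable
    categories: np.ndarray

    def aims(self, family: str = "SNV") -> set[str]:
        sub = self.records[(self.records["family"] == family) & self.records["is_aim"]]
        return set(sub["variant"])


def _family_mask(categories: np.ndarray, family: str) -> np.ndarray:
    if family == "SNV":
        return categories != VariantCategory.MAF0.value
    return categories == VariantCategory[family].value


def aim_scan(
    gm: GenotypeMatrix,
    groupspec: GroupSpec,
    families: tuple[str, ...] = CATEGORY_FAMILIES,
    mc_reps: int = 10_000,
    seed: int = 0,
    alpha: float = ALPHA,
    max_enumeration: int = 5_000,
) -> AIMScanResult:
    """Scan every polymorphic variant for allele-frequency differentiation.

    Per variant a subgroups x 2 allele-count table is tested with the
    two-sided Fisher exact test (enumeration or seeded Monte-Carlo for large
    supports); BH adjustment runs separately within each requested category
    family.  Variants monomorphic in the pooled group (MAF0) are excluded.
    """
    maf = allele_counts_by_group(gm, groupspec)
    cats = categorize_variants(maf)
    n_sub = len(groupspec.subgroups)
    alt = maf.alt_count[:, :n_sub]
    tot = maf.total[:, :n_sub]
    freqs = maf.subgroup_freq()

    polymorphic = cats != VariantCategory.MAF0.value
    pvals = np.full(gm.n_variants, np.nan)
    child_seeds = np.random.SeedSequence(seed).generate_state(gm.n_variants) % (2**31)
    for j in np.flatnonzero(polymorphic):
        table = np.stack([alt[j], tot[j] - alt[j]], axis=1)
        pvals[j] = stats.fisher_rx2_two_sided(
            table, mc_reps=mc_reps, seed=int(child_seeds[j]),
            max_enumeration=max_enumeration,
        )

    deltas = np.array([delta_max(freqs[j]) for j in range(gm.n_variants)])

    rec_frames = []
    summaries = []
    for family in families:
        mask = _family_mask(cats, family) & polymorphic
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            summaries.append({"family": family, "n_tested": 0, "n_aim": 0, "p_aim": np.nan})
            continue
        p_adj = stats.bh_adjust(pvals[idx])
        is_aim = p_adj < alpha
        df = pd.DataFrame(
            {
                "variant": [gm.variants[j] for j in idx],
                "category": [cats[j] for j in idx],
                "family": family,
                "p": pvals[idx],
                "p_adj": p_adj,
                "is_aim": is_aim,
                "delta_max": deltas[idx],
            }
        )
        for k, code in enumerate(groupspec.subgroups):
            df[f"freq_{code}"] = freqs[idx, k]
        rec_frames.append(df)
        summaries.append(
            {
                "family": family,
                "n_tested": int(idx.size),
                "n_aim": int(is_aim.sum()),
                "p_aim": float(is_aim.mean()),
            }
        )
    records = (
        pd.concat(rec_frames, ignore_index=True)
        if rec_frames
        else pd.DataFrame(
            columns=["variant", "category", "family", "p", "p_adj", "is_aim", "delta_max"]
        )
    )
    return AIMScanResult(
        group=groupspec.code,
        records=records,
        summary=pd.DataFrame(summaries),
        maf_table=maf,
        categories=cats,
    )


@dataclass
class EnrichmentResult:
    """AIM x PGx 2x2 enrichment for one analysis group."""

    group: str
    counts: stats.EnrichmentCounts
    p_aim: float
    p_aim_given_pgx: float
    odds_ratio: float
    p: float
    log10_p: float

    def to_dict(self) -> dict:
        c = self.counts
        return {
            "group": self.group,
            "a_pgx_aim": c.a,
            "b_nonpgx_aim": c.b,
            "c_pgx_nonaim": c.c,
            "d_nonpgx_nonaim": c.d,
            "p_aim": self.p_aim,
            "p_aim_given_pgx": self.p_aim_given_pgx,
            "odds_ratio": self.odds_ratio,
            "p": self.p,
            "log10_p": self.log10_p,
        }


def enrichment_test(
    aim_flags: np.ndarray, pgx_member: np.ndarray, group: str = ""
) -> EnrichmentResult:
    """One-sided Fisher test for AIM excess among PGx loci.

    Both masks are aligned on the same tested-variant universe (the group's
    polymorphic variants).  With zero PGx loci, P_AIM|PGx is NaN.
    """
    aim = np.asarray(aim_flags, dtype=bool)
    pgx = np.asarray(pgx_member, dtype=bool)
    if aim.shape != pgx.shape:
        raise ValueError("masks not aligned")
    a = int(np.sum(pgx & aim))
    b = int(np.sum(~pgx & aim))
    c = int(np.sum(pgx & ~aim))
    d = int(np.sum(~pgx & ~aim))
    counts = stats.EnrichmentCounts(a, b, c, d)
    res = stats.fisher_2x2_one_sided(counts)
    n_pgx = a + c
    return EnrichmentResult(
        group=group,
        counts=counts,
        p_aim=(a + b) / counts.total,
        p_aim_given_pgx=(a / n_pgx) if n_pgx else float("nan"),
        odds_ratio=res.odds_ratio,
        p=res.p,
        log10_p=res.log10_p,
    )


def enrichment_from_counts(a: int, b: int, c: int, d: int, group: str = "") -> EnrichmentResult:
    """Enrichment result straight from 2x2 counts (e.g. a published table)."""
    counts = stats.EnrichmentCounts(a, b, c, d)
    res = stats.fisher_2x2_one_sided(counts)
    n_pgx = a + c
    return EnrichmentResult(
        group=group,
        counts=counts,
        p_aim=(a + b) / counts.total,
        p_aim_given_pgx=(a / n_pgx) if n_pgx else float("nan"),
        odds_ratio=res.odds_ratio,
        p=res.p,
        log10_p=res.log10_p,
    )


def aig_scan(
    gene_intensities: pd.DataFrame,
    groupspec: GroupSpec,
    gene_positions: pd.DataFrame | None = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Kruskal-Wallis scan of gene homozygosity intensities across subgroups.

    ``gene_intensities``: individuals (index) x genes, NaN = insufficient
    loci for that individual/gene.  Genes without >= 2 subgroups of >= 2
    defined values are recorded as skipped.  BH adjustment runs across the
    tested genes; output includes a Manhattan-ready -log10 adjusted p and,
    when ``gene_positions`` (gene, chrom, start) is given, coordinates.
    """
    rows = []
    sub_ids = {
        code: [s for s in ids if s in gene_intensities.index]
        for code, ids in groupspec.subgroups.items()
    }
    for gene in gene_intensities.columns:
        col = gene_intensities[gene]
        groups = []
        medians = {}
        for code, ids in sub_ids.items():
            vals = col.loc[ids].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            medians[code] = float(np.median(vals)) if vals.size else np.nan
            if vals.size >= 2:
                groups.append(vals)
        if len(groups) < 2:
            rows.append({"gene": gene, "H": np.nan, "p": np.nan, "skipped": True, **{
                f"median_{c}": m for c, m in medians.items()}})
            continue
        H, p = stats.kruskal_wallis(groups)
        rows.append({"gene": gene, "H": H, "p": p, "skipped": False, **{
            f"median_{c}": m for c, m in medians.items()}})
    df = pd.DataFrame(rows)
    tested = ~df["skipped"]
    p_adj = np.full(len(df), np.nan)
    if tested.any():
        p_adj[tested.to_numpy()] = stats.bh_adjust(df.loc[tested, "p"].to_numpy())
    df["p_adj"] = p_adj
    df["is_aig"] = df["p_adj"] < alpha
    with np.errstate(divide="ignore"):
        df["neglog10_p_adj"] = -np.log10(df["p_adj"])
    if gene_positions is not None:
        df = df.merge(gene_positions[["gene", "chrom", "start"]], on="gene", how="left")
    return df


def delta_max(freqs) -> float:
    """Maximum pairwise allele-frequency difference, max(f) - min(f).

    NaN entries are ignored; fewer than two defined frequencies -> NaN.
    """
    f = np.asarray(freqs, dtype=float)
    f = f[~np.isnan(f)]
    if f.size < 2:
        return float("nan")
    return float(f.max() - f.min())


def pgx_crosstab(
    pgx: PGxTable,
    annotations: dict[str, str],
    min_count: int | None = None,
) -> pd.DataFrame:
    """Drug category x functional annotation contingency table with margins.

    PGx loci absent from ``annotations`` count under "unannotated".  With
    ``min_count``, interior cells with frequency <= min_count are zeroed
    (display rule for dense relationship plots); margins stay complete.
    """
    df = pgx.df.copy()
    if df.empty:
        return pd.DataFrame([[0]], index=pd.Index(["All"], name="drug_category"),
                            columns=pd.Index(["All"], name="annotation"))
    df["annotation"] = df["locus"].map(annotations).fillna("unannotated")
    tab = pd.crosstab(df["drug_category"], df["annotation"], margins=True, margins_name="All")
    if min_count is not None:
        inner = tab.drop(index="All", columns="All")
        tab.loc[inner.index, inner.columns] = inner.where(inner > min_count, 0)
    return tab


def shared_within_continental_aims(
    catalogs: dict[str, set[str]]
) -> tuple[set[str], pd.DataFrame]:
    """Intersections of within-continental AIM sets across the five groups.

    Returns the full intersection and a Venn-style table with one row per
    non-empty combination of groups: the number of markers that are AIMs in
    exactly that combination.
    """
    codes = sorted(catalogs)
    if not codes:
        raise ValueError("no catalogs given")
    full = set.intersection(*(set(catalogs[c]) for c in codes))
    universe = set.union(*(set(catalogs[c]) for c in codes))
    rows = []
    for r in range(1, len(codes) + 1):
        for combo in itertools.combinations(codes, r):
            inside = set(combo)
            exact = [
                v
                for v in universe
                if all(v in catalogs[c] for c in inside)
                and not any(v in catalogs[c] for c in set(codes) - inside)
            ]
            rows.append({"groups": "+".join(combo), "n_exact": len(exact)})
    return full, pd.DataFrame(rows)
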