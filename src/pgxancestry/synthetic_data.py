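"""Synthetic genotype datasets with 1000-Genomes-like structure.

The generator follows a two-level Balding-Nichols hierarchy: an ancestral
allele frequency p per locus (a mixture of a common and a rare band), a
continental frequency drawn from Beta(p (1-F_c)/F_c, (1-p)(1-F_c)/F_c), and a
population frequency drawn the same way around its continent (or around a
mixture of continental frequencies for admixed populations).  Genotypes are
Binomial(2, p) per individual, i.e. Hardy-Weinberg within populations.

On top of that it injects runs of homozygosity (ROH) with group-specific
Poisson counts and exponential lengths — the signal homozygosity-
disequilibrium profiling is meant to recover — and labels a random subset of
loci as pharmacogenetic (PGx), optionally with elevated differentiation
(F multiplied by beta at labeled loci) so that ancestry-informativeness is
enriched among them.

Everything is deterministic under (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_io import (
    ANNOTATION_CATEGORIES,
    MISSING,
    GeneRegionSet,
    GenotypeMatrix,
    PGxTable,
    SampleTable,
    VariantRecord,
)

__all__ = [
    "PopulationSpec",
    "ContinentSpec",
    "ROHSpec",
    "PGxSpec",
    "SimConfig",
    "default_config",
    "draw_allele_frequencies",
    "draw_genotypes",
    "inject_roh",
    "label_pgx_loci",
    "simulate_dataset",
    "SimResult",
]


@dataclass(frozen=True)
class PopulationSpec:
    code: str
    n_individuals: int
    F_population: float = 0.01
    #: optional mixing weights over continent codes; None = unadmixed
    admixture: dict[str, float] | None = None


@dataclass(frozen=True)
class ContinentSpec:
    code: str
    F_continent: float
    populations: tuple[PopulationSpec, ...]


@dataclass(frozen=True)
class ROHSpec:
    """Mean injected ROH segments per individual and mean length (bp)."""

    lambda_segments: float = 0.0
    mean_length_bp: float = 1_000_000.0


@dataclass(frozen=True)
class PGxSpec:
    fraction_labeled: float = 0.05
    #: multiplier applied to F at labeled loci (clipped to [0, 0.99])
    differentiation_multiplier: float = 1.0


# Drug-category and functional-annotation sampling weights for labeled loci,
# echoing the observed resource mix (pharmacodynamics-heavy categories,
# intron-heavy annotations).
DEFAULT_DRUG_CATEGORY_WEIGHTS = {
    "PD": 2303,
    "PK": 503,
    "CYP endogenous substrates": 334,
    "ADR": 60,
    "FX": 59,
}
DEFAULT_ANNOTATION_WEIGHTS = {
    "intron": 1583,
    "missense": 514,
    "upstream_gene": 355,
    "synonymous": 180,
    "3_prime_UTR": 150,
    "downstream_gene": 140,
    "intergenic": 120,
    "regulatory_region": 90,
    "5_prime_UTR": 60,
    "noncoding_transcript_exon": 40,
    "splice_region": 20,
    "stop_gained": 7,
}
DEFAULT_SOURCE_WEIGHTS = {
    "PharmGKB": 2597,
    "Biotransformation": 1001,
    "PharmaADME": 138,
    "DrugBank": 106,
}


@dataclass(frozen=True)
class SimConfig:
    seed: int
    continents: tuple[ContinentSpec, ...]
    n_loci: int = 20_000
    #: ancestral-frequency mixture: Uniform(0.05, 0.95) with weight w_common,
    #: Uniform(0.0005, 0.01) with weight 1 - w_common
    w_common: float = 0.5
    roh: dict[str, ROHSpec] = field(default_factory=dict)
    pgx: PGxSpec = PGxSpec()
    chrom_length_bp: int = 50_000_000
    chrom: str = "1"
    gene_length_bp: int = 250_000

    def __post_init__(self):
        codes = [c.code for c in self.continents]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate continent codes")
        for c in self.continents:
            if not (0 <= c.F_continent < 1):
                raise ValueError(f"F_continent for {c.code} must be in [0, 1)")
            for p in c.populations:
                if not (0 <= p.F_population < 1):
                    raise ValueError(f"F_population for {p.code} must be in [0, 1)")
                if p.n_individuals < 1:
                    raise ValueError(f"population {p.code} needs >= 1 individual")
                if p.admixture is not None:
                    if abs(sum(p.admixture.values()) - 1.0) > 1e-9:
                        raise ValueError(f"admixture weights for {p.code} must sum to 1")
                    unknown = set(p.admixture) - set(codes)
                    if unknown:
                        raise ValueError(f"admixture over unknown continents: {unknown}")
        if not (0 <= self.pgx.fraction_labeled <= 1):
            raise ValueError("fraction_labeled must be in [0, 1]")
        if not (0 <= self.w_common <= 1):
            raise ValueError("w_common must be in [0, 1]")

    @property
    def population_specs(self) -> list[tuple[str, PopulationSpec]]:
        return [(c.code, p) for c in self.continents for p in c.populations]


def default_config(
    seed: int = 0,
    n_per_population: int = 60,
    n_loci: int = 20_000,
    pgx_beta: float = 1.0,
    fraction_pgx: float = 0.05,
) -> SimConfig:
    """Desk-scale study conditions: 5 continents x 2 populations.

    Continental differentiation F_c = 0.10 (a 1000-Genomes-like continental
    FST), within-continent F_p = 0.01; the two AMR populations are admixed
    over EUR / AFR / AMR sources, mirroring the admixed Americas.  ROH rates
    follow the observed ordering: East Asians most/longest, Africans
    fewest/shortest, Americans intermediate with a large spread.
    """
    def pops(prefix, admixture=None):
        return tuple(
            PopulationSpec(f"{prefix}{i}", n_per_population, 0.01, admixture)
            for i in (1, 2)
        )

    continents = (
        ContinentSpec("AFR", 0.10, pops("AFR")),
        ContinentSpec("AMR", 0.10, pops("AMR", {"EUR": 0.45, "AFR": 0.25, "AMR": 0.30})),
        ContinentSpec("EAS", 0.10, pops("EAS")),
        ContinentSpec("EUR", 0.10, pops("EUR")),
        ContinentSpec("SAS", 0.10, pops("SAS")),
    )
    roh = {
        "AFR": ROHSpec(2.0, 500_000.0),
        "AMR": ROHSpec(5.0, 1_000_000.0),
        "EAS": ROHSpec(8.0, 1_500_000.0),
        "EUR": ROHSpec(5.0, 1_000_000.0),
        "SAS": ROHSpec(4.0, 800_000.0),
    }
    return SimConfig(
        seed=seed,
        continents=continents,
        n_loci=n_loci,
        roh=roh,
        pgx=PGxSpec(fraction_labeled=fraction_pgx, differentiation_multiplier=pgx_beta),
    )


@dataclass
class FrequencyTable:
    ancestral: np.ndarray                  # (n_loci,)
    continent: pd.DataFrame                # loci x continent codes
    population: pd.DataFrame               # loci x population codes
    pgx_mask: np.ndarray                   # (n_loci,) bool


def _bn_draw(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Balding-Nichols Beta draw around p with differentiation F."""
    if F == 0:
        return p.copy()
    ratio = (1 - F) / F
    return rng.beta(np.maximum(p * ratio, 1e-12), np.maximum((1 - p) * ratio, 1e-12))


def draw_allele_frequencies(config: SimConfig) -> FrequencyTable:
    """Hierarchical allele-frequency draw (seeded substream 0)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[0])
    n = config.n_loci
    common = rng.random(n) < config.w_common
    p = np.where(common, rng.uniform(0.05, 0.95, n), rng.uniform(0.0005, 0.01, n))
    pgx_mask = rng.random(n) < config.pgx.fraction_labeled
    beta = config.pgx.differentiation_multiplier

    def eff_F(F):
        return np.where(pgx_mask, np.clip(F * beta, 0.0, 0.99), F)

    cont = {}
    for c in config.continents:
        Fv = eff_F(c.F_continent)
        if c.F_continent == 0 and beta == 1.0:
            cont[c.code] = p.copy()
        else:
            ratio = (1 - Fv) / np.maximum(Fv, 1e-300)
            with np.errstate(divide="ignore"):
                a = np.maximum(p * ratio, 1e-12)
                b = np.maximum((1 - p) * ratio, 1e-12)
            draw = rng.beta(a, b)
            cont[c.code] = np.where(Fv == 0, p, draw)
    cont_df = pd.DataFrame(cont)

    pop = {}
    for c in config.continents:
        for ps in c.populations:
            if ps.admixture is None:
                base = cont_df[c.code].to_numpy()
            else:
                base = np.zeros(n)
                for code, q in ps.admixture.items():
                    base += q * cont_df[code].to_numpy()
            Fv = eff_F(ps.F_population)
            ratio = (1 - Fv) / np.maximum(Fv, 1e-300)
            a = np.maximum(base * ratio, 1e-12)
            b = np.maximum((1 - base) * ratio, 1e-12)
            draw = rng.beta(a, b)
            pop[ps.code] = np.where(Fv == 0, base, draw)
    pop_df = pd.DataFrame(pop)
    return FrequencyTable(ancestral=p, continent=cont_df, population=pop_df, pgx_mask=pgx_mask)


def draw_genotypes(
    freqs: FrequencyTable, config: SimConfig
) -> tuple[GenotypeMatrix, SampleTable, list[VariantRecord]]:
    """Binomial(2, p_population) genotypes plus variant records (substream 1)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[1])
    n_loci = config.n_loci
    positions = np.sort(
        rng.choice(np.arange(1, config.chrom_length_bp + 1), size=n_loci, replace=False)
    )
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, n_loci)
    alt_idx = (ref_idx + rng.integers(1, 4, n_loci)) % 4
    variants = [
        VariantRecord(
            id=f"var{i:06d}",
            chrom=config.chrom,
            pos=int(positions[i]),
            ref=str(bases[ref_idx[i]]),
            alt=str(bases[alt_idx[i]]),
        )
        for i in range(n_loci)
    ]

    sample_rows = []
    dosage_rows = []
    for c in config.continents:
        for ps in c.populations:
            pvec = freqs.population[ps.code].to_numpy()
            g = rng.binomial(2, pvec[None, :].repeat(ps.n_individuals, axis=0))
            dosage_rows.append(g.astype(np.int8))
            for i in range(ps.n_individuals):
                sample_rows.append(
                    {
                        "sample": f"{ps.code}_{i:04d}",
                        "population": ps.code,
                        "continent": c.code,
                    }
                )
    dosage = np.concatenate(dosage_rows, axis=0)
    samples = SampleTable(pd.DataFrame(sample_rows))
    gm = GenotypeMatrix(
        samples=samples.samples, variants=[v.id for v in variants], dosage=dosage
    )
    return gm, samples, variants


def inject_roh(
    gm: GenotypeMatrix,
    positions: np.ndarray,
    config: SimConfig,
    samples: SampleTable,
    freqs: FrequencyTable,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Overwrite genotypes inside drawn ROH segments with homozygotes.

    Per individual: segment count ~ Poisson(lambda of its continent), start
    uniform on the chromosome, length ~ Exponential(mean_length_bp); within a
    segment each locus becomes dosage 2 with its population frequency, else
    0.  Segments running past the chromosome end are truncated and flagged.
    Returns the new matrix and the (sample, start, end, truncated) truth
    table.  Seeded substream 2 of the config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[2])
    positions = np.asarray(positions)
    dosage = gm.dosage.copy()
    truth = []
    meta = samples.df.set_index("sample")
    for i, sid in enumerate(gm.samples):
        continent = meta.loc[sid, "continent"]
        spec = config.roh.get(continent, ROHSpec())
        if spec.lambda_segments <= 0:
            continue
        pvec = freqs.population[meta.loc[sid, "population"]].to_numpy()
        n_seg = rng.poisson(spec.lambda_segments)
        for _ in range(n_seg):
            start = int(rng.integers(1, config.chrom_length_bp + 1))
            length = rng.exponential(spec.mean_length_bp)
            end = int(start + length)
            truncated = end > config.chrom_length_bp
            if truncated:
                end = config.chrom_length_bp
            inside = np.flatnonzero((positions >= start) & (positions <= end))
            if inside.size:
                hom = rng.random(inside.size) < pvec[inside]
                dosage[i, inside] = np.where(hom, 2, 0).astype(np.int8)
            truth.append(
                {"sample": sid, "start": start, "end": end, "truncated": truncated,
                 "n_loci": int(inside.size)}
            )
    truth_df = pd.DataFrame(
        truth, columns=["sample", "start", "end", "truncated", "n_loci"]
    )
    out = GenotypeMatrix(samples=list(gm.samples), variants=list(gm.variants), dosage=dosage)
    return out, truth_df


def label_pgx_loci(
    variants: list[VariantRecord],
    config: SimConfig,
    pgx_mask: np.ndarray,
) -> PGxTable:
    """Attach drug categories / annotations / sources to the labeled loci.

    The labeled subset is the mask drawn with the frequencies (so the same
    loci carry the elevated differentiation); categorical attributes are
    sampled from the default weight tables (seeded substream 3).  Variant
    ``annotation`` fields are filled in place for labeled loci.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    idx = np.flatnonzero(pgx_mask)
    rows = []

    def sample_from(weights, size):
        keys = list(weights)
        w = np.array([weights[k] for k in keys], dtype=float)
        return [keys[j] for j in rng.choice(len(keys), size=size, p=w / w.sum())]

    cats = sample_from(DEFAULT_DRUG_CATEGORY_WEIGHTS, idx.size)
    anns = sample_from(DEFAULT_ANNOTATION_WEIGHTS, idx.size)
    srcs = sample_from(DEFAULT_SOURCE_WEIGHTS, idx.size)
    for k, j in enumerate(idx):
        variants[j].annotation = anns[k]
        rows.append(
            {
                "locus": variants[j].id,
                "source": srcs[k],
                "drug_category": cats[k],
                "drugs": "",
            }
        )
    df = pd.DataFrame(rows, columns=["locus", "source", "drug_category", "drugs"])
    return PGxTable(df)


def _gene_regions(config: SimConfig) -> GeneRegionSet:
    """Contiguous gene tiles across the chromosome."""
    rows = []
    g = 0
    start = 1
    while start <= config.chrom_length_bp:
        end = min(start + config.gene_length_bp - 1, config.chrom_length_bp)
        rows.append({"gene": f"gene{g:05d}", "chrom": config.chrom, "start": start, "end": end})
        start = end + 1
        g += 1
    return GeneRegionSet(pd.DataFrame(rows))


@dataclass
class SimResult:
    config: SimConfig
    freqs: FrequencyTable
    gm: GenotypeMatrix
    samples: SampleTable
    variants: list[VariantRecord]
    pgx: PGxTable
    genes: GeneRegionSet
    roh_truth: pd.DataFrame


def simulate_dataset(config: SimConfig) -> SimResult:
    """Full generator pipeline: frequencies, genotypes, ROH, PGx labels."""
    freqs = draw_allele_frequencies(config)
    gm, samples, variants = draw_genotypes(freqs, config)
    positions = np.array([v.pos for v in variants])
    gm, truth = inject_roh(gm, positions, config, samples, freqs)
    pgx = label_pgx_loci(variants, config, freqs.pgx_mask)
    return SimResult(
        config=config,
        freqs=freqs,
        gm=gm,
        samples=samples,
        variants=variants,
        pgx=pgx,
        genes=_gene_regions(config),
        roh_truth=truth,
    )
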