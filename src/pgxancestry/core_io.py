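"""Core data model and file I/O.

The central container is :class:`GenotypeMatrix`: samples x biallelic SNVs
coded as alternate-allele dosage (0, 1, 2) with ``-1`` for missing.  Around it
sit readers/writers for the standard formats (VCF with GT fields, BED gene
regions, TSV sample metadata and pharmacogenetic-locus tables) and the
variant quality-control filters applied before any population-genetic
analysis: duplicate chrom:pos records, multi-allelic records, indels, and
variants monomorphic (MAF = 0) within the analysis group.

Coordinates are 1-based inclusive internally (the VCF convention); BED input
is converted at the boundary.  Missing genotypes are never imputed here —
each downstream analysis chooses its own policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

MISSING = -1

CONTINENTS = ("AFR", "AMR", "EAS", "EUR", "SAS")

PGX_SOURCES = ("DrugBank", "PharmGKB", "PharmaADME", "Biotransformation")

#: Closed set of functional-annotation categories for PGx variants.
ANNOTATION_CATEGORIES = (
    "NMD_transcript",
    "noncoding_transcript",
    "noncoding_transcript_exon",
    "regulatory_region",
    "intergenic",
    "upstream_gene",
    "5_prime_UTR",
    "initiator_codon",
    "synonymous",
    "missense",
    "stop_gained",
    "splice_donor",
    "splice_acceptor",
    "splice_region",
    "intron",
    "stop_lost",
    "3_prime_UTR",
    "downstream_gene",
)

_BASES = frozenset("ACGT")


class VcfParseError(ValueError):
    """Malformed VCF content; the message names the offending line."""


class ValidationError(ValueError):
    """Table content violates the documented schema."""


@dataclass
class VariantRecord:
    """One variant site.  ``alt`` may hold a comma-joined list before QC."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    annotation: str = "unknown"

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in _BASES
            and self.alt in _BASES
            and self.ref != self.alt
        )

    @property
    def is_multiallelic(self) -> bool:
        return "," in self.alt


@dataclass
class GenotypeMatrix:
    """Samples x variants alternate-allele dosage matrix.

    ``dosage[i, j]`` is the number of alternate alleles carried by sample
    ``samples[i]`` at ``variants[j]``: 0, 1, 2, or ``MISSING`` (-1).
    """

    samples: list[str]
    variants: list[str]
    dosage: np.ndarray

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"({len(self.samples)} samples, {len(self.variants)} variants)"
            )
        vals = np.unique(self.dosage)
        bad = vals[~np.isin(vals, (MISSING, 0, 1, 2))]
        if bad.size:
            raise ValueError(f"invalid dosage values: {bad.tolist()}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("duplicate variant ids")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in ids], dtype=np.intp)

    def subset_variants(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[j] for j in idx],
            dosage=self.dosage[:, idx],
        )

    def subset_samples(self, ids) -> "GenotypeMatrix":
        idx = self.sample_index(ids)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            variants=list(self.variants),
            dosage=self.dosage[idx, :],
        )


@dataclass
class SampleTable:
    """Sample -> population -> continent assignments."""

    df: pd.DataFrame  # columns: sample, population, continent

    def __post_init__(self):
        required = {"sample", "population", "continent"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValidationError(f"sample table missing columns: {sorted(missing)}")
        bad = self.df.loc[~self.df["continent"].isin(CONTINENTS)]
        if len(bad):
            raise ValidationError(
                "unknown continent codes in rows: "
                + ", ".join(f"{r.sample}:{r.continent}" for r in bad.itertuples())
            )
        if self.df["sample"].duplicated().any():
            raise ValidationError("duplicate sample ids in sample table")
        multi = self.df.groupby("population")["continent"].nunique()
        if (multi > 1).any():
            raise ValidationError(
                f"populations mapped to >1 continent: {multi[multi > 1].index.tolist()}"
            )

    @property
    def samples(self) -> list[str]:
        return self.df["sample"].tolist()

    def samples_of_continent(self, code: str) -> list[str]:
        return self.df.loc[self.df["continent"] == code, "sample"].tolist()

    def samples_of_population(self, code: str) -> list[str]:
        return self.df.loc[self.df["population"] == code, "sample"].tolist()

    def populations_of_continent(self, code: str) -> list[str]:
        sub = self.df.loc[self.df["continent"] == code, "population"]
        return sorted(sub.unique())


@dataclass
class PGxTable:
    """Pharmacogenetic loci/genes merged across public resources.

    Deduplicated on (locus, drug_category) after merging, mirroring how the
    four resources (DrugBank, PharmGKB, PharmaADME, Biotransformation) are
    combined into one catalog.
    """

    df: pd.DataFrame  # columns: locus, source, drug_category, drugs

    def __post_init__(self):
        required = {"locus", "source", "drug_category", "drugs"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValidationError(f"PGx table missing columns: {sorted(missing)}")
        bad = self.df.loc[~self.df["source"].isin(PGX_SOURCES)]
        if len(bad):
            raise ValidationError(
                "unknown PGx source in rows: "
                + ", ".join(f"{r.locus}:{r.source}" for r in bad.itertuples())
            )
        self.df = self.df.drop_duplicates(subset=["locus", "drug_category"]).reset_index(
            drop=True
        )

    @property
    def loci(self) -> set[str]:
        return set(self.df["locus"])


@dataclass
class GeneRegionSet:
    """Gene regions with 1-based inclusive coordinates."""

    df: pd.DataFrame  # columns: gene, chrom, start, end

    def __post_init__(self):
        required = {"gene", "chrom", "start", "end"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValidationError(f"gene region table missing columns: {sorted(missing)}")
        bad = self.df.loc[self.df["start"] > self.df["end"]]
        if len(bad):
            raise ValidationError(f"zero/negative-length regions: {bad['gene'].tolist()}")

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _dosage_from_gt(gt) -> int:
    """Alt-allele dosage from a GT tuple; any missing allele -> MISSING."""
    if gt is None:
        return MISSING
    alleles = [a for a in gt]
    if len(alleles) != 2 or any(a is None for a in alleles):
        return MISSING
    return int(alleles[0] > 0) + int(alleles[1] > 0)


def read_vcf(path, region: str | None = None) -> tuple[GenotypeMatrix, list[VariantRecord]]:
    """Read a VCF v4.x into a dosage matrix plus variant records.

    Parameters
    ----------
    path : str
        Plain-text or bgzipped VCF with GT fields.
    region : str, optional
        ``"chrom:start-end"`` (1-based inclusive) restricting the records
        kept; applied by streaming, no index needed.

    No QC is applied here — multi-allelic records and indels pass through
    (multi-allelic ALT kept comma-joined; dosage then counts any non-ref
    allele).  Phase is ignored; half-missing genotypes are missing.
    """
    want_chrom = want_lo = want_hi = None
    if region is not None:
        chrom_part, _, span = region.partition(":")
        want_chrom = chrom_part
        if span:
            lo, _, hi = span.partition("-")
            want_lo, want_hi = int(lo), int(hi or lo)

    vf = pysam.VariantFile(str(path))
    sample_ids = list(vf.header.samples)
    if not sample_ids:
        raise VcfParseError(f"{path}: VCF has no sample columns")
    n_header = str(vf.header).count("\n")

    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    n_data = 0
    it = iter(vf)
    while True:
        try:
            rec = next(it)
        except StopIteration:
            break
        except Exception as exc:  # htslib parse failure
            raise VcfParseError(
                f"{path}: malformed VCF near line {n_header + n_data + 1}: {exc}"
            ) from exc
        n_data += 1
        if want_chrom is not None:
            if rec.chrom != want_chrom:
                continue
            if want_lo is not None and not (want_lo <= rec.pos <= want_hi):
                continue
        alts = rec.alts or ()
        vid = rec.id if rec.id else f"{rec.chrom}:{rec.pos}"
        variants.append(
            VariantRecord(
                id=vid,
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=",".join(alts) if alts else ".",
            )
        )
        rows.append(
            np.array(
                [_dosage_from_gt(rec.samples[s].get("GT")) for s in sample_ids],
                dtype=np.int8,
            )
        )
    dosage = (
        np.stack(rows, axis=1) if rows else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    # variant ids may collide (duplicated positions, missing rsids); uniquify
    seen: dict[str, int] = {}
    ids = []
    for v in variants:
        if v.id in seen:
            seen[v.id] += 1
            v.id = f"{v.id}_dup{seen[v.id]}"
        else:
            seen[v.id] = 0
        ids.append(v.id)
    return GenotypeMatrix(samples=sample_ids, variants=ids, dosage=dosage), variants


def write_vcf(gm: GenotypeMatrix, variants: list[VariantRecord], path) -> None:
    """Write a minimal VCF v4.2 with GT fields (unphased)."""
    chroms = []
    for v in variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    gt_str = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, v in enumerate(variants):
            col = gm.dosage[:, j]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                + "\t".join(gt_str[int(d)] for d in col)
                + "\n"
            )


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Per-rule removal counts; rules applied in the listed order."""

    duplicate_position: int = 0
    multiallelic: int = 0
    indel: int = 0
    maf_zero: int = 0
    n_input: int = 0
    n_retained: int = 0
    empty_result: bool = False

    @property
    def n_removed(self) -> int:
        return self.duplicate_position + self.multiallelic + self.indel + self.maf_zero


def apply_variant_filters(
    gm: GenotypeMatrix,
    variants: list[VariantRecord],
    group: set[str] | None = None,
) -> tuple[GenotypeMatrix, list[VariantRecord], FilterReport]:
    """Apply the standard variant QC: duplicates, multi-allelics, indels, MAF=0.

    All records sharing a chrom:pos with any other record are removed (no
    tie-break — deterministic and order-independent).  MAF is computed within
    ``group`` (sample-id set; default all samples) from called alleles only.
    Each variant is charged to the first rule that removes it, so report
    counts sum to the number removed.
    """
    if len(variants) != gm.n_variants:
        raise ValueError("variants not aligned with matrix columns")
    rep = FilterReport(n_input=gm.n_variants)

    pos_counts: dict[tuple[str, int], int] = {}
    for v in variants:
        key = (v.chrom, v.pos)
        pos_counts[key] = pos_counts.get(key, 0) + 1

    if group is None:
        rows = np.arange(gm.n_samples)
    else:
        rows = gm.sample_index([s for s in gm.samples if s in group])
    sub = gm.dosage[rows, :]
    called = sub != MISSING
    alt = np.where(called, sub, 0).sum(axis=0)
    tot = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)

    keep = np.ones(gm.n_variants, dtype=bool)
    for j, v in enumerate(variants):
        if pos_counts[(v.chrom, v.pos)] > 1:
            rep.duplicate_position += 1
        elif v.is_multiallelic:
            rep.multiallelic += 1
        elif not v.is_snv:
            rep.indel += 1
        elif tot[j] == 0 or freq[j] == 0.0 or freq[j] == 1.0:
            rep.maf_zero += 1
        else:
            continue
        keep[j] = False

    rep.n_retained = int(keep.sum())
    rep.empty_result = rep.n_retained == 0
    out_gm = gm.subset_variants(keep)
    out_variants = [v for v, k in zip(variants, keep) if k]
    return out_gm, out_variants, rep


# ---------------------------------------------------------------------------
# TSV / BED
# ---------------------------------------------------------------------------

def read_samples(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleTable(df)


def write_samples(table: SampleTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_pgx_table(path) -> PGxTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return PGxTable(df)


def write_pgx_table(table: PGxTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_gene_bed(path) -> GeneRegionSet:
    """Read gene regions from BED (0-based half-open) into 1-based inclusive."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"{path}:{i}: BED line needs >= 4 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            rows.append({"gene": name, "chrom": chrom, "start": start + 1, "end": end})
    return GeneRegionSet(pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]))


def write_gene_bed(regions: GeneRegionSet, path) -> None:
    with open(path, "w") as fh:
        for r in regions.df.itertuples():
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene}\n")


def write_tsv_catalog(df: pd.DataFrame, path) -> None:
    """Write an analysis catalog: fixed column order, header line, >= 6
    significant digits on floats."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_tsv_catalog(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
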