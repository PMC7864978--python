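"""Homozygosity disequilibrium (HD) profiling.

Homozygosity intensity is a [0, 1] local estimate of the homozygous-genotype
proportion around a genomic anchor, obtained from a double-weight local
polynomial fit of per-locus homozygosity indicators against position.  The
two weights are (i) a tricube kernel over the window for local smoothing and
(ii) a locus weight down-weighting rare variants, w = min(MAF, t) / t with
threshold t = 0.05, since a rare variant is almost always homozygous and
carries little information about autozygosity.

Regions under HD are maximal runs of anchors whose intensity exceeds a
threshold (default 0.9); per individual they are summarized as the region
count #(HD) and region lengths L(HD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypeMatrix, VariantRecord, GeneRegionSet
from .popstruct import GroupSpec
from . import stats

__all__ = [
    "WindowConfig",
    "HomozygosityProfile",
    "HDRegion",
    "HDSummary",
    "homozygosity_indicators",
    "local_intensity",
    "profile_genome",
    "gene_intensity",
    "gene_intensity_matrix",
    "call_hd_regions",
    "hd_group_difference",
]

MAF_WEIGHT_THRESHOLD = 0.05


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window parameters for genome profiling.

    half_window is in SNVs (window spans 2 * half_window + 1 loci), anchors
    are placed every ``step`` SNVs, and windows with fewer than ``min_loci``
    usable loci yield an undefined (NaN) intensity.

    The 51-SNV default window resolves runs of homozygosity down to about 50
    SNVs, the scale the region caller is expected to detect; substantially
    wider windows over-smooth segments near that size so their intensity
    never clears the HD threshold.
    """

    half_window: int = 25
    step: int = 10
    degree: int = 1
    min_loci: int = 10
    maf_threshold: float = MAF_WEIGHT_THRESHOLD


@dataclass
class HomozygosityProfile:
    """Per-chromosome intensity tracks for all individuals.

    ``anchors[chrom]`` holds strictly increasing anchor positions (bp);
    ``intensity[chrom]`` is (n_samples, n_anchors), values in [0, 1] or NaN.
    """

    samples: list[str]
    anchors: dict[str, np.ndarray]
    intensity: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, pos in self.anchors.items():
            mat = self.intensity[chrom]
            for i, s in enumerate(self.samples):
                for a, x in zip(pos, mat[i]):
                    rows.append((s, chrom, int(a), x))
        return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "intensity"])


@dataclass
class HDRegion:
    sample: str
    chrom: str
    start: int
    end: int
    mean_intensity: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class HDSummary:
    """#(HD) and L(HD) per individual."""

    n_regions: dict[str, int]
    lengths: dict[str, list[int]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s, self.n_regions[s], sum(self.lengths[s]))
            for s in self.n_regions
        ]
        return pd.DataFrame(rows, columns=["sample", "n_hd", "total_length"])


def homozygosity_indicators(gm: GenotypeMatrix) -> np.ndarray:
    """1.0 for homozygous (dosage 0 or 2), 0.0 for heterozygous, NaN missing."""
    d = gm.dosage
    out = np.where(d == 1, 0.0, 1.0)
    return np.where(d == MISSING, np.nan, out)


def _locus_weights(mafs: np.ndarray, threshold: float = MAF_WEIGHT_THRESHOLD) -> np.ndarray:
    m = np.asarray(mafs, dtype=float)
    w = np.where(m >= threshold, 1.0, m / threshold)
    return np.where(np.isnan(m), 0.0, w)


def _tricube(u: np.ndarray) -> np.ndarray:
    a = np.abs(u)
    k = (1 - a**3) ** 3
    return np.where(a <= 1, k, 0.0)


def local_intensity(
    indicators_row: np.ndarray,
    positions: np.ndarray,
    mafs: np.ndarray,
    anchor_index: int,
    half_window: int = 50,
    degree: int = 1,
    min_loci: int = 10,
    maf_threshold: float = MAF_WEIGHT_THRESHOLD,
) -> float:
    """Double-weight local polynomial intensity at one anchor for one row.

    Weights are tricube(u) * locus_weight with u = (pos - pos_anchor) / h and
    h the maximal in-window distance; missing indicators get weight 0.  The
    polynomial (default degree 1) is evaluated at the anchor; degree 0 is the
    weighted mean.  Returns NaN when fewer than ``min_loci`` loci are usable.
    """
    y = np.asarray(indicators_row, dtype=float)
    pos = np.asarray(positions, dtype=float)
    lo = max(0, anchor_index - half_window)
    hi = min(len(y), anchor_index + half_window + 1)
    yw, pw, mw = y[lo:hi], pos[lo:hi], np.asarray(mafs, dtype=float)[lo:hi]
    t = pw - pos[anchor_index]
    h = np.max(np.abs(t))
    u = t / h if h > 0 else np.zeros_like(t)
    w = _tricube(u) * _locus_weights(mw, maf_threshold)
    w = np.where(np.isnan(yw), 0.0, w)
    usable = np.sum((w > 0) & ~np.isnan(yw))
    if usable < min_loci:
        return float("nan")
    yf = np.where(np.isnan(yw), 0.0, yw)
    if degree == 0:
        val = np.sum(w * yf) / np.sum(w)
    else:
        # weighted polynomial fit in centered coordinate, evaluated at t=0
        V = np.vander(t, degree + 1, increasing=True)
        sw = np.sqrt(w)
        A = V * sw[:, None]
        b = yf * sw
        coef, *_ = np.linalg.lstsq(A, b, rcond=None)
        val = coef[0]
    return float(np.clip(val, 0.0, 1.0))


def _fit_anchor_block(y, w, t, degree):
    """Vectorized weighted local fit at t=0 for many rows at one anchor.

    y, w: (n_samples, m) indicator values (NaN-free; weight 0 where missing);
    t: (m,) centered positions.  Degree 0 or 1 closed forms; a near-singular
    degree-1 design falls back to the weighted mean.
    """
    S0 = w.sum(axis=1)
    Sy = (w * y).sum(axis=1)
    if degree == 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            return Sy / S0
    S1 = (w * t).sum(axis=1)
    S2 = (w * t * t).sum(axis=1)
    Sxy = (w * t * y).sum(axis=1)
    det = S0 * S2 - S1 * S1
    with np.errstate(invalid="ignore", divide="ignore"):
        beta0 = (S2 * Sy - S1 * Sxy) / det
        fallback = Sy / S0
    scale = np.maximum(S0 * S2, 1e-300)
    bad = ~np.isfinite(beta0) | (np.abs(det) <= 1e-12 * scale)
    return np.where(bad, fallback, beta0)


def profile_genome(
    gm: GenotypeMatrix,
    variants: list[VariantRecord],
    mafs: np.ndarray,
    window: WindowConfig = WindowConfig(),
) -> HomozygosityProfile:
    """Genome-wide homozygosity-intensity profile for every individual.

    Variants must be sorted by (chrom, pos); anchors are placed every
    ``window.step`` SNVs per chromosome with windows truncated at chromosome
    ends; chromosomes with fewer than ``min_loci`` SNVs are skipped.
    """
    ind = homozygosity_indicators(gm)
    pos_all = np.array([v.pos for v in variants], dtype=float)
    chrom_all = np.array([v.chrom for v in variants])
    lw_all = _locus_weights(np.asarray(mafs, dtype=float), window.maf_threshold)

    anchors: dict[str, np.ndarray] = {}
    intensity: dict[str, np.ndarray] = {}
    for chrom in dict.fromkeys(chrom_all):  # preserve order
        cols = np.flatnonzero(chrom_all == chrom)
        if np.any(np.diff(pos_all[cols]) < 0):
            raise ValueError(f"variants not position-sorted on {chrom}")
        if cols.size < window.min_loci:
            warnings.warn(f"chromosome {chrom}: fewer than {window.min_loci} SNVs, skipped")
            continue
        y_c = ind[:, cols]
        pos_c = pos_all[cols]
        lw_c = lw_all[cols]
        anchor_idx = np.arange(0, cols.size, window.step)
        out = np.full((gm.n_samples, anchor_idx.size), np.nan)
        for k, a in enumerate(anchor_idx):
            lo = max(0, a - window.half_window)
            hi = min(cols.size, a + window.half_window + 1)
            t = pos_c[lo:hi] - pos_c[a]
            h = np.max(np.abs(t))
            u = t / h if h > 0 else np.zeros_like(t)
            base_w = _tricube(u) * lw_c[lo:hi]
            yw = y_c[:, lo:hi]
            miss = np.isnan(yw)
            w = np.where(miss, 0.0, base_w[None, :])
            yf = np.where(miss, 0.0, yw)
            vals = _fit_anchor_block(yf, w, t, window.degree)
            usable = ((w > 0) & ~miss).sum(axis=1)
            vals = np.where(usable >= window.min_loci, vals, np.nan)
            out[:, k] = np.clip(vals, 0.0, 1.0)
        anchors[chrom] = pos_c[anchor_idx]
        intensity[chrom] = out
    return HomozygosityProfile(samples=list(gm.samples), anchors=anchors, intensity=intensity)


def gene_intensity(
    indicators: np.ndarray,
    positions: np.ndarray,
    mafs: np.ndarray,
    region: tuple[int, int],
    min_loci: int = 10,
    maf_threshold: float = MAF_WEIGHT_THRESHOLD,
) -> np.ndarray:
    """Locus-weighted mean homozygosity over SNVs inside [start, end].

    A degree-0 fit: the kernel is flat over the gene, only the MAF locus
    weight applies.  Individuals with fewer than ``min_loci`` usable SNVs in
    the region get NaN.
    """
    start, end = region
    pos = np.asarray(positions, dtype=float)
    inside = (pos >= start) & (pos <= end)
    y = np.asarray(indicators, dtype=float)[:, inside]
    w0 = _locus_weights(np.asarray(mafs, dtype=float)[inside], maf_threshold)
    miss = np.isnan(y)
    w = np.where(miss, 0.0, w0[None, :])
    yf = np.where(miss, 0.0, y)
    usable = ((w > 0) & ~miss).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        val = (w * yf).sum(axis=1) / w.sum(axis=1)
    return np.where(usable >= min_loci, np.clip(val, 0.0, 1.0), np.nan)


def gene_intensity_matrix(
    gm: GenotypeMatrix,
    variants: list[VariantRecord],
    mafs: np.ndarray,
    regions: GeneRegionSet,
    min_loci: int = 10,
) -> pd.DataFrame:
    """Individuals x genes intensity matrix (NaN = insufficient loci)."""
    ind = homozygosity_indicators(gm)
    pos = np.array([v.pos for v in variants], dtype=float)
    chrom = np.array([v.chrom for v in variants])
    cols = {}
    for r in regions.df.itertuples():
        on_chrom = chrom == r.chrom
        vals = gene_intensity(
            ind[:, on_chrom], pos[on_chrom], np.asarray(mafs)[on_chrom],
            (r.start, r.end), min_loci=min_loci,
        )
        cols[r.gene] = vals
    return pd.DataFrame(cols, index=gm.samples)


def call_hd_regions(
    profile: HomozygosityProfile, threshold: float = 0.9
) -> tuple[list[HDRegion], HDSummary]:
    """Maximal runs of consecutive anchors with intensity > threshold.

    Region bounds are the first/last anchor positions of the run (anchor
    coordinates, not window extents — conservative and deterministic).  NaN
    anchors break runs.
    """
    regions: list[HDRegion] = []
    n_regions = {s: 0 for s in profile.samples}
    lengths: dict[str, list[int]] = {s: [] for s in profile.samples}
    for chrom, pos in profile.anchors.items():
        mat = profile.intensity[chrom]
        above = np.nan_to_num(mat, nan=-1.0) > threshold
        for i, s in enumerate(profile.samples):
            row = above[i]
            # run boundaries
            edges = np.diff(np.concatenate(([0], row.view(np.int8), [0])))
            starts = np.flatnonzero(edges == 1)
            ends = np.flatnonzero(edges == -1) - 1
            for a, b in zip(starts, ends):
                reg = HDRegion(
                    sample=s,
                    chrom=chrom,
                    start=int(pos[a]),
                    end=int(pos[b]),
                    mean_intensity=float(np.mean(mat[i, a : b + 1])),
                )
                regions.append(reg)
                n_regions[s] += 1
                lengths[s].append(reg.length)
    return regions, HDSummary(n_regions=n_regions, lengths=lengths)


def hd_group_difference(
    intensities: pd.DataFrame,
    groupspec: GroupSpec,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Kruskal-Wallis test per region/gene for between-subgroup differences.

    ``intensities``: rows = individuals (index = sample ids), columns =
    regions or genes.  Per column, individuals with NaN are dropped; the
    tie-corrected KW test runs across subgroups and BH adjustment is applied
    across columns.  Returns the result table and the significant proportion.
    """
    sub_ids = {
        code: [s for s in ids if s in intensities.index]
        for code, ids in groupspec.subgroups.items()
    }
    sub_ids = {c: ids for c, ids in sub_ids.items() if len(ids) >= 2}
    if len(sub_ids) < 2:
        raise ValueError("need >= 2 subgroups with >= 2 individuals each")
    rows = []
    for col in intensities.columns:
        groups = []
        for ids in sub_ids.values():
            vals = intensities.loc[ids, col].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if len(vals) >= 2:
                groups.append(vals)
        if len(groups) < 2:
            rows.append((col, np.nan, np.nan))
            continue
        H, p = stats.kruskal_wallis(groups)
        rows.append((col, H, p))
    df = pd.DataFrame(rows, columns=["region", "H", "p"])
    tested = df["p"].notna()
    padj = np.full(len(df), np.nan)
    if tested.any():
        padj[tested.to_numpy()] = stats.bh_adjust(df.loc[tested, "p"].to_numpy())
    df["p_adj"] = padj
    df["significant"] = df["p_adj"] < alpha
    prop = float(df.loc[tested, "significant"].mean()) if tested.any() else float("nan")
    return df, prop
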