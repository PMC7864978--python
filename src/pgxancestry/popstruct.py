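"""Population structure: group allele frequencies, variant categories,
sample-space PCA, and average-linkage clustering.

The PCA works in sample space: with n individuals and m >> n loci, the n x n
variance-covariance (Gram) matrix of centered individual-level allele
frequencies (dosage / 2) is accumulated over locus blocks, so memory stays
O(n^2 + n * block) regardless of m, and a symmetric eigendecomposition gives
the same nonzero spectrum as the infeasible m x m locus-space problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .core_io import CONTINENTS, MISSING, GenotypeMatrix, SampleTable

__all__ = [
    "GroupSpec",
    "MAFTable",
    "VariantCategory",
    "PCAResult",
    "Dendrogram",
    "make_group_spec",
    "allele_counts_by_group",
    "categorize_variants",
    "pca_sample_space",
    "hca_upgma",
    "hudson_fst",
]

ANALYSIS_GROUPS = ("ALL",) + CONTINENTS


class VariantCategory(str, Enum):
    """Variant class by minor allele frequency within an analysis group."""

    MAF0 = "MAF0"      # monomorphic in the pooled group: excluded from testing
    SNP = "SNP"        # common in every polymorphic subgroup (MAF > 0.01)
    RV = "RV"          # rare in every polymorphic subgroup (0 < MAF <= 0.01)
    SNP_RV = "SNP_RV"  # common in some subgroups, rare in others


@dataclass
class GroupSpec:
    """An analysis group and the subgroups it is tested across.

    For the whole-continental group the subgroups are the five continents;
    for a continental group they are its populations.
    """

    code: str
    subgroups: dict[str, list[str]]  # subgroup code -> sample ids

    def __post_init__(self):
        if len(self.subgroups) < 1:
            raise ValueError("need at least one subgroup")
        seen: set[str] = set()
        for code, ids in self.subgroups.items():
            if not ids:
                raise ValueError(f"subgroup {code} is empty")
            dup = seen.intersection(ids)
            if dup:
                raise ValueError(f"samples in multiple subgroups: {sorted(dup)[:5]}")
            seen.update(ids)

    @property
    def all_samples(self) -> list[str]:
        out: list[str] = []
        for ids in self.subgroups.values():
            out.extend(ids)
        return out


def make_group_spec(samples: SampleTable, code: str) -> GroupSpec:
    """Build the GroupSpec for one of the six analysis groups."""
    if code == "ALL":
        subgroups = {c: samples.samples_of_continent(c) for c in CONTINENTS}
        subgroups = {c: ids for c, ids in subgroups.items() if ids}
    elif code in CONTINENTS:
        subgroups = {
            p: samples.samples_of_population(p)
            for p in samples.populations_of_continent(code)
        }
    else:
        raise ValueError(f"unknown analysis group {code!r}")
    if not subgroups:
        raise ValueError(f"analysis group {code!r} has no samples")
    return GroupSpec(code=code, subgroups=subgroups)


@dataclass
class MAFTable:
    """Per-variant, per-subgroup allele counts and frequencies.

    Arrays are (n_variants, n_subgroups); the pooled group is appended under
    the reserved key ``__pooled__``.  ``freq`` is NaN where a subgroup has no
    called alleles at a variant.
    """

    variants: list[str]
    subgroup_codes: list[str]
    alt_count: np.ndarray
    total: np.ndarray
    freq: np.ndarray
    maf: np.ndarray

    POOLED = "__pooled__"

    def column(self, code: str) -> int:
        return self.subgroup_codes.index(code)

    @property
    def pooled_maf(self) -> np.ndarray:
        return self.maf[:, self.column(self.POOLED)]

    def subgroup_maf(self) -> np.ndarray:
        cols = [j for j, c in enumerate(self.subgroup_codes) if c != self.POOLED]
        return self.maf[:, cols]

    def subgroup_freq(self) -> np.ndarray:
        cols = [j for j, c in enumerate(self.subgroup_codes) if c != self.POOLED]
        return self.freq[:, cols]


def allele_counts_by_group(gm: GenotypeMatrix, groupspec: GroupSpec) -> MAFTable:
    """Alt-allele counts, totals, frequencies and MAF per subgroup.

    Missing genotypes are excluded from both numerator and denominator.  A
    pooled column over all the group's samples is appended.
    """
    codes = list(groupspec.subgroups)
    n_v = gm.n_variants
    n_g = len(codes) + 1
    alt = np.zeros((n_v, n_g), dtype=np.int64)
    tot = np.zeros((n_v, n_g), dtype=np.int64)
    for j, code in enumerate(codes):
        rows = gm.sample_index(groupspec.subgroups[code])
        sub = gm.dosage[rows, :]
        called = sub != MISSING
        alt[:, j] = np.where(called, sub, 0).sum(axis=0)
        tot[:, j] = 2 * called.sum(axis=0)
    alt[:, -1] = alt[:, :-1].sum(axis=1)
    tot[:, -1] = tot[:, :-1].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    maf = np.where(np.isnan(freq), np.nan, np.minimum(freq, 1 - freq))
    return MAFTable(
        variants=list(gm.variants),
        subgroup_codes=codes + [MAFTable.POOLED],
        alt_count=alt,
        total=tot,
        freq=freq,
        maf=maf,
    )


def categorize_variants(maf: MAFTable, snp_threshold: float = 0.01) -> np.ndarray:
    """Assign each variant to MAF0 / SNP / RV / SNP_RV within the group.

    Pooled MAF of 0 (or undefined) -> MAF0.  Among subgroups with nonzero
    MAF: all > threshold -> SNP; all <= threshold -> RV; a mixture -> SNP_RV.
    """
    sub = maf.subgroup_maf()
    pooled = maf.pooled_maf
    n = sub.shape[0]
    # plain-string array (numpy comparisons against str enums are unreliable)
    out = np.full(n, VariantCategory.MAF0.value, dtype=object)
    with np.errstate(invalid="ignore"):
        nonzero = (sub > 0) & ~np.isnan(sub)
        rare = nonzero & (sub <= snp_threshold)
        common = sub > snp_threshold
    any_rare = rare.any(axis=1)
    any_common = common.any(axis=1)
    polymorphic = ~(np.isnan(pooled) | (pooled == 0))
    out[polymorphic & any_common & ~any_rare] = VariantCategory.SNP.value
    out[polymorphic & any_rare & ~any_common] = VariantCategory.RV.value
    out[polymorphic & any_rare & any_common] = VariantCategory.SNP_RV.value
    return out


# ---------------------------------------------------------------------------
# Sample-space PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Principal components of the sample-space decomposition.

    ``eigenvalues`` are those of the centered Gram matrix X_c X_c' of the
    individual-level allele frequency matrix (rows = samples); their sum
    equals the total centered sum of squares.  ``coordinates[:, k]`` =
    eigenvector_k * sqrt(eigenvalue_k).
    """

    samples: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_variance: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        df = pd.DataFrame(
            self.coordinates, columns=[f"PC{i + 1}" for i in range(k)]
        )
        df.insert(0, "sample", self.samples)
        return df


def pca_sample_space(
    gm: GenotypeMatrix,
    n_components: int | None = None,
    block_size: int = 8192,
    standardize: bool = False,
) -> PCAResult:
    """PCA of ultrahigh-dimensional genotypes via the n x n Gram matrix.

    Individual-level allele frequency x = dosage / 2; missing values are
    imputed to the locus mean of x; loci are mean-centered (and unit-variance
    scaled when ``standardize``, zero-variance loci dropped from scaling).
    The Gram matrix is accumulated locus-block by locus-block so the full
    m-locus matrix never has to be materialized as floats at once.

    Sign convention: each component is flipped so its largest-magnitude
    sample loading is positive (first such index on exact ties).
    """
    n = gm.n_samples
    if n < 2:
        raise ValueError("PCA needs >= 2 samples")
    m = gm.n_variants
    if m < 1:
        raise ValueError("PCA needs >= 1 variant")
    gram = np.zeros((n, n), dtype=np.float64)
    for start in range(0, m, block_size):
        block = gm.dosage[:, start : start + block_size].astype(np.float64)
        miss = block == MISSING
        block[miss] = np.nan
        x = block / 2.0
        col_mean = np.nanmean(x, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)  # all-missing locus
        inds = np.where(np.isnan(x), col_mean[None, :], x)
        xc = inds - col_mean[None, :]
        if standardize:
            sd = xc.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            xc = xc / sd[None, :]
        gram += xc @ xc.T
    eigvals, eigvecs = np.linalg.eigh(gram)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    if n_components is not None:
        eigvals = eigvals[:n_components]
        eigvecs = eigvecs[:, :n_components]
    for k in range(eigvecs.shape[1]):
        j = int(np.argmax(np.abs(eigvecs[:, k])))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    coords = eigvecs * np.sqrt(eigvals)[None, :]
    total = eigvals.sum() if n_components is None else np.trace(gram)
    prop = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return PCAResult(
        samples=list(gm.samples),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_variance=prop,
    )


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Binary merge tree from average-linkage agglomeration.

    ``merges`` follows the scipy linkage convention: row t merges clusters
    ``merges[t, 0]`` and ``merges[t, 1]`` (ids < n are leaves, id n + t is
    the cluster created at step t) at height ``merges[t, 2]`` with
    ``merges[t, 3]`` leaves below.
    """

    labels: list[str]
    merges: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cophenetic(self) -> np.ndarray:
        """Pairwise cophenetic distances (merge height of the join)."""
        n = len(self.labels)
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        coph = np.zeros((n, n))
        for t, (a, b, h, _) in enumerate(self.merges):
            ma, mb = members.pop(int(a)), members.pop(int(b))
            for i in ma:
                for j in mb:
                    coph[i, j] = coph[j, i] = h
            members[n + t] = ma + mb
        return coph

    def to_newick(self) -> str:
        n = len(self.labels)
        node: dict[int, tuple[str, float]] = {
            i: (self.labels[i], 0.0) for i in range(n)
        }
        for t, (a, b, h, _) in enumerate(self.merges):
            (sa, ha), (sb, hb) = node.pop(int(a)), node.pop(int(b))
            half = h / 2.0  # ultrametric: leaf depth = half merge height
            node[n + t] = (f"({sa}:{half - ha:.6g},{sb}:{half - hb:.6g})", half)
        (s, _), = node.values()
        return s + ";"


def hca_upgma(data, labels: list[str] | None = None, is_distance: bool = False) -> Dendrogram:
    """Average-linkage (UPGMA) hierarchical clustering.

    ``data`` is either an items x features matrix of individual-level allele
    frequencies (Euclidean distances are computed) or, with ``is_distance``,
    a precomputed square distance matrix.  Ties are broken deterministically
    by the smallest (i, j) pair in row-major order.
    """
    if is_distance:
        D = np.array(data, dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("non-finite feature values")
        sq = (X**2).sum(axis=1)
        D = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0))
    if not np.isfinite(D).all():
        raise ValueError("non-finite distances")
    n = D.shape[0]
    if n < 2 or D.shape != (n, n):
        raise ValueError("need a square distance matrix over >= 2 items")
    if labels is None:
        labels = [str(i) for i in range(n)]

    D = D.copy()
    np.fill_diagonal(D, np.inf)
    active = list(range(n))            # positions into D
    cluster_id = list(range(n))        # scipy-style ids
    sizes = [1] * n
    merges = np.zeros((n - 1, 4))
    for t in range(n - 1):
        sub = D[np.ix_(active, active)]
        flat = int(np.argmin(sub))     # first minimum = smallest (i, j) row-major
        i, j = divmod(flat, len(active))
        if i > j:
            i, j = j, i
        pi, pj = active[i], active[j]
        h = sub[i, j]
        ia, ja = cluster_id[pi], cluster_id[pj]
        lo, hi = (ia, ja) if ia < ja else (ja, ia)
        merges[t] = (lo, hi, h, sizes[pi] + sizes[pj])
        # average linkage update onto slot pi
        for pk in active:
            if pk in (pi, pj):
                continue
            dnew = (sizes[pi] * D[pi, pk] + sizes[pj] * D[pj, pk]) / (
                sizes[pi] + sizes[pj]
            )
            D[pi, pk] = D[pk, pi] = dnew
        sizes[pi] += sizes[pj]
        cluster_id[pi] = n + t
        active.remove(pj)
    return Dendrogram(labels=list(labels), merges=merges)


# ---------------------------------------------------------------------------
# Hudson FST (verification statistic)
# ---------------------------------------------------------------------------

def hudson_fst(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Hudson's FST estimator between two populations, ratio-of-averages.

    Per locus: numerator (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    denominator p1(1-p2) + p2(1-p1), with n the called allele counts; the
    estimate is sum(num) / sum(den) over loci with data in both groups.
    """
    def freq_n(d):
        d = np.asarray(d)
        called = d != MISSING
        n = 2 * called.sum(axis=0)
        p = np.where(called, d, 0).sum(axis=0) / np.maximum(n, 1)
        return p, n

    p1, n1 = freq_n(dosage_a)
    p2, n2 = freq_n(dosage_b)
    ok = (n1 > 1) & (n2 > 1)
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    if not keep.any():
        return float("nan")
    return float(num[keep].sum() / den[keep].sum())
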