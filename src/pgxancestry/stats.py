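"""Statistical kernels: exact Fisher tests, Kruskal-Wallis, BH adjustment.

The Fisher machinery is built to stay accurate at genome-scale counts: the
one-sided 2x2 tail is summed in log space from log-gamma terms (finite and
accurate down past 1e-300), and the two-sided r x 2 test enumerates the
fixed-margin support exactly when it is small and otherwise falls back to
seeded Monte-Carlo sampling from the multivariate hypergeometric null.

The two-sided r x 2 p-value uses the probability-mass criterion (the classic
Fisher convention): the total null probability of tables no more probable
than the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentCounts",
    "FisherResult",
    "fisher_2x2_one_sided",
    "fisher_rx2_two_sided",
    "kruskal_wallis",
    "bh_adjust",
]

#: Relative tolerance used when comparing floating table probabilities for
#: the "no more probable than observed" criterion.
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class EnrichmentCounts:
    """2x2 counts for AIM-in-PGx enrichment.

    a = PGx & AIM, b = non-PGx & AIM, c = PGx & non-AIM, d = non-PGx & non-AIM.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero 2x2 table")

    @property
    def n_pgx(self) -> int:
        return self.a + self.c

    @property
    def n_aim(self) -> int:
        return self.a + self.b

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class FisherResult:
    p: float
    log10_p: float
    odds_ratio: float


def _log_binom(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_2x2_one_sided(counts: EnrichmentCounts) -> FisherResult:
    """Upper-tail Fisher exact test on a 2x2 table.

    With margins fixed, the PGx&AIM cell is hypergeometric; the p-value is
    P(X >= a), summed in log space so values far below the double-precision
    underflow of naive products remain accurate.  The odds ratio is the
    unconditional sample OR a*d / (b*c) (no continuity correction; see
    ``haldane`` for the +0.5 variant).
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    N = counts.total
    K = counts.n_aim   # row margin: AIM
    n = counts.n_pgx   # column margin: PGx
    k_hi = min(K, n)
    ks = np.arange(a, k_hi + 1)
    if ks.size == 0:
        log_p = -np.inf
    else:
        log_terms = (
            _log_binom(K, ks) + _log_binom(N - K, n - ks) - _log_binom(N, n)
        )
        log_p = float(logsumexp(log_terms))
    log_p = min(log_p, 0.0)
    p = float(np.exp(log_p))
    if b * c > 0:
        orr = (a * d) / (b * c)
    elif a * d > 0:
        orr = np.inf
    else:
        orr = np.nan
    return FisherResult(p=p, log10_p=log_p / np.log(10), odds_ratio=orr)


def odds_ratio_haldane(counts: EnrichmentCounts) -> float:
    """Haldane-Anscombe odds ratio: +0.5 to every cell (finite at zero cells)."""
    return ((counts.a + 0.5) * (counts.d + 0.5)) / ((counts.b + 0.5) * (counts.c + 0.5))


# ---------------------------------------------------------------------------
# r x 2 two-sided exact test
# ---------------------------------------------------------------------------

def _count_tables(row_margins, c1, cap: float = 1e18) -> int:
    """Number of non-negative integer vectors k with sum(k)=c1, k_i<=r_i."""
    bound = 1.0
    for r in row_margins:
        bound *= min(r, c1) + 1
        if bound > cap:  # cheap upper bound before the exact DP
            return int(cap)
    counts = np.zeros(c1 + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in row_margins:
        csum = np.cumsum(counts)
        shifted = np.zeros_like(csum)
        if r + 1 <= c1:
            shifted[r + 1 :] = csum[: c1 - r]
        counts = csum - shifted
        if counts.max() > cap:
            return int(cap)
    return int(counts[c1])


def fisher_rx2_two_sided(
    table,
    method: str = "auto",
    mc_reps: int = 10_000,
    seed: int = 0,
    max_enumeration: int = 1_000_000,
) -> float:
    """Two-sided Fisher exact test on a G x 2 allele-count table.

    Parameters
    ----------
    table : array-like, shape (G, 2)
        Per-subgroup (allele-1 count, allele-2 count).
    method : {"auto", "exact", "mc"}
        ``auto`` enumerates the fixed-margin support when it holds at most
        ``max_enumeration`` tables, else samples ``mc_reps`` tables from the
        multivariate hypergeometric null with the observed margins.  The
        Monte-Carlo estimate uses the add-one correction
        ``(1 + #{P(T) <= P(obs)}) / (reps + 1)`` and is reproducible under
        ``seed``.

    Returns the total null probability of tables whose point probability is
    at most that of the observed table (relative float tolerance 1e-7).
    """
    tab = np.asarray(table, dtype=np.int64)
    if tab.ndim != 2 or tab.shape[1] != 2:
        raise ValueError("table must be G x 2")
    if (tab < 0).any():
        raise ValueError("negative counts")
    row_tot = tab.sum(axis=1)
    if (row_tot == 0).any():
        warnings.warn("dropping subgroups with zero total alleles")
        tab = tab[row_tot > 0]
        row_tot = tab.sum(axis=1)
    G = tab.shape[0]
    if G <= 1:
        return 1.0
    c1 = int(tab[:, 0].sum())
    if c1 == 0 or int(tab[:, 1].sum()) == 0:
        return 1.0
    r = row_tot.astype(int).tolist()
    N = int(row_tot.sum())
    log_denom = float(_log_binom(N, c1))
    log_p_obs = float(np.sum(_log_binom(row_tot, tab[:, 0]))) - log_denom

    if method == "auto":
        method = "exact" if _count_tables(r, c1) <= max_enumeration else "mc"
    if method == "exact":
        return _enumerate_exact(r, c1, log_denom, log_p_obs)
    if method != "mc":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(r, c1, size=mc_reps)
    # log point probability of each sampled table, via a log-factorial table
    lf = np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, N + 1)))))
    rv = np.asarray(r)

    def log_binom_tab(n, k):
        return lf[n] - lf[k] - lf[n - k]

    lp = log_binom_tab(rv[None, :], draws).sum(axis=1) - log_denom
    tol = abs(log_p_obs) * _TIE_RTOL + 1e-12
    hits = int(np.sum(lp <= log_p_obs + tol))
    return (1 + hits) / (mc_reps + 1)


def _enumerate_exact(row_margins, c1, log_denom, log_p_obs) -> float:
    """Exact probability-mass p over the full fixed-margin support."""
    G = len(row_margins)
    rem_cap = np.cumsum(np.asarray(row_margins)[::-1])[::-1]
    tol = abs(log_p_obs) * _TIE_RTOL + 1e-12
    total = 0.0
    stack = [(0, c1, 0.0)]
    # iterative DFS over k_0..k_{G-1}
    while stack:
        i, remaining, log_acc = stack.pop()
        if i == G - 1:
            if 0 <= remaining <= row_margins[i]:
                lp = log_acc + float(_log_binom(row_margins[i], remaining)) - log_denom
                if lp <= log_p_obs + tol:
                    total += np.exp(lp)
            continue
        lo = max(0, remaining - int(rem_cap[i + 1]))
        hi = min(row_margins[i], remaining)
        for k in range(lo, hi + 1):
            stack.append((i + 1, remaining - k, log_acc + float(_log_binom(row_margins[i], k))))
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# Kruskal-Wallis and FDR
# ---------------------------------------------------------------------------

def kruskal_wallis(samples: list) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p across >= 2 groups.

    Degenerate input (every value identical) returns (0.0, 1.0) rather than
    erroring, so genome-wide scans over near-constant intensity tracks stay
    total.
    """
    groups = [np.asarray(g, dtype=float) for g in samples]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need total n >= 3")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        return 0.0, 1.0
    H, p = sps.kruskal(*groups)
    return float(H), float(p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
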