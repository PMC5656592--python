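"""Supporting statistics: t-test DEGs, aging regression, overlap tests.

These are the ordinary-statistics companions to the rank-pair pipeline:
per-gene two-sample t-tests (brain-region differential expression),
per-gene expression-on-age least-squares regression (aging-associated
genes), the Benjamini-Hochberg step-up FDR adjustment used throughout, and
the small exact tests the analyses report: upper-tail hypergeometric
overlap of two gene sets in an explicit universe, one-sided binomial
direction-consistency, the two-sided Wilcoxon rank-sum comparison of
per-sample reversal burdens, and a generic 2x2 Fisher exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def ttest_degs(
    matrix,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene two-sample t-test, case vs control, BH-adjusted.

    ``equal_var=True`` is the classical Student test; Welch is available by
    flag.  Genes constant in both groups with equal means get p = 1.
    Direction is the sign of the case-minus-control mean difference.
    """
    ctrl = matrix.values[:, matrix.group == "control"]
    case = matrix.values[:, matrix.group == "case"]
    if ctrl.shape[1] < 2 or case.shape[1] < 2:
        raise ValueError("both groups need at least two samples")
    t, p = sps.ttest_ind(case, ctrl, axis=1, equal_var=equal_var)
    diff = case.mean(axis=1) - ctrl.mean(axis=1)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.info("%d gene(s) with zero variance in both groups; p set to 1 "
                    "where means are equal", int(degenerate.sum()))
        p = np.where(degenerate & (diff == 0), 1.0, p)
        t = np.where(degenerate & (diff == 0), 0.0, t)
        # constant groups with different means: infinitely strong evidence
        p = np.where(~np.isfinite(p), 0.0, p)
    p_adj = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "direction": np.sign(diff).astype(int),
            "is_deg": p_adj < alpha,
        }
    )


@dataclass(frozen=True)
class AgingRecord:
    gene_id: str
    slope: float      # expression units per year
    p: float
    p_adj: float
    direction: int    # sign of the slope


def aging_genes(matrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene OLS regression of expression on age, BH-adjusted.

    Uses the closed-form simple-regression slope t-test (df = n - 2),
    vectorized over genes.  Samples with missing age are dropped; constant
    expression gives slope 0 and p = 1.
    """
    has_age = np.isfinite(matrix.age)
    if has_age.sum() < 3:
        raise ValueError("need at least 3 samples with age")
    age = matrix.age[has_age]
    if np.ptp(age) == 0:
        raise ValueError("age is constant; regression undefined")
    Y = matrix.values[:, has_age]
    n = len(age)
    xc = age - age.mean()
    sxx = float(xc @ xc)
    yc = Y - Y.mean(axis=1, keepdims=True)
    slope = yc @ xc / sxx
    resid = yc - slope[:, None] * xc[None, :]
    rss = (resid ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / (n - 2) / sxx)
        tstat = slope / se
    p = 2 * sps.t.sf(np.abs(tstat), df=n - 2)
    const = np.ptp(yc, axis=1) == 0
    p = np.where(const, 1.0, p)
    slope = np.where(const, 0.0, slope)
    p = np.where(~np.isfinite(p), 0.0, p)  # exact linear fit, rss == 0
    p_adj = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "slope": slope,
            "p": p,
            "p_adj": p_adj,
            "direction": np.sign(slope).astype(int),
            "is_significant": p_adj < alpha,
        }
    )


@dataclass(frozen=True)
class OverlapTestResult:
    """Upper-tail hypergeometric overlap of two sets in a universe of N."""

    N: int
    K: int
    n: int
    k: int
    p: float


def hypergeom_overlap(N: int, K: int, n: int, k: int) -> OverlapTestResult:
    """P(overlap >= k) when a set of n is drawn from a universe of N
    containing K marked genes.  The universe is always explicit."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts N={N} K={K} n={n} k={k}")
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return OverlapTestResult(N=N, K=K, n=n, k=k, p=p)


def binomial_consistency(k_consistent: int, n_total: int, p0: float = 0.5) -> float:
    """Exact one-sided P(X >= k) for X ~ Binomial(n, p0)."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= k_consistent <= n_total:
        raise ValueError("k must lie in [0, n]")
    return float(sps.binom.sf(k_consistent - 1, n_total, p0))


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided rank-sum p: exact when combined n <= 20 and tie-free,
    otherwise the normal approximation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=False)
    return float(min(res.pvalue, 1.0))


def fisher_2x2(a: int, b: int, c: int, d: int, sided: str = "two") -> float:
    """Fisher exact test on the table [[a, b], [c, d]].

    Two-sided sums all margin-compatible tables whose point probability
    does not exceed the observed one; one-sided is the upper tail of the
    ``a`` cell.
    """
    cells = (a, b, c, d)
    if any(int(v) != v or v < 0 for v in cells):
        raise ValueError("cells must be non-negative integers")
    if sum(cells) == 0:
        raise ValueError("all-zero table")
    alternative = {"two": "two-sided", "one": "greater"}.get(sided)
    if alternative is None:
        raise ValueError("sided must be 'one' or 'two'")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])
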