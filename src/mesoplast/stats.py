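"""Statistical machinery shared by all analyses.

Two-sample Student t tests (pooled variance by default, Welch optional),
label-permutation tests on the group mean difference, Pearson correlation,
Benjamini-Hochberg FDR control, and Cohen's D effect sizes with the
conventional magnitude bins: negligible (|D| <= 0.2), small (<= 0.5),
moderate (<= 0.8), large (<= 1.2), huge (> 1.2).  Boundary values fall in
the lower bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "independent_t_test",
    "permutation_mean_diff",
    "pearson_r",
    "bh_fdr",
    "cohens_d",
    "cohens_d_label",
]

_D_BINS = ((0.2, "negligible"), (0.5, "small"), (0.8, "moderate"), (1.2, "large"))


@dataclass
class TestResult:
    statistic: float
    p_value: float
    effect_size: float  # Cohen's D
    label: str
    n_a: int
    n_b: int


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's D with pooled standard deviation; 0 when the pooled SD is 0."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    if sp == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / sp)


def cohens_d_label(d: float) -> str:
    """Magnitude bin of a Cohen's D value (boundaries go to the lower bin)."""
    if not np.isfinite(d):
        raise ValueError("d must be finite")
    mag = abs(d)
    for bound, label in _D_BINS:
        if mag <= bound:
            return label
    return "huge"


def independent_t_test(
    a, b, one_tailed: bool = False, welch: bool = False
) -> TestResult:
    """Two-sample Student t test (pooled variance unless ``welch``)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise ValueError("degenerate: both samples have zero variance")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    p = float(res.pvalue)
    if one_tailed:
        p = p / 2.0 if res.statistic > 0 else 1.0 - p / 2.0
    d = cohens_d(a, b)
    return TestResult(
        statistic=float(res.statistic),
        p_value=p,
        effect_size=d,
        label=cohens_d_label(d),
        n_a=a.size,
        n_b=b.size,
    )


def permutation_mean_diff(
    a, b, n_perm: int = 10000, seed: int = 0, exhaustive_limit: int = 20000
) -> TestResult:
    """Two-sided permutation test on the group mean difference.

    When the number of distinct label splits is at most ``exhaustive_limit``
    the full enumeration is used and p is the exact proportion of splits
    with |mean difference| >= observed.  Otherwise ``n_perm`` random
    shuffles are drawn and p uses add-one smoothing,
    p = (1 + #{|perm| >= |obs|}) / (1 + n_perm), so p is never 0.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    obs = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    na, ntot = a.size, a.size + b.size
    tol = 1e-12

    if comb(ntot, na) <= exhaustive_limit:
        count = total = 0
        idx_all = frozenset(range(ntot))
        for idx in combinations(range(ntot), na):
            rest = list(idx_all - set(idx))
            diff = pooled[list(idx)].mean() - pooled[rest].mean()
            count += abs(diff) >= abs(obs) - tol
            total += 1
        p = count / total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(ntot)
            diff = pooled[perm[:na]].mean() - pooled[perm[na:]].mean()
            count += abs(diff) >= abs(obs) - tol
        p = (1.0 + count) / (1.0 + n_perm)

    d = cohens_d(a, b) if a.size > 1 and b.size > 1 else 0.0
    return TestResult(
        statistic=float(obs),
        p_value=float(p),
        effect_size=d,
        label=cohens_d_label(d),
        n_a=a.size,
        n_b=b.size,
    )


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation and its two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
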