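"""Alpha diversity, coverage, rarefaction/accumulation curves, rank-sum test.

Estimators follow the classical definitions: Shannon-Wiener in nats,
Gini-Simpson diversity (1 - sum p^2), Pielou evenness H/ln(S), Good's
coverage 1 - F1/N, Chao1 in the bias-corrected form (the classical variant
selectable) with its standard variance, and ACE with the usual rare/abundant
cutoff of 10 individuals.  The rarefaction curve is the analytic
hypergeometric expectation, not a resampled average.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .otu_io import CountMatrix, DataError


@dataclass
class AlphaRecord:
    """Alpha-diversity summary for one sample."""

    sample_id: str
    observed_richness: int
    chao1: float
    chao1_se: float
    ace: float
    shannon: float
    simpson_diversity: float
    pielou: float
    goods_coverage: float


def _clean(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=np.int64)
    if c.sum() <= 0:
        raise DataError("all-zero count vector")
    return c[c > 0]


def shannon(counts) -> float:
    """Shannon-Wiener index H = -sum p ln p (nats)."""
    c = _clean(counts)
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def simpson_diversity(counts, inverse: bool = False) -> float:
    """Gini-Simpson diversity 1 - sum p^2 (or inverse Simpson 1/sum p^2)."""
    c = _clean(counts)
    p = c / c.sum()
    d = float((p**2).sum())
    return 1.0 / d if inverse else 1.0 - d


def pielou(counts) -> float:
    """Evenness H / ln(S_obs); defined as 0 for a single-species sample."""
    c = _clean(counts)
    s = len(c)
    if s == 1:
        return 0.0
    return shannon(c) / np.log(s)


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/N, F1 the number of singleton OTUs."""
    c = _clean(counts)
    return 1.0 - (c == 1).sum() / c.sum()


def chao1(counts, bias_corrected: bool = True) -> tuple[float, float]:
    """Chao1 richness estimate and its standard error.

    Bias-corrected form S_obs + F1(F1-1)/(2(F2+1)) by default; the classical
    S_obs + F1^2/(2 F2) is selectable (undefined when F2 = 0, in which case
    the bias-corrected form is substituted).
    """
    c = _clean(counts)
    s_obs = len(c)
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected or f2 == 0:
        est = s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
        var = (
            f1 * (f1 - 1) / (2 * (f2 + 1))
            + f1 * (2 * f1 - 1) ** 2 / (4 * (f2 + 1) ** 2)
            + f1**2 * f2 * (f1 - 1) ** 2 / (4 * (f2 + 1) ** 4)
        )
    else:
        est = s_obs + f1**2 / (2 * f2)
        ratio = f1 / f2
        var = f2 * (ratio**2 / 2 + ratio**3 + ratio**4 / 4)
    return float(est), float(np.sqrt(max(var, 0.0)))


def ace(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator with rare cutoff 10."""
    c = _clean(counts)
    rare = c[c <= rare_cutoff]
    s_abund = int((c > rare_cutoff).sum())
    s_rare = len(rare)
    n_rare = int(rare.sum())
    f1 = int((c == 1).sum())
    if s_rare == 0:
        return float(len(c))
    if n_rare == f1:
        # no coverage information; fall back to Chao1
        return chao1(c)[0]
    c_ace = 1.0 - f1 / n_rare
    freq = np.array([(rare == i).sum() for i in range(1, rare_cutoff + 1)])
    i = np.arange(1, rare_cutoff + 1)
    gamma2 = max(
        (s_rare / c_ace) * (i * (i - 1) * freq).sum() / (n_rare * (n_rare - 1)) - 1.0,
        0.0,
    ) if n_rare > 1 else 0.0
    return float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2)


def alpha_diversity(counts, sample_id: str = "") -> AlphaRecord:
    """All alpha-diversity statistics for one sample's count vector."""
    c = _clean(counts)
    est, se = chao1(c)
    return AlphaRecord(
        sample_id=sample_id,
        observed_richness=len(c),
        chao1=est,
        chao1_se=se,
        ace=ace(c),
        shannon=shannon(c),
        simpson_diversity=simpson_diversity(c),
        pielou=pielou(c),
        goods_coverage=goods_coverage(c),
    )


def alpha_diversity_table(cm: CountMatrix):
    """Per-sample alpha table as a pandas DataFrame."""
    import pandas as pd

    recs = [alpha_diversity(cm.counts[:, j], s) for j, s in enumerate(cm.sample_ids)]
    return pd.DataFrame([r.__dict__ for r in recs])


def rarefaction_curve(counts, depths) -> np.ndarray:
    """Expected richness at each subsample depth (analytic hypergeometric).

    E[S_d] = sum_i [1 - C(N - n_i, d) / C(N, d)], evaluated with log-gamma
    for numerical stability; exact at d = N where it returns S_obs.
    """
    c = _clean(counts)
    n = int(c.sum())
    depths = np.asarray(depths, dtype=np.int64)
    if (depths > n).any():
        raise DataError(f"depth exceeds total count {n}")
    if (depths < 0).any():
        raise DataError("depths must be non-negative")

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = np.empty(len(depths))
    for k, d in enumerate(depths):
        miss = np.zeros(len(c))
        feasible = (n - c) >= d
        miss[feasible] = np.exp(log_choose(n - c[feasible], d) - log_choose(n, d))
        out[k] = (1.0 - miss).sum()
    return out


def species_accumulation(cm: CountMatrix, n_perm: int = 100, seed: int = 0) -> np.ndarray:
    """Mean cumulative OTU richness as samples are added in random order."""
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    present = cm.counts > 0
    n = cm.n_samples
    acc = np.zeros(n)
    for _ in range(n_perm):
        order = rng.permutation(n)
        seen = np.zeros(cm.n_otus, dtype=bool)
        for k, j in enumerate(order):
            seen |= present[:, j]
            acc[k] += seen.sum()
    return acc / n_perm


def rank_sum_compare(x, y, exact_limit: int = 10) -> tuple[float, float]:
    """Mann-Whitney U (min-U convention) with a two-sided p-value.

    Exact enumeration of all C(nx+ny, nx) group assignments when
    nx + ny <= ``exact_limit`` (handles ties correctly); otherwise the
    normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DataError("empty input")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)

    def min_u(rank_x_sum: float) -> float:
        u1 = rank_x_sum - nx * (nx + 1) / 2
        return min(u1, nx * ny - u1)

    u_obs = min_u(ranks[:nx].sum())
    if nx + ny <= exact_limit:
        count = total = 0
        for combo in itertools.combinations(range(nx + ny), nx):
            u = min_u(ranks[list(combo)].sum())
            count += u <= u_obs + 1e-12
            total += 1
        return float(u_obs), count / total
    mu = nx * ny / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = nx + ny
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = nx * ny / 12 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return float(u_obs), 1.0
    z = (u_obs - mu) / np.sqrt(sigma2)
    p = 2 * stats.norm.cdf(z)  # u_obs <= mu by the min-U convention
    return float(u_obs), float(min(1.0, p))
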