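"""Community dissimilarity, NMDS ordination, and matrix permutation tests.

Bray-Curtis dissimilarity on (by default) square-root transformed relative
abundances; non-metric multidimensional scaling by SMACOF majorization
alternating with isotonic regression on dissimilarity ranks; ANOSIM as the
rank-based between/within group contrast; Mantel and partial Mantel tests
with simultaneous row/column permutation of one matrix.

All permutation p-values use the (count + 1) / (n_perm + 1) estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .otu_io import DataError, RelAbundanceMatrix


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance/dissimilarity matrix."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DataError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise DataError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise DataError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise DataError("negative distances")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in scipy condensed order."""
        return squareform(self.values, checks=False)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class NMDSResult:
    coordinates: np.ndarray
    stress: float
    n_starts: int
    converged: bool
    labels: list[str]


@dataclass
class ANOSIMResult:
    R: float
    p: float
    n_perm: int


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str
    partial: bool = False


def _check_labels(*dms: DistanceMatrix) -> None:
    first = dms[0].labels
    for dm in dms[1:]:
        if dm.labels != first:
            raise DataError("distance matrices have mismatched labels")


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def bray_curtis(ra: RelAbundanceMatrix, transform: str = "sqrt") -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples.

    ``transform`` is applied to the per-sample abundance profiles first:
    ``sqrt`` (default, matching square-root transformed abundances),
    ``hellinger`` (square root of re-closed relative abundances — identical
    to ``sqrt`` when columns already sum to one) or ``none``.
    """
    if ra.n_samples < 2:
        raise DataError("need at least 2 samples")
    x = ra.ra.T.copy()  # samples x OTUs
    if transform == "sqrt":
        x = np.sqrt(x)
    elif transform == "hellinger":
        x = np.sqrt(x / x.sum(axis=1, keepdims=True))
    elif transform != "none":
        raise DataError(f"unknown transform {transform!r}")
    if (x.sum(axis=1) == 0).sum() >= 2:
        raise DataError("two all-zero samples: Bray-Curtis undefined")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(list(ra.sample_ids), d)


# ---------------------------------------------------------------------------
# NMDS (SMACOF + isotonic regression)
# ---------------------------------------------------------------------------

def _stress1(dhat: np.ndarray, dist: np.ndarray) -> float:
    denom = (dist**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dhat - dist) ** 2).sum() / denom))


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> NMDSResult:
    """Non-metric MDS minimising Kruskal stress-1.

    Each start alternates a Guttman (majorization) configuration update with
    isotonic regression of the configuration distances on the rank order of
    the observed dissimilarities (ties handled by the secondary approach:
    tied dissimilarities share one fitted value); the best of ``n_starts``
    random initialisations is returned with centred coordinates.
    """
    n = dm.n
    if k >= n:
        raise DataError("k must be smaller than the number of sites")
    delta = dm.condensed()
    order = np.argsort(delta, kind="stable")
    # tie blocks of equal dissimilarity, in sorted order
    sorted_delta = delta[order]
    block_ids = np.concatenate([[0], np.cumsum(np.diff(sorted_delta) > 1e-12)])
    rng = np.random.default_rng(seed)
    iso = IsotonicRegression()
    best: tuple[float, np.ndarray, bool] | None = None
    idx_i, idx_j = np.triu_indices(n, 1)
    for _ in range(n_starts):
        x = rng.normal(size=(n, k))
        prev = np.inf
        converged = False
        for _ in range(max_iter):
            dist = pdist(x)
            dist[dist == 0] = 1e-12
            fit = iso.fit_transform(np.arange(len(delta)), dist[order])
            # secondary tie treatment: average the fit within tie blocks
            sums = np.bincount(block_ids, weights=fit)
            counts = np.bincount(block_ids)
            fit = (sums / counts)[block_ids]
            dhat = np.empty_like(delta)
            dhat[order] = fit
            s = _stress1(dhat, dist)
            if prev - s < tol:
                converged = True
                break
            prev = s
            # Guttman transform with weights 1
            ratio = dhat / dist
            b = np.zeros((n, n))
            b[idx_i, idx_j] = -ratio
            b[idx_j, idx_i] = -ratio
            b[np.diag_indices(n)] = -b.sum(axis=1)
            x = b @ x / n
        x -= x.mean(axis=0)
        if best is None or s < best[0]:
            best = (s, x, converged)
    stress, coords, conv = best  # type: ignore[misc]
    return NMDSResult(coords, float(stress), n_starts, bool(conv), list(dm.labels))


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = len(ranks)
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return (rb - rw) / (m / 2)


def anosim(dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> ANOSIMResult:
    """Analysis of similarities: rank-based group-separation statistic R.

    R = (mean between-group rank - mean within-group rank) / (M/2), with
    M = n(n-1)/2 pairwise distances ranked with average ties; the p-value
    permutes group labels freely (one-way design).
    """
    groups = np.asarray(list(groups), dtype=object)
    if len(groups) != dm.n:
        raise DataError("group vector length does not match distance matrix")
    levels, counts = np.unique(groups, return_counts=True)
    if len(levels) < 2:
        raise DataError("need at least two groups")
    if (counts < 2).any():
        small = levels[counts < 2]
        raise DataError(f"group(s) of size 1: {list(small)}")
    ranks = stats.rankdata(dm.condensed())
    i, j = np.triu_indices(dm.n, 1)
    within = groups[i] == groups[j]
    r_obs = _anosim_r(ranks, within)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(groups))
        g = groups[perm]
        count += _anosim_r(ranks, g[i] == g[j]) >= r_obs - 1e-12
    p = (count + 1) / (n_perm + 1)
    return ANOSIMResult(float(r_obs), float(p), n_perm)


# ---------------------------------------------------------------------------
# Mantel / partial Mantel
# ---------------------------------------------------------------------------

def _triangle_corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "spearman":
        a, b = stats.rankdata(a), stats.rankdata(b)
    elif method != "pearson":
        raise DataError(f"unknown method {method!r}")
    if a.std() == 0 or b.std() == 0:
        raise DataError("zero-variance distance matrix")
    return float(np.corrcoef(a, b)[0, 1])


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test of matrix correlation over the n(n-1)/2 pairs.

    The permutation null relabels ``d2``'s rows and columns simultaneously;
    one-sided (positive association) by default.
    """
    _check_labels(d1, d2)
    v1 = d1.condensed()
    if method == "spearman":
        v1 = stats.rankdata(v1)
    r_obs = _triangle_corr(v1, d2.condensed(), method if method == "pearson" else "spearman")
    # NOTE: when method == spearman v1 is pre-ranked; re-ranking is idempotent
    rng = np.random.default_rng(seed)
    n = d1.n
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        v2p = squareform(d2.values[np.ix_(perm, perm)], checks=False)
        r = _triangle_corr(v1, v2p, method)
        if alternative == "greater":
            count += r >= r_obs - 1e-12
        else:
            count += abs(r) >= abs(r_obs) - 1e-12
    p = (count + 1) / (n_perm + 1)
    return MantelResult(float(r_obs), float(p), n_perm, method)


def _residualize(v: np.ndarray, on: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones(len(on)), on])
    beta, *_ = np.linalg.lstsq(x, v, rcond=None)
    return v - x @ beta


def partial_mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    d3: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Partial Mantel test: correlation of d1 and d2 controlling for d3.

    Residuals of d1 ~ d3 and d2 ~ d3 are computed on the upper-triangle
    vectors (ranked first for Spearman); the null permutes d2's rows and
    columns and re-residualises.
    """
    _check_labels(d1, d2, d3)

    def tri(dm: DistanceMatrix) -> np.ndarray:
        v = dm.condensed()
        return stats.rankdata(v) if method == "spearman" else v

    v1, v3 = tri(d1), tri(d3)
    r1 = _residualize(v1, v3)

    def partial_r(v2: np.ndarray) -> float:
        r2 = _residualize(v2, v3)
        # controlling a matrix for itself leaves numerical dust, not signal
        if r2.std() < 1e-10 * max(v2.std(), 1.0):
            return 0.0
        return _triangle_corr(r1, r2, "pearson")

    r_obs = partial_r(tri(d2))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(d1.n)
        v2p = squareform(d2.values[np.ix_(perm, perm)], checks=False)
        if method == "spearman":
            v2p = stats.rankdata(v2p)
        count += partial_r(v2p) >= r_obs - 1e-12
    p = (count + 1) / (n_perm + 1)
    return MantelResult(float(r_obs), float(p), n_perm, method, partial=True)
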