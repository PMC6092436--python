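"""Constrained ordination and variation partitioning.

The workflow mirrors standard practice for relating community composition
to explanatory variables:

1. a detrended correspondence analysis (DCA) gradient-length gate chooses
   the linear (RDA, longest gradient < 3 SD) or unimodal (CCA, > 4 SD)
   engine;
2. explanatory variables with variance inflation factor (VIF) above 20 are
   eliminated iteratively;
3. permutation forward selection retains variables with step p < 0.05;
4. variation partitioning (VPA) decomposes the community variance explained
   by the environmental (E) and spatial (S) variable sets into pure E|S,
   pure S|E, shared and residual fractions on the adjusted-R2 scale
   (Ezekiel's formula for RDA, a permutation analogue for CCA), with the
   pure fractions tested by permutation ANOVA on partial models.

Negative adjusted fractions are reported as-is, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .otu_io import DataError, RelAbundanceMatrix


# ---------------------------------------------------------------------------
# community transforms
# ---------------------------------------------------------------------------

def community_matrix(ra: RelAbundanceMatrix, transform: str = "hellinger") -> np.ndarray:
    """Samples x OTUs response matrix for linear ordination.

    ``hellinger`` (default, square root of within-sample fractions) or
    ``sqrt`` (identical on a valid relative-abundance matrix) or ``none``.
    """
    x = ra.ra.T
    if transform in ("hellinger", "sqrt"):
        return np.sqrt(x)
    if transform == "none":
        return x.copy()
    raise DataError(f"unknown transform {transform!r}")


def _as_matrix(x) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), [str(c) for c in x.columns]
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x, [f"x{i}" for i in range(x.shape[1])]


def _orthonormal_basis(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing, SVD-based)."""
    if x.size == 0:
        return np.zeros((x.shape[0], 0))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    if s.size == 0 or s.max() == 0:
        return np.zeros((x.shape[0], 0))
    rank = int((s > s.max() * 1e-10).sum())
    return u[:, :rank]


# ---------------------------------------------------------------------------
# response engines: RDA (linear) and CCA (chi-square / weighted)
# ---------------------------------------------------------------------------

class _Engine:
    """Shared projection machinery for RDA and CCA.

    Holds a prepared response matrix whose total sum of squares is the
    ordination's total variance (RDA) or inertia (CCA), and a predictor
    transform mapping raw explanatory columns into the space in which
    orthogonal projection yields the explained sum of squares.
    """

    method: str

    def __init__(self, response: np.ndarray):
        self.response = response
        self.n = response.shape[0]
        self.total_ss = float((response**2).sum())
        if self.total_ss <= 1e-12:
            raise DataError("total inertia is zero (degenerate community table)")

    def prepare_x(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def explained_ss(self, x: np.ndarray, response: np.ndarray | None = None) -> float:
        resp = self.response if response is None else response
        basis = _orthonormal_basis(self.prepare_x(x))
        if basis.shape[1] == 0:
            return 0.0
        return float(((basis.T @ resp) ** 2).sum())

    def fitted(self, x: np.ndarray) -> np.ndarray:
        basis = _orthonormal_basis(self.prepare_x(x))
        return basis @ (basis.T @ self.response)


class _RDAEngine(_Engine):
    method = "rda"

    def __init__(self, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        super().__init__(y - y.mean(axis=0))

    def prepare_x(self, x: np.ndarray) -> np.ndarray:
        return x - x.mean(axis=0)


class _CCAEngine(_Engine):
    method = "cca"

    def __init__(self, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        if (y < 0).any():
            raise DataError("CCA requires non-negative community data")
        total = y.sum()
        if total <= 0:
            raise DataError("empty community table")
        p = y / total
        self.r = p.sum(axis=1)
        self.c = p.sum(axis=0)
        if (self.r == 0).any() or (self.c == 0).any():
            raise DataError("CCA requires nonzero row and column sums")
        expected = np.outer(self.r, self.c)
        qbar = (p - expected) / np.sqrt(expected)
        super().__init__(qbar)

    def prepare_x(self, x: np.ndarray) -> np.ndarray:
        mean = self.r @ x  # row-weighted mean
        return np.sqrt(self.r)[:, None] * (x - mean)


def _make_engine(method: str, y: np.ndarray) -> _Engine:
    if method == "rda":
        return _RDAEngine(y)
    if method == "cca":
        return _CCAEngine(y)
    raise DataError(f"unknown ordination method {method!r}")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    method: str
    eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    site_scores: np.ndarray
    constrained_fraction: float
    adj_r2: float
    selected_vars: list[str]


@dataclass
class ForwardSelectionResult:
    selected: list[str]
    pseudo_f: list[float]
    p_values: list[float]
    cumulative_adj_r2: list[float]
    dropped_by_vif: dict[str, float] = field(default_factory=dict)


@dataclass
class VarPartResult:
    """Two-component variation partition on the adjusted-R2 scale."""

    E: float
    S: float
    pure_env: float
    pure_spatial: float
    shared: float
    residual: float
    p_pure_env: float | None = None
    p_pure_spatial: float | None = None

    def fractions(self) -> dict[str, float]:
        return {
            "pure_env": self.pure_env,
            "pure_spatial": self.pure_spatial,
            "shared": self.shared,
            "residual": self.residual,
        }


@dataclass
class DCAResult:
    axis_lengths: np.ndarray  # SD-of-turnover units, 4 axes
    recommendation: str  # rda | cca | either


# ---------------------------------------------------------------------------
# adjusted R2
# ---------------------------------------------------------------------------

def ezekiel_adj_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel's adjusted R2 = 1 - (1 - R2)(n - 1)/(n - m - 1)."""
    if n - m - 1 <= 0:
        raise DataError("overdetermined: n - m - 1 <= 0")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def _rank(x: np.ndarray) -> int:
    xc = x - x.mean(axis=0)
    if xc.size == 0:
        return 0
    s = np.linalg.svd(xc, compute_uv=False)
    return int((s > s.max() * 1e-10).sum()) if s.size and s.max() > 0 else 0


def _permutation_adj_r2(engine: _Engine, x: np.ndarray, r2: float, n_perm: int, seed: int) -> float:
    """Permutation analogue of Ezekiel's correction (CCA has no closed form)."""
    rng = np.random.default_rng(seed)
    acc = 0.0
    for _ in range(n_perm):
        perm = rng.permutation(engine.n)
        r2p = engine.explained_ss(x[perm]) / engine.total_ss
        acc += 1.0 / max(1e-12, 1.0 - r2p)
    return 1.0 - (1.0 - r2) * acc / n_perm


# ---------------------------------------------------------------------------
# RDA / CCA
# ---------------------------------------------------------------------------

def _ordination(method: str, y, x, n_perm: int = 199, seed: int = 0) -> OrdinationResult:
    xm, names = _as_matrix(x)
    engine = _make_engine(method, np.asarray(y, dtype=float))
    n = engine.n
    if xm.shape[0] != n:
        raise DataError("response and explanatory row counts differ")
    m = _rank(xm)
    if m >= n - 1:
        raise DataError("overdetermined: as many explanatory dimensions as samples")
    fitted = engine.fitted(xm)
    resid = engine.response - fitted
    ss_fit = float((fitted**2).sum())
    r2 = ss_fit / engine.total_ss
    # axes from the fitted (constrained) and residual (unconstrained) parts
    _, s_fit, vt = np.linalg.svd(fitted, full_matrices=False)
    eig = (s_fit**2)[s_fit**2 > 1e-12 * max(1.0, ss_fit)]
    s_res = np.linalg.svd(resid, compute_uv=False)
    eig_res = (s_res**2)[s_res**2 > 1e-10]
    site_scores = fitted @ vt.T[:, : max(1, len(eig))]
    if method == "rda":
        adj = ezekiel_adj_r2(r2, n, m)
    else:
        adj = _permutation_adj_r2(engine, xm, r2, n_perm, seed)
    return OrdinationResult(method, eig, eig_res, site_scores, float(r2), float(adj), names)


def rda(y, x, **kw) -> OrdinationResult:
    """Redundancy analysis of a (transformed) community matrix on x."""
    return _ordination("rda", y, x, **kw)


def cca(y, x, **kw) -> OrdinationResult:
    """Canonical correspondence analysis of non-negative community data on x."""
    return _ordination("cca", y, x, **kw)


# ---------------------------------------------------------------------------
# VIF filter
# ---------------------------------------------------------------------------

def vif_filter(x: pd.DataFrame, threshold: float = 20.0) -> tuple[pd.DataFrame, dict[str, float]]:
    """Iteratively drop the highest-VIF column while any VIF exceeds threshold.

    VIF_j = 1/(1 - R2_j) from regressing column j on the remaining columns
    (with intercept); perfect collinearity counts as infinite VIF.  Ties
    break toward the later column.
    """
    if not isinstance(x, pd.DataFrame):
        x = pd.DataFrame(np.asarray(x, dtype=float),
                         columns=[f"x{i}" for i in range(np.asarray(x).shape[1])])
    if x.shape[1] < 2:
        return x.copy(), {}
    keep = list(x.columns)
    dropped: dict[str, float] = {}
    while len(keep) >= 2:
        vifs = _vifs(x[keep].to_numpy(dtype=float))
        worst = int(np.argmax([v if np.isfinite(v) else np.inf for v in vifs]))
        # later-column tie-break
        vmax = vifs[worst]
        for j in range(len(vifs) - 1, -1, -1):
            if vifs[j] == vmax or (np.isinf(vifs[j]) and np.isinf(vmax)):
                worst = j
                break
        if vifs[worst] <= threshold:
            break
        dropped[keep[worst]] = float(vifs[worst])
        keep.pop(worst)
    return x[keep].copy(), dropped


def _vifs(x: np.ndarray) -> list[float]:
    n, m = x.shape
    out = []
    for j in range(m):
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        yj = x[:, j]
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        sst = float(((yj - yj.mean()) ** 2).sum())
        if sst == 0:
            out.append(np.inf)
            continue
        r2 = 1.0 - float((resid**2).sum()) / sst
        out.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
    return out


# ---------------------------------------------------------------------------
# forward selection and permutation ANOVA
# ---------------------------------------------------------------------------

def _partial_f(engine: _Engine, ss_sel: float, ss_both: float, k_sel: int, k_add: int) -> float:
    n = engine.n
    df_resid = n - k_sel - k_add - 1
    if df_resid <= 0:
        return np.nan
    num = (ss_both - ss_sel) / k_add
    den = (engine.total_ss - ss_both) / df_resid
    return num / max(den, 1e-300)


def forward_select(
    y,
    x: pd.DataFrame,
    method: str = "rda",
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> ForwardSelectionResult:
    """Permutation forward selection of explanatory variables.

    At each step the unselected variable with the largest partial pseudo-F
    is tested by permuting reduced-model residual rows; it joins the model
    if p < alpha, and selection stops at the first failure.  ``x`` must
    already be VIF-filtered (collinear candidates are a contract violation).
    """
    if not isinstance(x, pd.DataFrame):
        x = pd.DataFrame(np.asarray(x, dtype=float),
                         columns=[f"x{i}" for i in range(np.asarray(x).shape[1])])
    xm = x.to_numpy(dtype=float)
    if x.shape[1] >= 2 and any(not np.isfinite(v) for v in _vifs(xm)):
        raise DataError("collinear candidates: VIF filter contract violated")
    engine = _make_engine(method, np.asarray(y, dtype=float))
    n = engine.n
    rng = np.random.default_rng(seed)
    names = list(x.columns)
    selected: list[int] = []
    fs: list[float] = []
    ps: list[float] = []
    adj: list[float] = []
    remaining = list(range(len(names)))
    while remaining:
        x_sel = xm[:, selected]
        k_sel = _rank(x_sel) if selected else 0
        ss_sel = engine.explained_ss(x_sel) if selected else 0.0
        cand_f = []
        for j in remaining:
            ss_both = engine.explained_ss(xm[:, selected + [j]])
            cand_f.append(_partial_f(engine, ss_sel, ss_both, k_sel, 1))
        best = remaining[int(np.nanargmax(cand_f))]
        f_obs = cand_f[remaining.index(best)]
        if not np.isfinite(f_obs):
            break
        # reduced-model residual permutation
        fitted_red = engine.fitted(x_sel) if selected else np.zeros_like(engine.response)
        resid_red = engine.response - fitted_red
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            resp_perm = fitted_red + resid_red[perm]
            ss_sel_p = float(((_orthonormal_basis(engine.prepare_x(x_sel)).T @ resp_perm) ** 2).sum()) if selected else 0.0
            ss_both_p = float(((_orthonormal_basis(engine.prepare_x(xm[:, selected + [best]])).T @ resp_perm) ** 2).sum())
            num = ss_both_p - ss_sel_p
            den = ((resp_perm**2).sum() - ss_both_p) / (n - k_sel - 2)
            count += num / max(den, 1e-300) >= f_obs - 1e-12
        p = (count + 1) / (n_perm + 1)
        if p >= alpha:
            break
        selected.append(best)
        remaining.remove(best)
        fs.append(float(f_obs))
        ps.append(float(p))
        r2 = engine.explained_ss(xm[:, selected]) / engine.total_ss
        k = _rank(xm[:, selected])
        adj.append(ezekiel_adj_r2(r2, n, k) if method == "rda"
                   else _permutation_adj_r2(engine, xm[:, selected], r2, 99, int(rng.integers(2**31))))
    return ForwardSelectionResult([names[j] for j in selected], fs, ps, adj)


def permutation_anova(
    y,
    x,
    method: str = "rda",
    n_perm: int = 999,
    seed: int = 0,
    conditioning=None,
) -> tuple[float, float]:
    """Permutation test of the (partial) constrained model; returns (F, p).

    With ``conditioning`` the test is of x given the conditioning set,
    permuting residual rows under the reduced (conditioning-only) model.
    """
    xm, _ = _as_matrix(x)
    engine = _make_engine(method, np.asarray(y, dtype=float))
    n = engine.n
    if conditioning is not None:
        zm, _ = _as_matrix(conditioning)
        k_z = _rank(zm)
        ss_z = engine.explained_ss(zm)
        fitted_red = engine.fitted(zm)
    else:
        zm = np.zeros((n, 0))
        k_z = 0
        ss_z = 0.0
        fitted_red = np.zeros_like(engine.response)
    both = np.column_stack([zm, xm]) if zm.shape[1] else xm
    k_x = _rank(both) - k_z
    if k_x <= 0:
        raise DataError("x adds no dimensions beyond the conditioning set")
    ss_both = engine.explained_ss(both)
    f_obs = _partial_f(engine, ss_z, ss_both, k_z, k_x)
    if not np.isfinite(f_obs):
        raise DataError("overdetermined model: no residual degrees of freedom")
    resid_red = engine.response - fitted_red
    basis_z = _orthonormal_basis(engine.prepare_x(zm)) if zm.shape[1] else np.zeros((n, 0))
    basis_both = _orthonormal_basis(engine.prepare_x(both))
    rng = np.random.default_rng(seed)
    count = 0
    df_resid = n - k_z - k_x - 1
    for _ in range(n_perm):
        perm = rng.permutation(n)
        resp = fitted_red + resid_red[perm]
        ss_z_p = float(((basis_z.T @ resp) ** 2).sum()) if basis_z.shape[1] else 0.0
        ss_b_p = float(((basis_both.T @ resp) ** 2).sum())
        num = (ss_b_p - ss_z_p) / k_x
        den = ((resp**2).sum() - ss_b_p) / df_resid
        count += num / max(den, 1e-300) >= f_obs - 1e-12
    return float(f_obs), float((count + 1) / (n_perm + 1))


# ---------------------------------------------------------------------------
# variation partitioning
# ---------------------------------------------------------------------------

def variation_partition(
    y,
    x_env,
    x_spa,
    method: str = "rda",
    n_perm: int = 999,
    seed: int = 0,
    test_pure: bool = True,
) -> VarPartResult:
    """Two-component variation partitioning on the adjusted-R2 scale.

    Fits the E, S and E+S models, adjusts each R2 (Ezekiel for RDA, the
    permutation analogue for CCA), and derives pure, shared and residual
    fractions; pure fractions are tested by partial permutation ANOVA.
    """
    xe, _ = _as_matrix(x_env)
    xs, _ = _as_matrix(x_spa)
    if xe.shape[1] == 0 or xs.shape[1] == 0:
        raise DataError("both explanatory sets must be non-empty")
    engine = _make_engine(method, np.asarray(y, dtype=float))
    n = engine.n
    rng = np.random.default_rng(seed)

    def adj_of(xm: np.ndarray) -> float:
        m = _rank(xm)
        if m >= n - 1:
            raise DataError("overdetermined explanatory set")
        r2 = engine.explained_ss(xm) / engine.total_ss
        if method == "rda":
            return ezekiel_adj_r2(r2, n, m)
        return _permutation_adj_r2(engine, xm, r2, max(199, n_perm // 5), int(rng.integers(2**31)))

    a_e = adj_of(xe)
    a_s = adj_of(xs)
    a_es = adj_of(np.column_stack([xe, xs]))
    pure_env = a_es - a_s
    pure_spatial = a_es - a_e
    shared = a_e + a_s - a_es
    residual = 1.0 - a_es
    p_e = p_s = None
    if test_pure:
        _, p_e = permutation_anova(y, xe, method, n_perm, int(rng.integers(2**31)), conditioning=xs)
        _, p_s = permutation_anova(y, xs, method, n_perm, int(rng.integers(2**31)), conditioning=xe)
    res = VarPartResult(a_e, a_s, pure_env, pure_spatial, shared, residual, p_e, p_s)
    total = res.pure_env + res.pure_spatial + res.shared + res.residual
    assert abs(total - 1.0) < 1e-9, "variation-partition fractions must sum to 1"
    return res


# ---------------------------------------------------------------------------
# DCA gradient length
# ---------------------------------------------------------------------------

def dca_gradient_length(ra: RelAbundanceMatrix | np.ndarray, n_axes: int = 4,
                        n_segments: int = 26) -> DCAResult:
    """Detrended correspondence analysis axis lengths, in turnover SD units.

    Site scores come from reciprocal averaging; axes beyond the first are
    detrended against earlier axes by segment-wise centring (26 segments).
    Each axis is rescaled so the abundance-weighted mean within-species
    standard deviation of site scores is one — its length is then the range
    of site scores, the number of species turnovers along the axis.

    Recommendation: ``rda`` when the longest axis is < 3, ``cca`` when > 4,
    ``either`` in between.
    """
    y = ra.ra.T if isinstance(ra, RelAbundanceMatrix) else np.asarray(ra, dtype=float)
    if y.shape[0] < 3 or y.shape[1] < 2:
        raise DataError("DCA needs >= 3 samples and >= 2 OTUs")
    if (y.sum(axis=0) > 0).sum() < 2:
        raise DataError("degenerate table: fewer than 2 nonzero OTUs")
    y = y[:, y.sum(axis=0) > 0]
    row_sums = y.sum(axis=1)
    if (row_sums == 0).any():
        raise DataError("all-zero sample in DCA input")
    col_sums = y.sum(axis=0)
    total = y.sum()
    w = row_sums / total

    def weighted_center(u: np.ndarray) -> np.ndarray:
        return u - (w * u).sum()

    def detrend(u: np.ndarray, prev: np.ndarray) -> np.ndarray:
        edges = np.linspace(prev.min(), prev.max() + 1e-12, n_segments + 1)
        seg = np.clip(np.digitize(prev, edges) - 1, 0, n_segments - 1)
        out = u.copy()
        for s in np.unique(seg):
            mask = seg == s
            out[mask] -= (w[mask] * u[mask]).sum() / max(w[mask].sum(), 1e-300)
        return out

    axes: list[np.ndarray] = []
    lengths = np.zeros(n_axes)
    rng = np.random.default_rng(0)
    for k in range(n_axes):
        u = np.arange(y.shape[0], dtype=float) + rng.normal(scale=1e-3, size=y.shape[0])
        u = weighted_center(u)
        shrink = 0.0
        for _ in range(300):
            v = (y.T @ u) / col_sums  # species scores (centroids)
            u_new = (y @ v) / row_sums  # site scores
            for prev in axes:
                u_new = detrend(u_new, prev)
            u_new = weighted_center(u_new)
            sd = np.sqrt((w * u_new**2).sum())
            # one reciprocal-averaging cycle contracts a unit-variance axis
            # by its eigenvalue; the converged sd is that eigenvalue
            shrink = sd
            if sd < 1e-12:
                u = u_new
                break
            u_new /= sd
            if np.abs(u_new - u).max() < 1e-10 or np.abs(u_new + u).max() < 1e-10:
                u = u_new
                break
            u = u_new
        sd = np.sqrt((w * u**2).sum())
        if sd < 1e-12:
            lengths[k] = 0.0
            axes.append(u)
            continue
        # within-species dispersion of site scores, abundance weighted
        v = (y.T @ u) / col_sums
        within = (y * (u[:, None] - v[None, :]) ** 2).sum(axis=0) / col_sums
        weights = col_sums / total
        occ = (y > 0).sum(axis=0)
        usable = occ >= 2
        if usable.any():
            tol = np.sqrt((weights[usable] * within[usable]).sum() / weights[usable].sum())
        else:
            tol = 0.0
        # within-species dispersion is measured on the reciprocal-averaged
        # (shrunken) scale; sqrt(eigenvalue) undoes the shrinkage so the
        # length comes out in species-turnover SD units
        lengths[k] = (u.max() - u.min()) * np.sqrt(max(shrink, 0.0)) / tol if tol > 1e-12 else 0.0
        axes.append(u)
    longest = lengths.max()
    rec = "rda" if longest < 3 else ("cca" if longest > 4 else "either")
    return DCAResult(lengths, rec)
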