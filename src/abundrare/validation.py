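"""Calibration and parameter-recovery experiments.

These routines exercise the estimators on data with known ground truth:
type-I error of the permutation tests on null data, recovery of the Sloan
Nm parameter from neutrally assembled communities, and recovery of the
dominant assembly process (selection vs. dispersal limitation) by variation
partitioning.  They back both the test suite and the reproducibility
script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .distance import DistanceMatrix, anosim, mantel
from .neutral import fit_ncm
from .ordination import forward_select, variation_partition
from .simulate import SimulationConfig, simulate_metacommunity, simulate_neutral_assembly
from .spatial import haversine_matrix, pcnm_basis


def _random_distance(rng: np.random.Generator, n: int) -> DistanceMatrix:
    pts = rng.normal(size=(n, 3))
    d = squareform(np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)), checks=False)
    return DistanceMatrix([f"s{i}" for i in range(n)], squareform(d))


def mantel_type1_error(n_sims: int = 500, n: int = 12, n_perm: int = 199,
                       alpha: float = 0.05, seed: int = 0) -> float:
    """Fraction of independent-matrix nulls the Mantel test rejects at alpha."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        d1 = _random_distance(rng, n)
        d2 = _random_distance(rng, n)
        res = mantel(d1, d2, n_perm=n_perm, seed=int(rng.integers(2**31)))
        rejections += res.p <= alpha
    return rejections / n_sims


def anosim_type1_error(n_sims: int = 500, n: int = 12, n_groups: int = 3,
                       n_perm: int = 199, alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of ANOSIM with random labels on structureless distances."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(n_groups), n // n_groups)[:n]
    rejections = 0
    for _ in range(n_sims):
        dm = _random_distance(rng, n)
        g = labels[rng.permutation(n)]
        res = anosim(dm, g, n_perm=n_perm, seed=int(rng.integers(2**31)))
        rejections += res.p <= alpha
    return rejections / n_sims


def forward_step_type1_error(n_sims: int = 500, n: int = 15, n_species: int = 30,
                             n_perm: int = 199, alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of the forward-selection step test on pure noise.

    One candidate variable, so the step test's level is not inflated by
    best-of-many selection.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        y = rng.normal(size=(n, n_species))
        x = pd.DataFrame({"v1": rng.normal(size=n)})
        res = forward_select(y, x, "rda", alpha=alpha, n_perm=n_perm,
                             seed=int(rng.integers(2**31)))
        rejections += len(res.selected) > 0
    return rejections / n_sims


def ncm_recovery(n_seeds: int = 20, nm_true: float = 1000.0, n_samples: int = 50,
                 depth: int = 10000, n_otus: int = 500, rel_tol: float = 0.15,
                 r2_min: float = 0.8, seed: int = 0) -> dict:
    """Recover Nm from neutrally assembled communities over many seeds.

    Returns the success fraction (|Nm_hat - Nm|/Nm <= rel_tol and
    R^2 > r2_min) plus the per-seed estimates.
    """
    rng = np.random.default_rng(seed)
    pool = rng.lognormal(0, 2.0, n_otus)
    pool /= pool.sum()
    estimates, r2s = [], []
    for _ in range(n_seeds):
        cm = simulate_neutral_assembly(pool, nm_true, n_samples, depth,
                                       seed=int(rng.integers(2**31)))
        fit = fit_ncm(cm)
        estimates.append(fit.Nm)
        r2s.append(fit.r_squared)
    estimates = np.array(estimates)
    r2s = np.array(r2s)
    ok = (np.abs(estimates - nm_true) / nm_true <= rel_tol) & (r2s > r2_min)
    return {"success_rate": float(ok.mean()), "Nm": estimates, "r2": r2s}


def vpa_process_recovery(n_runs: int = 50, n_samples: int = 40, n_otus: int = 400,
                         depth: int = 2000, mode: str = "env", margin: float = 0.1,
                         n_perm: int = 99, seed: int = 0) -> dict:
    """Does VPA identify the process that actually structured the community?

    ``mode="env"`` simulates pure selection (w_env=1, w_space=0) and counts
    runs where pure_env - pure_spatial > margin; ``mode="space"`` is the
    mirror image.  Explanatory sets are the simulated environmental panel
    and forward-selected PCNM axes.
    """
    rng = np.random.default_rng(seed)
    wins = []
    for _ in range(n_runs):
        cfg = SimulationConfig(
            n_otus=n_otus, n_samples=n_samples, n_clusters=4, depth=depth,
            w_env=2.0 if mode == "env" else 0.0,
            w_space=0.0 if mode == "env" else 2.0,
            dispersal_range=60.0,
            env_spatial_confounding=0.0,
            seed=int(rng.integers(2**31)),
        )
        cm, meta, _ = simulate_metacommunity(cfg)
        ra = cm.counts / cm.sample_sums()
        y = np.sqrt(ra.T)
        env = meta.env()
        envz = (env - env.mean()) / env.std(ddof=1)
        geo = haversine_matrix(meta)
        pcnm = pcnm_basis(geo)
        spa = pcnm.to_frame().reset_index(drop=True)
        sel = forward_select(y, spa, "rda", n_perm=n_perm,
                             seed=int(rng.integers(2**31)))
        spa_sel = spa[sel.selected] if sel.selected else spa.iloc[:, :3]
        vpa = variation_partition(y, envz.reset_index(drop=True), spa_sel,
                                  method="rda", test_pure=False)
        diff = vpa.pure_env - vpa.pure_spatial
        wins.append(diff > margin if mode == "env" else -diff > margin)
    return {"success_rate": float(np.mean(wins)), "n_runs": n_runs}
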