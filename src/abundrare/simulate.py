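"""Synthetic metacommunities with tunable niche and dispersal structure.

The generator emulates a coastal survey: stations grouped into a few bays
along a roughly one-dimensional coastline arc spanning ~5 degrees of
latitude, two depth layers per station, a long-tailed (lognormal) regional
OTU pool, environmental gradients partially confounded with space, and
multinomial sequencing at a fixed read depth.

Each OTU i has a regional pool abundance, an environmental optimum and a
geographic source position.  The expected composition of sample s is

    pool_i * exp(-w_env (env_s - opt_i)^2 / (2 breadth^2))
           * exp(-w_space dist(s, source_i) / dispersal_range)

renormalised and sampled multinomially at the configured depth.  With
w_env = w_space = 0 every sample is an iid multinomial draw from the pool
(pure sampling noise); the two weights dial selection and dispersal
limitation independently, and the confounding parameter mixes the spatial
coordinate into the environmental gradients so that the shared fraction of
a variation partition has a known control.

``simulate_neutral_assembly`` instead draws each local community from a
Dirichlet(Nm x pool) law — the stationary multivariate form consistent
with the Sloan model's Beta marginals — and serves as the ground truth for
neutral-model parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .otu_io import CountMatrix, DataError, SampleTable

#: environmental variable names emulating a coastal physico-chemical panel
ENV_NAMES = ("temperature", "salinity", "DO", "NH4_N", "NO2_N")


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic metacommunity.

    Defaults emulate the survey design the pipeline targets: 22 samples in
    3 bays spanning ~5 degrees of latitude, a lognormal pool of 20,000
    OTUs, and 28,923 reads per sample.
    """

    n_otus: int = 20000
    n_samples: int = 22
    n_clusters: int = 3
    depth: int = 28923
    w_env: float = 1.0
    w_space: float = 1.0
    niche_breadth: float = 1.0
    dispersal_range: float = 150.0  # km
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 2.5
    env_spatial_confounding: float = 0.5
    span_degrees: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 100:
            raise DataError("depth must be >= 100")
        if self.n_clusters > self.n_samples:
            raise DataError("more clusters than samples")
        if self.w_env < 0 or self.w_space < 0:
            raise DataError("weights must be >= 0")
        if not 0 <= self.env_spatial_confounding <= 1:
            raise DataError("confounding must lie in [0, 1]")


@dataclass
class SimulationTruth:
    """Latent drivers: everything needed to recompute expected compositions."""

    pool: np.ndarray  # regional relative abundances
    position_km: np.ndarray  # per-sample along-coast position
    env_score: np.ndarray  # per-sample latent environmental position
    optimum: np.ndarray  # per-OTU environmental optimum
    source_km: np.ndarray  # per-OTU geographic source
    cluster: np.ndarray  # per-sample bay index
    config: SimulationConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def expected_composition(self) -> np.ndarray:
        """Recompute the expected OTU x sample composition from the latents."""
        cfg = self.config
        logw = np.broadcast_to(
            np.log(self.pool)[:, None], (len(self.pool), len(self.position_km))
        ).copy()
        if cfg.w_env > 0:
            logw = logw - cfg.w_env * (self.env_score[None, :] - self.optimum[:, None]) ** 2 / (
                2 * cfg.niche_breadth**2
            )
        if cfg.w_space > 0:
            dist = np.abs(self.position_km[None, :] - self.source_km[:, None])
            logw = logw - cfg.w_space * dist / cfg.dispersal_range
        w = np.exp(logw - logw.max(axis=0))
        return w / w.sum(axis=0)


def simulate_metacommunity(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, SampleTable, SimulationTruth]:
    """Generate a count table, matching metadata, and the latent truth."""
    rng = np.random.default_rng(cfg.seed)
    km_per_deg = 111.19
    arc_km = cfg.span_degrees * km_per_deg

    # stations along the coastline, clustered into bays
    cluster = np.sort(np.arange(cfg.n_samples) % cfg.n_clusters)
    centres = (np.arange(cfg.n_clusters) + 0.5) / cfg.n_clusters * arc_km
    jitter = rng.normal(scale=arc_km / (12 * cfg.n_clusters), size=cfg.n_samples)
    position = np.clip(centres[cluster] + jitter, 0, arc_km)

    # latent environmental position: confounded mix of space and noise
    z_space = (position - position.mean()) / max(position.std(), 1e-12)
    noise = rng.normal(size=cfg.n_samples)
    rho = cfg.env_spatial_confounding
    env_score = rho * z_space + (1 - rho) * noise
    env_score = (env_score - env_score.mean()) / max(env_score.std(), 1e-12)

    # regional pool: long-tailed lognormal
    pool = rng.lognormal(cfg.lognormal_mu, cfg.lognormal_sigma, cfg.n_otus)
    pool /= pool.sum()
    optimum = rng.normal(scale=1.5, size=cfg.n_otus)
    source = rng.uniform(0, arc_km, size=cfg.n_otus)

    truth = SimulationTruth(pool, position, env_score, optimum, source, cluster, cfg)
    comp = truth.expected_composition()
    counts = np.empty((cfg.n_otus, cfg.n_samples), dtype=np.int64)
    for j in range(cfg.n_samples):
        counts[:, j] = rng.multinomial(cfg.depth, comp[:, j])

    otu_ids = [f"OTU{i + 1}" for i in range(cfg.n_otus)]
    sample_ids = [f"S{j + 1}" for j in range(cfg.n_samples)]
    cm = CountMatrix(otu_ids, sample_ids, counts)

    bays = np.array([f"bay{c + 1}" for c in cluster])
    lat0 = 21.0
    lat = lat0 + position / km_per_deg
    lon = 110.0 + 0.2 * np.sin(position / arc_km * np.pi)  # gentle coastline curvature
    layer = np.where(np.arange(cfg.n_samples) % 2 == 0, "surface", "bottom")
    env_vars = {}
    for k, name in enumerate(ENV_NAMES):
        loading = 1.0 - 0.15 * k
        base = {"temperature": 25.0, "salinity": 31.0, "DO": 7.0, "NH4_N": 0.05, "NO2_N": 0.02}[name]
        scale = {"temperature": 2.0, "salinity": 1.5, "DO": 0.8, "NH4_N": 0.03, "NO2_N": 0.01}[name]
        vals = base + scale * (loading * env_score + 0.3 * rng.normal(size=cfg.n_samples))
        env_vars[name] = np.maximum(vals, 0.0)
    meta = SampleTable(pd.DataFrame({
        "sample_id": sample_ids,
        "station": [f"ST{j // 2 + 1}" for j in range(cfg.n_samples)],
        "bay": bays,
        "layer": layer,
        "latitude": lat,
        "longitude": lon,
        **env_vars,
    }))
    return cm, meta, truth


def simulate_neutral_assembly(
    pool: np.ndarray, Nm: float, n_samples: int, depth: int, seed: int = 0
) -> CountMatrix:
    """Neutrally assembled local communities: Dirichlet(Nm x pool) then multinomial.

    The Dirichlet law is the stationary joint distribution whose marginals
    are the Beta(Nm p, Nm (1-p)) abundances of the Sloan formulation, so a
    table generated here is the recovery oracle for :func:`~abundrare.neutral.fit_ncm`.
    """
    pool = np.asarray(pool, dtype=float)
    if abs(pool.sum() - 1.0) > 1e-9:
        raise DataError("pool must sum to 1")
    if (pool > 0).sum() < 2:
        raise DataError("degenerate pool: need at least 2 taxa")
    if Nm <= 0:
        raise DataError("Nm must be positive")
    rng = np.random.default_rng(seed)
    counts = np.empty((len(pool), n_samples), dtype=np.int64)
    alpha = Nm * pool
    for j in range(n_samples):
        # gamma representation of the Dirichlet is stable for tiny alphas
        g = rng.gamma(np.maximum(alpha, 1e-300))
        total = g.sum()
        if total == 0:
            g[np.argmax(pool)] = 1.0
            total = 1.0
        counts[:, j] = rng.multinomial(depth, g / total)
    otu_ids = [f"OTU{i + 1}" for i in range(len(pool))]
    sample_ids = [f"S{j + 1}" for j in range(n_samples)]
    return CountMatrix(otu_ids, sample_ids, counts)
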