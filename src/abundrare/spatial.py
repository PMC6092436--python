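"""Geographic and environmental distances, distance-decay, and PCNM axes.

Geographic distance is the great-circle (haversine) distance in km; the
sampled bays span several degrees of latitude, so Euclidean distance on raw
degrees would distort longitudinal separations.  Environmental distance is
Euclidean on log(x+1)-transformed (pH excepted) and z-scored variables.

PCNM (principal coordinates of neighbour matrices) builds orthogonal
spatial eigenfunctions from a truncated geographic distance matrix: keep
distances up to a truncation threshold t (by default the longest edge of
the minimum spanning tree), replace larger ones by 4t, Gower-double-centre
-0.5 D*^2, and retain the eigenvectors with positive eigenvalues scaled by
the square root of their eigenvalue.  These axes serve as spatial
explanatory variables for constrained ordination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

from .distance import DistanceMatrix, MantelResult, mantel
from .otu_io import DataError, SampleTable

EARTH_RADIUS_KM = 6371.0088


@dataclass
class PCNMBasis:
    """Spatial eigenfunctions from truncated geographic distances."""

    labels: list[str]
    eigenvalues: np.ndarray  # descending, positive only
    vectors: np.ndarray  # sites x axes, scaled by sqrt(eigenvalue)
    truncation: float  # km
    n_positive: int

    def to_frame(self):
        import pandas as pd

        cols = [f"PCNM{i + 1}" for i in range(self.n_positive)]
        return pd.DataFrame(self.vectors, index=self.labels, columns=cols)


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance between two points in km."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1))))


def haversine_matrix(meta: SampleTable) -> DistanceMatrix:
    """Pairwise great-circle distances (km) between samples."""
    coords = meta.coordinates()
    lat = np.radians(coords["latitude"].to_numpy())
    lon = np.radians(coords["longitude"].to_numpy())
    dphi = lat[:, None] - lat[None, :]
    dlam = lon[:, None] - lon[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(meta.sample_ids, d)


def env_distance(meta: SampleTable, variables=None, log_exempt=("pH", "ph")) -> DistanceMatrix:
    """Euclidean distance on transformed, standardised environmental data.

    Every variable except pH is log(x+1) transformed, then each variable is
    z-scored across samples before the Euclidean distance is taken.
    """
    env = meta.env(variables)
    if env.isna().any().any():
        col = env.columns[env.isna().any()][0]
        raise DataError(f"missing value in environmental variable {col!r}")
    x = env.to_numpy(dtype=float).copy()
    exempt = {e.lower() for e in log_exempt}
    for j, name in enumerate(env.columns):
        if name.lower() in exempt:
            continue
        if (x[:, j] < 0).any():
            raise DataError(f"negative value in {name!r} under log(x+1) transform")
        x[:, j] = np.log1p(x[:, j])
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    x = (x - x.mean(axis=0)) / sd
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(meta.sample_ids, (d + d.T) / 2)


def distance_decay(
    comm: DistanceMatrix,
    geo: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[MantelResult, float]:
    """Distance-decay of community similarity: Mantel test plus OLS slope.

    Returns the Mantel result (Spearman by default, one-sided positive) and
    the least-squares slope of dissimilarity against geographic distance.
    """
    res = mantel(comm, geo, method=method, n_perm=n_perm, seed=seed)
    x, y = geo.condensed(), comm.condensed()
    slope = float(np.polyfit(x, y, 1)[0])
    return res, slope


def mst_longest_edge(d: np.ndarray) -> float:
    """Longest edge of the minimum spanning tree of a distance matrix."""
    tree = minimum_spanning_tree(d).toarray()
    return float(tree.max())


def pcnm_basis(geo: DistanceMatrix, truncation: float | None = None) -> PCNMBasis:
    """Construct PCNM spatial eigenfunctions from a geographic distance matrix.

    ``truncation=None`` uses the minimum-spanning-tree longest edge; larger
    distances are replaced by 4 x truncation before principal-coordinate
    analysis.  Axes are numbered in descending eigenvalue order and
    sign-fixed so each axis' largest-magnitude loading is positive.
    """
    n = geo.n
    if n < 3:
        raise DataError("PCNM needs at least 3 sites")
    d = geo.values.copy()
    offdiag = d[~np.eye(n, dtype=bool)]
    if offdiag.max() == 0:
        raise DataError("all sites coincident")
    t = mst_longest_edge(d) if truncation is None else float(truncation)
    dstar = np.where(d > t, 4.0 * t, d)
    np.fill_diagonal(dstar, 0.0)
    a = -0.5 * dstar**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    g = (g + g.T) / 2
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > 1e-8
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    vectors = eigvec * np.sqrt(eigval)
    # reproducible sign: largest |loading| positive on every axis
    for j in range(vectors.shape[1]):
        i = np.argmax(np.abs(vectors[:, j]))
        if vectors[i, j] < 0:
            vectors[:, j] = -vectors[:, j]
    return PCNMBasis(list(geo.labels), eigval, vectors, t, int(keep.sum()))
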