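"""Sloan neutral community model for large microbial populations.

The model predicts the frequency with which a taxon of regional mean
relative abundance p is detected across local communities assembled purely
by random drift and immigration.  In a local community of size N with
immigration rate m, the stationary local abundance of the taxon follows a
Beta(Nm p, Nm (1 - p)) distribution, so the probability of detecting it
above a detection limit d is

    freq(p) = 1 - BetaCDF(d; Nm p, Nm (1 - p)).

A single free parameter Nm (metacommunity size x immigration) is fitted by
least squares of observed occurrence frequencies on regional abundances;
the fit's R^2 measures how much of the frequency-abundance relationship
neutral assembly alone explains.

Two detection kernels are offered.  The classic *threshold* kernel above
treats a taxon as detected when its latent local abundance exceeds d
(conventionally one read at the mean depth, d = 1/N).  The default
*sampling* kernel instead models detection as drawing at least one read in
a multinomial sample of size N from the latent composition,

    freq(p) = 1 - E[(1 - x)^N] = 1 - B(Nm p, Nm (1 - p) + N) / B(Nm p, Nm (1 - p)),

which is exact for count data and avoids the upward Nm bias the hard
threshold introduces at finite sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .otu_io import CountMatrix, DataError


@dataclass
class NCMFit:
    """Fitted Sloan model: Nm, the implied immigration rate m = Nm/N, R^2."""

    Nm: float
    N: float
    m: float
    r_squared: float
    detection_limit: float
    table: pd.DataFrame  # per-OTU: p, freq_obs, freq_pred, ci_low, ci_high


def ncm_predict(p, Nm: float, d: float):
    """Predicted detection frequency for regional abundance(s) p."""
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise DataError("regional abundance must lie strictly in (0, 1)")
    if Nm <= 0 or not 0 < d < 1:
        raise DataError("require Nm > 0 and detection limit in (0, 1)")
    out = 1.0 - stats.beta.cdf(d, Nm * p, Nm * (1.0 - p))
    return float(out) if out.ndim == 0 else out


def _sampling_freq(p: np.ndarray, nm: float, depth: float) -> np.ndarray:
    """P(at least one read) for a Beta(Nm p, Nm(1-p)) taxon sampled at ``depth``."""
    a = nm * p
    b = nm * (1.0 - p)
    return 1.0 - np.exp(special.betaln(a, b + depth) - special.betaln(a, b))


def _wilson_interval(p: np.ndarray, n: int, z: float = 1.959963984540054):
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return np.clip(centre - half, 0, 1), np.clip(centre + half, 0, 1)


def fit_ncm(
    cm: CountMatrix,
    detection_limit: float | None = None,
    kernel: str = "sampling",
) -> NCMFit:
    """Fit the Sloan neutral model to occurrence frequency vs. abundance.

    Regional abundance p is each OTU's mean relative abundance over all
    samples (zeros included); observed frequency is the fraction of samples
    where the OTU has at least one read.  The default ``sampling`` kernel
    models detection exactly (at least one read at the mean depth N);
    ``kernel="threshold"`` uses the classic Beta-CDF form with detection
    limit d (default 1/N).  Nm is found on a log grid and polished by
    bounded scalar minimisation; 95% bands are Wilson score intervals
    around the predicted frequency at the sample count.
    """
    if cm.n_samples < 5:
        raise DataError("need at least 5 samples")
    detected = cm.otu_sums() > 0
    if detected.sum() < 20:
        raise DataError("need at least 20 detected OTUs")
    sub = cm.select_otus(detected)
    n_samples = sub.n_samples
    ra = sub.counts / sub.sample_sums()
    p = ra.mean(axis=1)
    freq_obs = (sub.counts > 0).mean(axis=1)
    n_mean = float(sub.sample_sums().mean())
    d = 1.0 / n_mean if detection_limit is None else float(detection_limit)
    if np.ptp(freq_obs) == 0:
        raise DataError("degenerate frequency spectrum: all frequencies identical")
    if kernel not in ("sampling", "threshold"):
        raise DataError(f"unknown kernel {kernel!r}")
    sstot = float(((freq_obs - freq_obs.mean()) ** 2).sum())

    def predict(nm: float) -> np.ndarray:
        if kernel == "sampling":
            return _sampling_freq(p, nm, n_mean)
        return 1.0 - stats.beta.cdf(d, nm * p, nm * (1.0 - p))

    def ssres(log_nm: float) -> float:
        return float(((freq_obs - predict(np.exp(log_nm))) ** 2).sum())

    lo, hi = np.log(1e-2), np.log(1e9)
    for attempt in range(2):
        grid = np.linspace(lo, hi, 120)
        best = grid[int(np.argmin([ssres(g) for g in grid]))]
        span = (hi - lo) / 119
        res = optimize.minimize_scalar(ssres, bounds=(best - 2 * span, best + 2 * span),
                                       method="bounded")
        log_nm = float(res.x)
        at_bound = log_nm < lo + 1e-6 or log_nm > hi - 1e-6 or best in (grid[0], grid[-1])
        if not at_bound:
            break
        if attempt == 1:
            raise DataError("Nm optimiser stuck at the search bound")
        lo, hi = lo - np.log(100), hi + np.log(100)  # widen once
    nm = float(np.exp(log_nm))
    freq_pred = predict(nm)
    r2 = 1.0 - ssres(log_nm) / sstot
    ci_low, ci_high = _wilson_interval(freq_pred, n_samples)
    table = pd.DataFrame({
        "otu_id": sub.otu_ids,
        "p": p,
        "freq_obs": freq_obs,
        "freq_pred": freq_pred,
        "ci_low": ci_low,
        "ci_high": ci_high,
    })
    return NCMFit(nm, n_mean, nm / n_mean, float(r2), d, table)
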