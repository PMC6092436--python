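"""Dual-threshold classification of OTUs into abundant, rare and intermediate.

An OTU is *locally* abundant in a sample when its relative abundance there
is at least 1%, and locally rare when it is below 0.01% (absences count as
below threshold).  Its *regional* relative abundance is the mean of its
local relative abundances over all samples, zeros included.  Regional
thresholds default to the local ones divided by 10.

Classification combines the two scales:

* abundant — locally abundant in at least one sample AND regionally
  abundant (mean >= 0.1%);
* rare — locally rare in at least one sample AND regionally rare
  (mean < 0.001%);
* intermediate — everything else.

The rare clause reads "in at least one sample" rather than "in every
sample": with a regional mean below 0.001% an OTU is almost inevitably
below the 0.01% local threshold somewhere, and the subset that is locally
rare *everywhere* is tracked separately by :func:`local_status_profiles`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .otu_io import CountMatrix, DataError, RelAbundanceMatrix

ABUNDANT = "abundant"
RARE = "rare"
INTERMEDIATE = "intermediate"


@dataclass
class ThresholdConfig:
    """Relative-abundance cutoffs for the dual-threshold rule.

    ``regional_*`` thresholds are derived as ``local_* / regional_divisor``
    unless given explicitly.
    """

    local_abundant: float = 0.01
    local_rare: float = 0.0001
    regional_divisor: float = 10.0
    regional_abundant: float = field(default=None)  # type: ignore[assignment]
    regional_rare: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (0 < self.local_rare < self.local_abundant <= 1):
            raise ValueError("thresholds must satisfy 0 < local_rare < local_abundant <= 1")
        if self.regional_abundant is None:
            self.regional_abundant = self.local_abundant / self.regional_divisor
        if self.regional_rare is None:
            self.regional_rare = self.local_rare / self.regional_divisor
        if not self.regional_rare < self.regional_abundant:
            raise ValueError("regional_rare must be below regional_abundant")


@dataclass
class AbundanceClassification:
    """Per-OTU abundance labels plus the statistics behind them."""

    otu_ids: list[str]
    label: np.ndarray  # categorical strings
    regional_mean: np.ndarray
    max_local: np.ndarray
    n_local_abundant: np.ndarray
    n_local_rare: np.ndarray

    def otus_with_label(self, label: str) -> list[str]:
        return [o for o, l in zip(self.otu_ids, self.label) if l == label]

    def counts_by_label(self) -> dict[str, int]:
        return {lab: int((self.label == lab).sum()) for lab in (ABUNDANT, RARE, INTERMEDIATE)}


def classify_otus(ra: RelAbundanceMatrix, cfg: ThresholdConfig | None = None) -> AbundanceClassification:
    """Apply the combined local+regional thresholds to every OTU."""
    cfg = cfg or ThresholdConfig()
    x = ra.ra
    regional_mean = x.mean(axis=1)
    max_local = x.max(axis=1)
    n_local_abundant = (x >= cfg.local_abundant).sum(axis=1)
    n_local_rare = (x < cfg.local_rare).sum(axis=1)

    abundant = (max_local >= cfg.local_abundant) & (regional_mean >= cfg.regional_abundant)
    rare = (n_local_rare >= 1) & (regional_mean < cfg.regional_rare)
    label = np.full(len(ra.otu_ids), INTERMEDIATE, dtype=object)
    label[abundant] = ABUNDANT
    label[rare] = RARE
    return AbundanceClassification(
        list(ra.otu_ids), label, regional_mean, max_local,
        n_local_abundant.astype(int), n_local_rare.astype(int),
    )


def local_status_profiles(
    ra: RelAbundanceMatrix, cfg: ThresholdConfig | None = None
) -> tuple[set[str], set[str]]:
    """OTUs that are locally abundant in *every* sample, and locally rare in every sample."""
    cfg = cfg or ThresholdConfig()
    ids = np.asarray(ra.otu_ids, dtype=object)
    always_abundant = set(ids[(ra.ra >= cfg.local_abundant).all(axis=1)])
    always_rare = set(ids[(ra.ra < cfg.local_rare).all(axis=1)])
    return always_abundant, always_rare


def _pct(part: float, whole: float) -> float:
    """Percentage rounded half-up to two decimals (report convention)."""
    if whole == 0:
        return float("nan")
    return float(Decimal(100.0 * part / whole).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def partition_summary(
    cls: AbundanceClassification | Sequence[str], cm: CountMatrix
) -> pd.DataFrame:
    """Bookkeeping table: OTU and sequence counts and percentages per label.

    ``cls`` may be a full classification or a bare per-OTU label sequence
    aligned with ``cm.otu_ids``.
    """
    labels = np.asarray(cls.label if isinstance(cls, AbundanceClassification) else list(cls), dtype=object)
    if isinstance(cls, AbundanceClassification) and cls.otu_ids != cm.otu_ids:
        raise DataError("classification and count matrix OTU ids differ")
    if len(labels) != cm.n_otus:
        raise DataError("label vector length does not match count matrix")
    otu_total = cm.n_otus
    seq_total = cm.total()
    row_sums = cm.otu_sums()
    rows = []
    for lab in (ABUNDANT, RARE, INTERMEDIATE):
        mask = labels == lab
        n = int(mask.sum())
        seqs = int(row_sums[mask].sum())
        rows.append({
            "label": lab,
            "otu_n": n,
            "otu_pct": _pct(n, otu_total),
            "seq_n": seqs,
            "seq_pct": _pct(seqs, seq_total),
        })
    rows.append({"label": "all", "otu_n": otu_total, "otu_pct": 100.0,
                 "seq_n": seq_total, "seq_pct": 100.0})
    return pd.DataFrame(rows)


def abundance_occupancy(
    ra: RelAbundanceMatrix, subset: Sequence[str] | set[str] | None = None
) -> tuple[pd.DataFrame, float, float]:
    """Abundance-occupancy relationship for a set of OTUs.

    Returns a per-OTU frame (mean relative abundance, occupancy = fraction
    of samples with nonzero abundance) plus Spearman's rho and its p-value
    (exact permutation enumeration for n <= 8 OTUs, t approximation above).
    """
    ids = list(ra.otu_ids) if subset is None else [o for o in ra.otu_ids if o in set(subset)]
    if len(ids) < 3:
        raise DataError("too few OTUs for correlation")
    idx = [ra.otu_ids.index(o) for o in ids]
    mean_ra = ra.ra[idx].mean(axis=1)
    occupancy = (ra.ra[idx] > 0).mean(axis=1)
    frame = pd.DataFrame({"otu_id": ids, "mean_ra": mean_ra, "occupancy": occupancy})
    if np.ptp(mean_ra) == 0 or np.ptp(occupancy) == 0:
        raise DataError("zero-variance input: Spearman rho undefined")
    rho, p = _spearman(mean_ra, occupancy)
    return frame, rho, p


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 8:
        # exact: enumerate all pairings of the observed rank vectors
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        return rho, count / total
    t = rho * np.sqrt((n - 2) / max(1e-300, 1 - rho**2))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(1.0, p))


def rank_abundance_by_group(
    cm: CountMatrix, groups: Mapping[str, str], top_k: int = 100
) -> tuple[dict[str, list[str]], dict[tuple[str, str], int]]:
    """Top-``top_k`` OTUs per group and pairwise overlap counts.

    Within each group OTUs are ranked by summed relative abundance over the
    group's samples; ties break lexicographically by OTU id.
    """
    if top_k < 1:
        raise DataError("top_k must be >= 1")
    unmapped = [s for s in cm.sample_ids if s not in groups]
    if unmapped:
        raise DataError(f"unmapped sample(s): {unmapped}")
    ra = cm.counts / cm.sample_sums()
    levels = sorted(set(groups[s] for s in cm.sample_ids))
    ranked: dict[str, list[str]] = {}
    for g in levels:
        cols = [j for j, s in enumerate(cm.sample_ids) if groups[s] == g]
        score = ra[:, cols].sum(axis=1)
        order = sorted(range(cm.n_otus), key=lambda i: (-score[i], cm.otu_ids[i]))
        ranked[g] = [cm.otu_ids[i] for i in order[:top_k]]
    overlap = {
        (a, b): len(set(ranked[a]) & set(ranked[b]))
        for a, b in itertools.combinations(levels, 2)
    }
    return ranked, overlap


def shared_otu_counts(
    cm: CountMatrix, groups: Mapping[str, str], subset: Sequence[str] | set[str] | None = None
) -> dict[frozenset[str], int]:
    """Venn-region counts of OTU presence across 2-3 groups.

    An OTU is present in a group when its summed count over that group's
    samples is positive.  Keys are frozensets of group names; values over
    all regions sum to the number of subset OTUs detected anywhere.
    """
    unmapped = [s for s in cm.sample_ids if s not in groups]
    if unmapped:
        raise DataError(f"unmapped sample(s): {unmapped}")
    levels = sorted(set(groups[s] for s in cm.sample_ids))
    if not 2 <= len(levels) <= 3:
        raise DataError("Venn regions defined for 2-3 groups only")
    wanted = None if subset is None else set(subset)
    presence = {}
    for g in levels:
        cols = [j for j, s in enumerate(cm.sample_ids) if groups[s] == g]
        presence[g] = cm.counts[:, cols].sum(axis=1) > 0
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(levels) + 1):
        for combo in itertools.combinations(levels, r):
            inside = np.logical_and.reduce([presence[g] for g in combo])
            outside = np.logical_or.reduce(
                [presence[g] for g in levels if g not in combo] or [np.zeros(cm.n_otus, bool)]
            )
            mask = inside & ~outside
            if wanted is not None:
                mask &= np.array([o in wanted for o in cm.otu_ids])
            regions[frozenset(combo)] = int(mask.sum())
    return regions
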