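"""Reading, writing and resampling of OTU count tables and sample metadata.

The count table is the pipeline's universal currency: an integer matrix of
OTUs (rows) by samples (columns).  Tables arrive either as the classic
tab-separated wide layout (first column ``#OTU ID``, header row of sample
ids) or as BIOM (JSON 1.0 or HDF5 2.x, read-only).  Sample metadata carries
station coordinates, grouping factors (bay, water layer) and any subset of
the physico-chemical variables measured at each station.

Rarefaction to even depth is multivariate-hypergeometric (sampling reads
without replacement within each sample), which removes depth bias while
conserving the per-sample total exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("abundrare")

#: metadata columns that are not environmental variables
_META_COLUMNS = ("sample_id", "station", "bay", "layer", "latitude", "longitude")


class DataError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass
class CountMatrix:
    """Integer OTU x sample read-count table.

    Parameters
    ----------
    otu_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    counts : ndarray of int, shape (n_otus, n_samples)
        Non-negative read counts.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise DataError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise DataError("counts must be integer-valued")
            self.counts = as_int
        if (self.counts < 0).any():
            r, c = np.argwhere(self.counts < 0)[0]
            raise DataError(f"negative count at OTU {self.otu_ids[r]!r}, sample {self.sample_ids[c]!r}")
        _check_unique(self.otu_ids, "otu_id")
        _check_unique(self.sample_ids, "sample_id")
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise DataError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> np.ndarray:
        """Reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def otu_sums(self) -> np.ndarray:
        """Reads per OTU across all samples (row sums)."""
        return self.counts.sum(axis=1)

    def total(self) -> int:
        return int(self.counts.sum())

    def select_otus(self, keep: Sequence[str] | np.ndarray) -> "CountMatrix":
        """Subset rows; ``keep`` is a boolean mask or an iterable of OTU ids."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            mask = keep
        else:
            wanted = set(map(str, keep))
            mask = np.array([o in wanted for o in self.otu_ids])
        ids = [o for o, k in zip(self.otu_ids, mask) if k]
        return CountMatrix(ids, list(self.sample_ids), self.counts[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)


@dataclass
class RelAbundanceMatrix:
    """Per-sample relative abundances (columns sum to 1)."""

    otu_ids: list[str]
    sample_ids: list[str]
    ra: np.ndarray

    def __post_init__(self) -> None:
        self.ra = np.asarray(self.ra, dtype=float)
        if self.ra.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise DataError("ra shape does not match id lists")
        if (self.ra < 0).any() or (self.ra > 1).any():
            raise DataError("relative abundances must lie in [0, 1]")
        colsums = self.ra.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            bad = np.argmax(np.abs(colsums - 1.0))
            raise DataError(f"column {self.sample_ids[bad]!r} sums to {colsums[bad]}, not 1")

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class SampleTable:
    """Per-sample metadata: coordinates, grouping factors and environment.

    ``env`` holds only the physico-chemical columns present in the input
    (water temperature, salinity, pH, DO, nutrient concentrations, ...);
    missing values stay as NaN and are never silently zeroed.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        if "sample_id" not in f.columns:
            raise DataError("metadata requires a sample_id column")
        if f["sample_id"].duplicated().any():
            dup = f.loc[f["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise DataError(f"duplicate sample_id {dup!r}")
        for coord, lo, hi in (("latitude", -90, 90), ("longitude", -180, 180)):
            if coord in f.columns:
                vals = pd.to_numeric(f[coord], errors="coerce")
                bad = vals.isna() | (vals < lo) | (vals > hi)
                if bad.any():
                    sid = f.loc[bad, "sample_id"].iloc[0]
                    raise DataError(f"unparseable or out-of-range {coord} for sample {sid!r}")
                self.frame[coord] = vals
        self.frame = self.frame.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def env_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in _META_COLUMNS]

    def env(self, variables: Sequence[str] | None = None) -> pd.DataFrame:
        """Environmental variables as a samples x variables frame."""
        cols = list(variables) if variables is not None else self.env_columns
        missing = [c for c in cols if c not in self.frame.columns]
        if missing:
            raise DataError(f"environmental variable(s) not present: {missing}")
        return self.frame[cols].astype(float)

    def coordinates(self) -> pd.DataFrame:
        for c in ("latitude", "longitude"):
            if c not in self.frame.columns:
                raise DataError(f"metadata lacks {c}")
            if self.frame[c].isna().any():
                sid = self.frame.loc[self.frame[c].isna(), "sample_id"].iloc[0]
                raise DataError(f"missing coordinate for sample {sid!r}")
        return self.frame[["latitude", "longitude"]].astype(float)

    def groups(self, column: str = "bay") -> pd.Series:
        if column not in self.frame.columns:
            raise DataError(f"metadata lacks grouping column {column!r}")
        return self.frame[column]

    def align_to(self, sample_ids: Sequence[str]) -> "SampleTable":
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise DataError(f"metadata missing sample(s): {missing}")
        return SampleTable(self.frame.loc[list(sample_ids)].reset_index(drop=True))


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DataError(f"duplicate {what} {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, dialect: str = "tsv-wide") -> CountMatrix:
    """Read an OTU count table.

    ``dialect`` is ``"tsv-wide"`` (tab-separated, first column OTU ids,
    header row sample ids) or ``"biom"`` (BIOM 1.0 JSON or 2.x HDF5).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if dialect == "biom":
        return _read_biom(path)
    if dialect != "tsv-wide":
        raise DataError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, comment=None)
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise DataError("no data rows")
    otu_ids = df.iloc[:, 0].astype(str).tolist()
    sample_ids = [str(c) for c in df.columns[1:]]
    raw = df.iloc[:, 1:]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise DataError(f"non-numeric cell at OTU {otu_ids[r]!r}, sample {sample_ids[c]!r}")
    vals = numeric.to_numpy()
    if (vals < 0).any() or not np.array_equal(vals, np.floor(vals)):
        r, c = np.argwhere((vals < 0) | (vals != np.floor(vals)))[0]
        raise DataError(f"invalid count at OTU {otu_ids[r]!r}, sample {sample_ids[c]!r}")
    cm = CountMatrix(otu_ids, sample_ids, vals.astype(np.int64))
    logger.info("read count table %s: %d OTUs x %d samples, %d reads",
                path.name, cm.n_otus, cm.n_samples, cm.total())
    return cm


def _read_biom(path: Path) -> CountMatrix:
    with open(path, "rb") as fh:
        magic = fh.read(8)
    if magic.startswith(b"\x89HDF"):
        import h5py

        with h5py.File(path, "r") as h5:
            otu_ids = [i.decode() if isinstance(i, bytes) else str(i) for i in h5["observation/ids"][:]]
            sample_ids = [i.decode() if isinstance(i, bytes) else str(i) for i in h5["sample/ids"][:]]
            from scipy.sparse import csr_matrix

            grp = h5["observation/matrix"]
            mat = csr_matrix(
                (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
                shape=(len(otu_ids), len(sample_ids)),
            )
            counts = np.asarray(mat.todense())
        return CountMatrix(otu_ids, sample_ids, counts.astype(np.int64))
    doc = json.loads(path.read_text())
    otu_ids = [str(r["id"]) for r in doc["rows"]]
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    counts = np.zeros((len(otu_ids), len(sample_ids)))
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            counts[int(r), int(c)] = v
    else:
        counts = np.asarray(doc["data"], dtype=float)
    return CountMatrix(otu_ids, sample_ids, counts.astype(np.int64))


def write_count_table(cm: CountMatrix, path: str | Path) -> None:
    """Write the canonical tsv-wide dialect (UTF-8, Unix newlines)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#OTU ID\t" + "\t".join(cm.sample_ids) + "\n")
        for oid, row in zip(cm.otu_ids, cm.counts):
            fh.write(oid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_sample_metadata(path: str | Path) -> SampleTable:
    """Read sample metadata from CSV or TSV (delimiter sniffed)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    first = path.read_text().splitlines()[0] if path.read_text() else ""
    sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [str(c).strip() for c in df.columns]
    if "sample_id" not in df.columns:
        raise DataError("metadata requires a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    return SampleTable(df)


def write_sample_metadata(table: SampleTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def drop_singletons(cm: CountMatrix) -> CountMatrix:
    """Remove OTUs whose total count across all samples equals 1."""
    totals = cm.otu_sums()
    keep = totals != 1
    if not keep.any():
        logger.warning("all OTUs are singletons; returning empty table")
    return cm.select_otus(keep)


def rarefy_even_depth(
    cm: CountMatrix, depth: int, seed: int, prune_empty: bool = False
) -> CountMatrix:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each column is drawn from the multivariate hypergeometric distribution
    conditioned on its observed counts, so per-sample totals equal ``depth``
    exactly and the same ``seed`` reproduces the draw bit-for-bit.  Samples
    with fewer than ``depth`` reads are rejected, not padded.

    With ``prune_empty`` the OTU rows left with zero reads everywhere are
    dropped (the default keeps them so row indices stay aligned).
    """
    depth = int(depth)
    if depth <= 0:
        raise DataError("depth must be positive")
    sums = cm.sample_sums()
    low = sums < depth
    if low.any():
        bad = [s for s, b in zip(cm.sample_ids, low) if b]
        raise DataError(f"samples below depth {depth}: {bad}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(cm.counts)
    for j in range(cm.n_samples):
        out[:, j] = rng.multivariate_hypergeometric(cm.counts[:, j], depth, method="marginals")
    result = CountMatrix(list(cm.otu_ids), list(cm.sample_ids), out)
    if prune_empty:
        result = result.select_otus(result.otu_sums() > 0)
    return result


def relative_abundance(cm: CountMatrix) -> RelAbundanceMatrix:
    """Convert counts to within-sample fractions (columns sum to 1)."""
    sums = cm.sample_sums()
    if (sums == 0).any():
        bad = [s for s, t in zip(cm.sample_ids, sums) if t == 0]
        raise DataError(f"all-zero sample(s): {bad}")
    return RelAbundanceMatrix(list(cm.otu_ids), list(cm.sample_ids), cm.counts / sums)
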