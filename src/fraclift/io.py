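"""Data model and tabular I/O for size-fractionated OTU count data.

The central object is :class:`OtuTable`, an integer count matrix with OTUs
as rows and samples as columns — the single source of abundance truth for
every downstream statistic.  Sample metadata carries the experimental
design factors (size fraction, surfactin treatment, cultivation period,
replicate, algal-cell change); taxonomy maps OTUs to ranked lineage
labels.

All tables are read and written as plain UTF-8 TSV.  A BIOM-style dense
TSV dialect (leading ``#OTU ID`` header, optional ``# Constructed from
biom file`` comment line) is accepted for the count table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

FRACTIONS = ("FL", "PA")
TREATMENTS = ("control", "S0", "S0.5", "S1", "S2", "S3", "S4")
PERIODS = (0, 24, 48, 72, 96)

RANKS = ("phylum", "class", "order", "family", "genus")
UNCLASSIFIED = "Unclassified"


class FormatError(ValueError):
    """A file or table violates the expected format or an invariant."""


class ConfigError(ValueError):
    """An invalid configuration value."""


@dataclass(frozen=True)
class OtuTable:
    """Integer OTU × sample count matrix.

    Parameters
    ----------
    counts
        DataFrame with OTU identifiers as the index and sample identifiers
        as columns.  Entries must be non-negative integers; identifiers
        must be unique; every sample (column) must have depth > 0.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.shape[0] == 0 or c.shape[1] == 0:
            raise FormatError("empty OTU table")
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate OTU ids: {dup}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dup}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric entries in OTU table")
        if np.isnan(arr.astype(float)).any():
            raise FormatError("missing values in OTU table")
        if (arr < 0).any():
            raise FormatError("negative counts in OTU table")
        if not np.allclose(arr, np.round(arr.astype(float))):
            raise FormatError("non-integral counts in OTU table")
        if not np.issubdtype(arr.dtype, np.integer):
            object.__setattr__(self, "counts", c.astype(np.int64))
        depths = self.counts.sum(axis=0)
        empty = depths.index[depths == 0].tolist()
        if empty:
            raise FormatError(f"samples with zero depth: {empty}")

    @property
    def otu_ids(self) -> list:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.counts.columns.tolist()

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> pd.Series:
        """Per-sample read depth (column sums)."""
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Sequence) -> "OtuTable":
        """Restrict to the given samples (order preserved as given)."""
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return OtuTable(self.counts.loc[:, list(sample_ids)])

    def drop_absent_otus(self) -> "OtuTable":
        """Remove OTUs with zero reads in every retained sample."""
        keep = self.counts.sum(axis=1) > 0
        return OtuTable(self.counts.loc[keep])


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample relative abundances (each column sums to 1).

    Raises
    ------
    FormatError
        If any sample has zero depth (cannot happen for a validated
        :class:`OtuTable`, but guards raw DataFrames too).
    """
    counts = table.counts if isinstance(table, OtuTable) else table
    depths = counts.sum(axis=0)
    zero = depths.index[depths == 0].tolist()
    if zero:
        raise FormatError(f"zero-depth sample(s): {zero}")
    return counts / depths


def hellinger_transform(table: OtuTable) -> pd.DataFrame:
    """Square root of per-sample relative abundances.

    Each column's squared entries sum to 1; the transform damps the
    leverage of dominant taxa in downstream distance-based analyses.
    """
    return np.sqrt(relative_abundance(table))


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample design factors.

    ``data`` is indexed by sample id with columns ``fraction`` (FL/PA),
    ``treatment`` (control or S<dose>), ``dose`` (surfactin mg/L, 0 for
    control), ``period`` (hours), ``replicate`` (positive int) and
    ``algal_cell_change`` (cells/mL per 24 h; NaN where undefined, e.g.
    at 0 h).
    """

    data: pd.DataFrame

    REQUIRED = ("fraction", "treatment", "period", "replicate")

    def __post_init__(self) -> None:
        d = self.data
        if d.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")
        for col in self.REQUIRED:
            if col not in d.columns:
                raise FormatError(f"metadata missing column {col!r}")
        bad = set(d["fraction"]) - set(FRACTIONS)
        if bad:
            raise FormatError(f"unknown fraction labels: {sorted(bad)}")
        bad = set(d["treatment"]) - set(TREATMENTS)
        if bad:
            raise FormatError(f"unknown treatment labels: {sorted(bad)}")
        bad = set(int(p) for p in d["period"]) - set(PERIODS)
        if bad:
            raise FormatError(f"unknown cultivation periods: {sorted(bad)}")
        if (d["replicate"].astype(int) < 1).any():
            raise FormatError("replicate numbers must be >= 1")
        if "algal_cell_change" not in d.columns:
            self.data["algal_cell_change"] = np.nan
        if "dose" not in d.columns:
            self.data["dose"] = [dose_of(t) for t in d["treatment"]]

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    def for_samples(self, sample_ids: Sequence, subset: bool = False) -> pd.DataFrame:
        """Metadata rows aligned to ``sample_ids``.

        Strict by default: every requested sample must have exactly one
        metadata row.  With ``subset=True`` unmatched samples are dropped
        (opt-in subset mode).
        """
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing and not subset:
            raise FormatError(f"samples without metadata: {missing}")
        present = [s for s in sample_ids if s in self.data.index]
        return self.data.loc[present]


def dose_of(treatment: str) -> float:
    """Surfactin dose in mg/L implied by a treatment label (control -> 0)."""
    if treatment == "control":
        return 0.0
    if treatment.startswith("S"):
        try:
            return float(treatment[1:])
        except ValueError:
            pass
    raise FormatError(f"cannot parse dose from treatment {treatment!r}")


@dataclass(frozen=True)
class TaxonomyTable:
    """OTU → ranked lineage labels; missing ranks become ``Unclassified``."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        if d.index.has_duplicates:
            raise FormatError("duplicate OTU ids in taxonomy")
        for rank in RANKS:
            if rank not in d.columns:
                self.data[rank] = UNCLASSIFIED
        object.__setattr__(
            self, "data", self.data.fillna(UNCLASSIFIED).replace("", UNCLASSIFIED)
        )

    def lineage(self, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}; choose from {RANKS}")
        return self.data[rank]

    def check_against(self, table: OtuTable) -> None:
        extra = self.data.index.difference(table.counts.index).tolist()
        if extra:
            raise FormatError(f"taxonomy rows for unknown OTUs: {extra[:10]}")


# ---------------------------------------------------------------------------
# readers / writers


def read_otu_table(
    path: str | Path, dialect: str = "tsv", transpose: bool = False
) -> OtuTable:
    """Read an OTU count table from TSV.

    ``dialect`` is ``"tsv"`` (plain header row) or ``"biom-tsv"`` (dense
    BIOM export whose header starts with ``#OTU ID``; a leading
    ``# Constructed from biom file`` comment is tolerated).  The file is
    expected OTU-rows × sample-columns; pass ``transpose=True`` only if
    you know the file is sample-rows (no silent auto-detection).
    """
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif dialect == "biom-tsv":
        with open(path) as fh:
            first = fh.readline()
            skip = 1 if first.startswith("# Constructed") else 0
        df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
        df.index.name = "#OTU ID"
    else:
        raise ConfigError(f"unknown dialect {dialect!r}")
    if transpose:
        df = df.T
    try:
        return OtuTable(df)
    except FormatError:
        raise
    except (TypeError, ValueError) as exc:  # non-numeric payloads
        raise FormatError(str(exc)) from exc


def write_otu_table(table: OtuTable, path: str | Path, dialect: str = "tsv") -> None:
    df = table.counts
    if dialect == "biom-tsv":
        df = df.rename_axis("#OTU ID")
    elif dialect == "tsv":
        df = df.rename_axis("otu_id")
    else:
        raise ConfigError(f"unknown dialect {dialect!r}")
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.data.rename_axis("sample_id").to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return TaxonomyTable(df)


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    tax.data.rename_axis("otu_id").to_csv(path, sep="\t")


def load_config(path: str | Path) -> dict:
    """Load a YAML analysis config; every value is echoed to the log."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    for key, value in sorted(cfg.items()):
        logger.info("config %s = %r", key, value)
    return cfg


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to a common depth without replacement.

    Off by default throughout the package (the analyses operate on
    relative abundances); provided for depth-sensitive comparisons.
    Samples shallower than ``depth`` are dropped with a log message.
    """
    if depth < 1:
        raise ConfigError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    cols = {}
    for s in table.sample_ids:
        col = table.counts[s].to_numpy()
        total = int(col.sum())
        if total < depth:
            logger.warning("dropping sample %s (depth %d < %d)", s, total, depth)
            continue
        pool = np.repeat(np.arange(col.size), col)
        keep = rng.choice(pool, size=depth, replace=False)
        cols[s] = np.bincount(keep, minlength=col.size)
    if not cols:
        raise FormatError("no sample reaches the rarefaction depth")
    out = pd.DataFrame(cols, index=table.counts.index)
    return OtuTable(out)
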