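"""Abundant/rare classification and fold-change sensitive-OTU detection.

Two rule-based classifiers operating on per-sample relative abundances:

* ``classify_rarity`` — an OTU is *abundant* when it reaches the upper
  threshold (default 1 %) in at least one sample and never falls below
  the lower threshold (default 0.01 %) in any sample; it is *rare* when
  it falls below the lower threshold somewhere and never reaches the
  upper one; every other OTU is *intermediate*.
* ``detect_sensitive_otus`` — an OTU is *sensitive* when its mean
  relative abundance at one cultivation period differs from another
  period's by more than ``fold`` (default 10×, equivalently below 0.1×),
  assessed within each stratum of the design (fraction × treatment by
  default) and requiring detection (>0 reads) in at least two periods.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ConfigError, OtuTable, SampleMetadata, relative_abundance

#: pseudo-abundance guarding ratios against zero period means
EPSILON = 1e-6

LABELS = ("abundant", "rare", "intermediate")


def classify_rarity(
    table: OtuTable, upper: float = 0.01, lower: float = 1e-4
) -> pd.DataFrame:
    """Partition OTUs into abundant / rare / intermediate.

    Returns a DataFrame indexed by otu_id with columns ``label``,
    ``max_rel_abund`` and ``min_rel_abund`` (extrema over all samples).
    The three labels partition the OTU set: exactly one label per OTU.
    """
    if not (0 < lower < upper):
        raise ConfigError(f"need upper > lower > 0, got {upper} <= {lower}")
    rel = relative_abundance(table)
    mx = rel.max(axis=1)
    mn = rel.min(axis=1)
    abundant = (mx >= upper) & (mn >= lower)
    rare = (mn < lower) & (mx < upper)
    label = pd.Series("intermediate", index=rel.index, name="label")
    label[abundant] = "abundant"
    label[rare] = "rare"
    return pd.DataFrame(
        {"label": label, "max_rel_abund": mx, "min_rel_abund": mn}
    ).rename_axis("otu_id")


def period_mean_abundance(
    table: OtuTable,
    meta: SampleMetadata,
    stratify_by: Sequence[str] = ("fraction", "treatment"),
) -> pd.DataFrame:
    """Mean relative abundance per OTU × stratum × period (long format)."""
    rel = relative_abundance(table)
    design = meta.for_samples(table.sample_ids)
    long = (
        rel.rename_axis("otu_id")
        .reset_index()
        .melt(id_vars="otu_id", var_name="sample_id", value_name="rel_abund")
        .merge(
            design[list(stratify_by) + ["period"]],
            left_on="sample_id",
            right_index=True,
        )
    )
    keys = ["otu_id", *stratify_by, "period"]
    return long.groupby(keys, sort=True, observed=True)["rel_abund"].mean().reset_index()


def detect_sensitive_otus(
    table: OtuTable,
    meta: SampleMetadata,
    fold: float = 10.0,
    stratify_by: Sequence[str] = ("fraction", "treatment"),
    epsilon: float = EPSILON,
    min_periods_detected: int = 2,
) -> pd.DataFrame:
    """Flag OTUs whose period means change beyond ``fold`` within a stratum.

    For each OTU and stratum the largest pairwise ratio of period means
    (pseudo-abundance ``epsilon`` added to numerator and denominator) is
    compared against ``fold``; the maximum-ratio formulation covers the
    "more than 10×" and "less than 0.1×" directions symmetrically.
    Strata observed at fewer than two periods are skipped with a warning.

    Returns one row per OTU × stratum with columns ``max_ratio``,
    ``n_periods_detected`` and ``is_sensitive``.
    """
    if fold <= 1:
        raise ConfigError("fold must be > 1")
    means = period_mean_abundance(table, meta, stratify_by)
    strata = means[list(stratify_by)].drop_duplicates()
    records = []
    for _, stratum in strata.iterrows():
        mask = np.ones(len(means), dtype=bool)
        for col in stratify_by:
            mask &= means[col].to_numpy() == stratum[col]
        sub = means[mask]
        n_periods = sub["period"].nunique()
        if n_periods < 2:
            warnings.warn(
                f"stratum {dict(stratum)} observed at a single period; skipped",
                stacklevel=2,
            )
            continue
        wide = sub.pivot(index="otu_id", columns="period", values="rel_abund")
        m = wide.to_numpy()
        max_ratio = (m.max(axis=1) + epsilon) / (m.min(axis=1) + epsilon)
        detected = (m > 0).sum(axis=1)
        rec = pd.DataFrame(
            {
                "otu_id": wide.index,
                **{col: stratum[col] for col in stratify_by},
                "max_ratio": max_ratio,
                "n_periods_detected": detected,
                "is_sensitive": (max_ratio > fold)
                & (detected >= min_periods_detected),
            }
        )
        records.append(rec)
    if not records:
        raise ConfigError("no stratum with >= 2 cultivation periods")
    return pd.concat(records, ignore_index=True)


def sensitive_otu_ids(records: pd.DataFrame, **stratum_filter) -> list:
    """OTUs flagged sensitive in any stratum matching ``stratum_filter``.

    E.g. ``sensitive_otu_ids(records, fraction="PA")`` gives the
    PA-sensitive set (union over treatments).
    """
    mask = records["is_sensitive"].to_numpy(copy=True)
    for col, value in stratum_filter.items():
        mask &= records[col].to_numpy() == value
    return sorted(records.loc[mask, "otu_id"].unique().tolist())


def sensitive_heatmap_matrix(
    records: pd.DataFrame,
    table: OtuTable,
    meta: SampleMetadata,
    rarity: pd.DataFrame | None = None,
    epsilon: float = EPSILON,
) -> tuple[pd.DataFrame, pd.Series]:
    """log10 relative-abundance matrix of sensitive OTUs for heatmaps.

    Rows are the sensitive OTUs, columns the samples ordered by fraction,
    treatment, then period; entries are ``log10(rel_abund + epsilon)`` so
    absences floor at ``log10(epsilon)``.  The second return value labels
    each row abundant/rare/intermediate (all ``intermediate`` when no
    rarity table is supplied).
    """
    otus = sensitive_otu_ids(records)
    if not otus:
        raise ConfigError("no sensitive OTUs to plot")
    rel = relative_abundance(table)
    design = meta.for_samples(table.sample_ids)
    order = design.sort_values(["fraction", "treatment", "period"]).index
    matrix = np.log10(rel.loc[otus, order] + epsilon)
    if rarity is not None:
        labels = rarity.loc[otus, "label"].rename("rarity")
    else:
        labels = pd.Series("intermediate", index=pd.Index(otus), name="rarity")
    return matrix, labels
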