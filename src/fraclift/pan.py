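"""Particle-association niche (PAN) index.

The PAN index places each OTU on a continuum from a completely
free-living (FL, value 0) to a completely particle-attached (PA, value
1) lifestyle: it is the abundance-weighted mean of a 0/1 fraction
indicator over all samples in which the OTU occurs,

    pan_i = sum_s w_is * 1[fraction_s = PA] / sum_s w_is .

An OTU found only in PA samples scores 1, only in FL samples 0, and one
with identical relative abundance in every sample of a balanced design
scores 0.5.  Weights ``w_is`` default to per-sample relative abundances
so that sequencing depth does not tilt the mean toward deep samples; raw
counts are available for comparison.  Only OTUs with more than
``min_sequences`` total reads (default 10) are scored.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ConfigError, OtuTable, SampleMetadata, TaxonomyTable, relative_abundance


def pan_index(
    table: OtuTable,
    meta: SampleMetadata,
    min_sequences: int = 10,
    weight: str = "relative",
) -> pd.DataFrame:
    """Per-OTU PAN index.

    Returns a DataFrame indexed by otu_id with columns ``pan`` (in
    [0, 1]), ``total_sequences`` and ``n_samples_present``.  OTUs with
    ``total_sequences <= min_sequences`` or absent everywhere are
    omitted.  If the sample set lacks one fraction entirely the index
    degenerates to 0 or 1 for every OTU (a warning is emitted).
    """
    if min_sequences < 0:
        raise ConfigError("min_sequences must be >= 0")
    if weight not in ("relative", "raw"):
        raise ConfigError("weight must be 'relative' or 'raw'")
    design = meta.for_samples(table.sample_ids)
    is_pa = (design["fraction"] == "PA").to_numpy()
    if is_pa.all() or (~is_pa).all():
        warnings.warn(
            "samples cover a single size fraction; PAN degenerates to "
            f"{int(is_pa.all())} for every OTU",
            stacklevel=2,
        )
    w = relative_abundance(table) if weight == "relative" else table.counts.astype(float)
    w = w.to_numpy()
    totals = table.counts.sum(axis=1)
    keep = (totals > min_sequences).to_numpy() & (w.sum(axis=1) > 0)
    pan = w[keep][:, is_pa].sum(axis=1) / w[keep].sum(axis=1)
    present = (table.counts.to_numpy()[keep] > 0).sum(axis=1)
    return pd.DataFrame(
        {
            "pan": pan,
            "total_sequences": totals[keep].astype(int),
            "n_samples_present": present,
        },
        index=table.counts.index[keep],
    ).rename_axis("otu_id")


def pan_by_group(
    table: OtuTable,
    meta: SampleMetadata,
    group_by: Sequence[str],
    min_sequences: int = 10,
    weight: str = "relative",
) -> pd.DataFrame:
    """PAN index computed separately within each design group.

    ``group_by`` names metadata columns (e.g. ``["treatment"]`` or
    ``["treatment", "period"]``).  Returns a long DataFrame with the
    group columns, ``otu_id``, ``pan``, ``total_sequences`` and
    ``n_samples_present``; groups lacking samples are simply absent.
    """
    design = meta.for_samples(table.sample_ids)
    frames = []
    for key, sub in design.groupby(list(group_by), sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        subtable = table.subset_samples(sub.index.tolist())
        res = pan_index(subtable, meta, min_sequences=min_sequences, weight=weight)
        res = res.reset_index()
        for col, val in zip(group_by, key):
            res.insert(0, col, val)
        frames.append(res)
    if not frames:
        raise ConfigError("no groups found")
    return pd.concat(frames, ignore_index=True)


def taxon_pan_summary(
    results: pd.DataFrame,
    taxonomy: TaxonomyTable,
    rarity: pd.DataFrame | None = None,
    rank: str = "class",
    group_by: Sequence[str] = (),
) -> pd.DataFrame:
    """Mean ± standard error of member OTUs' PAN per taxon.

    ``results`` is the output of :func:`pan_index` (reset or indexed) or
    :func:`pan_by_group`.  Aggregation is per taxon at ``rank``, crossed
    with the rarity stratum when ``rarity`` labels are supplied and with
    any ``group_by`` columns present in ``results``.  Standard error is
    ``sd / sqrt(n)`` (ddof=1); singleton taxa get ``se_pan = 0``.
    """
    res = results.reset_index() if "otu_id" not in results.columns else results.copy()
    res["taxon"] = taxonomy.lineage(rank).reindex(res["otu_id"]).to_numpy()
    keys = [*group_by, "taxon"]
    if rarity is not None:
        res["rarity"] = rarity["label"].reindex(res["otu_id"]).to_numpy()
        keys.append("rarity")
    grouped = res.groupby(keys, sort=True, observed=True)["pan"]
    out = grouped.agg(mean_pan="mean", sd="std", n_otus="size").reset_index()
    out["se_pan"] = (out.pop("sd") / np.sqrt(out["n_otus"])).fillna(0.0)
    return out


def lifestyle_shift(
    results_by_group: pd.DataFrame,
    taxonomy: TaxonomyTable,
    rank: str = "class",
    group_col: str = "period",
) -> pd.DataFrame:
    """Trajectory of mean PAN per taxon across ordered groups.

    Summarizes :func:`pan_by_group` output: per taxon, the mean PAN at
    each level of ``group_col`` (ordered ascending), the change from the
    first level, and a least-squares slope whose sign classifies the
    taxon as shifting ``"toward PA"`` (increasing), ``"toward FL"``
    (decreasing) or ``"stable"`` (flat).
    """
    groups = sorted(results_by_group[group_col].unique())
    if len(groups) < 2:
        raise ConfigError("need at least two groups for a trajectory")
    summary = taxon_pan_summary(
        results_by_group, taxonomy, rank=rank, group_by=(group_col,)
    )
    wide = summary.pivot(index="taxon", columns=group_col, values="mean_pan")
    wide = wide.reindex(columns=groups)
    x = np.arange(len(groups), dtype=float)
    rows = []
    for taxon, y in wide.iterrows():
        yv = y.to_numpy(dtype=float)
        ok = ~np.isnan(yv)
        if ok.sum() >= 2:
            slope = float(np.polyfit(x[ok], yv[ok], 1)[0])
        else:
            slope = float("nan")
        first = yv[ok][0] if ok.any() else float("nan")
        if np.isnan(slope) or slope == 0:
            direction = "stable"
        else:
            direction = "toward PA" if slope > 0 else "toward FL"
        rows.append(
            {
                "taxon": taxon,
                **{f"mean_pan_{g}": yv[i] for i, g in enumerate(groups)},
                "delta_from_first": (yv[ok][-1] - first) if ok.sum() >= 2 else float("nan"),
                "slope": slope,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)
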