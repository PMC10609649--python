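"""Alpha diversity and the one-way ANOVA screen applied to it.

Per-sample indices: observed richness, Shannon–Wiener H (natural log by
default, base 2 for compatibility with older amplicon pipelines),
Simpson's index in both dominance (D = sum p_i^2) and diversity (1 − D)
forms, Pielou evenness H / log S, and the Chao1 richness estimator
(bias-corrected by default).  One-way ANOVA tests each design factor
against an index across samples; the continuous algal-cell-change
covariate enters after sign-binning into decline / stable / increase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ConfigError, OtuTable, SampleMetadata


def alpha_diversity(
    table: OtuTable, log_base: str = "e", bias_corrected: bool = True
) -> pd.DataFrame:
    """All alpha-diversity indices for every sample.

    Returns a DataFrame indexed by sample_id with columns
    ``otu_richness``, ``shannon``, ``simpson_d`` (dominance),
    ``simpson_diversity`` (1 − D), ``evenness`` and ``chao1``.  Evenness
    is undefined (NaN) for single-OTU samples.  Chao1 uses the
    bias-corrected form S + F1(F1−1)/(2(F2+1)) by default; the classic
    form S + F1²/(2 F2) is available (NaN when F2 = 0 and F1 > 0).
    """
    if log_base not in ("e", "2"):
        raise ConfigError("log_base must be 'e' or '2'")
    log = np.log if log_base == "e" else np.log2
    rows = {}
    for s in table.sample_ids:
        counts = table.counts[s].to_numpy()
        counts = counts[counts > 0]
        n = counts.sum()
        p = counts / n
        richness = counts.size
        shannon = float(-(p * log(p)).sum())
        simpson_d = float((p**2).sum())
        evenness = shannon / float(log(richness)) if richness > 1 else float("nan")
        f1 = int((counts == 1).sum())
        f2 = int((counts == 2).sum())
        if bias_corrected:
            chao1 = richness + f1 * (f1 - 1) / (2 * (f2 + 1))
        elif f2 > 0:
            chao1 = richness + f1**2 / (2 * f2)
        else:
            chao1 = richness if f1 == 0 else float("nan")
        rows[s] = {
            "otu_richness": richness,
            "shannon": shannon,
            "simpson_d": simpson_d,
            "simpson_diversity": 1.0 - simpson_d,
            "evenness": evenness,
            "chao1": float(chao1),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way ANOVA of one response against one factor."""

    response: str
    factor: str
    F: float
    p: float
    df_between: int
    df_within: int


def one_way_anova(
    values: Sequence[float],
    groups: Sequence,
    response: str = "value",
    factor: str = "group",
) -> AnovaResult:
    """Between/within sums-of-squares decomposition and the F test.

    Missing values are dropped pairwise.  When every observation is
    identical both sums of squares vanish; the statistic is reported as
    F = 0 with p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    levels = np.unique(groups)
    if levels.size < 2:
        raise ConfigError("one-way ANOVA needs at least two groups")
    n = values.size
    if n - levels.size < 1:
        raise ConfigError("no within-group degrees of freedom")
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for lv in levels:
        x = values[groups == lv]
        ss_between += x.size * (x.mean() - grand) ** 2
        ss_within += ((x - x.mean()) ** 2).sum()
    df_b = levels.size - 1
    df_w = n - levels.size
    if ss_within == 0.0:
        if ss_between == 0.0:
            F, p = 0.0, 1.0
        else:
            F, p = float("inf"), 0.0
    else:
        F = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(response, factor, float(F), p, df_b, df_w)


def bin_algal_change(delta: Sequence[float], stable_band: float = 0.0) -> np.ndarray:
    """Sign-bin the algal-cell-change covariate.

    Values within ``±stable_band`` are labelled ``stable``, below it
    ``decline``, above it ``increase``; NaN stays NaN (dropped by the
    ANOVA).  With the default band of 0 a noisy covariate effectively
    yields two groups, which is intended: the binning is purely
    sign-based.
    """
    delta = np.asarray(delta, dtype=float)
    out = np.full(delta.shape, None, dtype=object)
    out[delta < -stable_band] = "decline"
    out[np.abs(delta) <= stable_band] = "stable"
    out[delta > stable_band] = "increase"
    return out


#: factor name → metadata column, matching the conventional SF/CP/AC/SC screen
FACTOR_COLUMNS = {
    "SF": "fraction",
    "CP": "period",
    "AC": "algal_cell_change",
    "SC": "treatment",
}


def anova_screen(
    alpha: pd.DataFrame,
    meta: SampleMetadata,
    factors: Sequence[str] = ("SF", "CP", "AC", "SC"),
    indices: Sequence[str] = ("otu_richness", "chao1", "shannon", "simpson_d"),
    stable_band: float = 0.0,
) -> pd.DataFrame:
    """One-way ANOVA of each alpha index against each design factor.

    Factors: SF size fraction, CP cultivation period, AC algal-cell
    change (sign-binned), SC surfactin treatment.  Returns a long
    DataFrame of :class:`AnovaResult` fields.  Factor/index combinations
    that degenerate (a single observed level) are skipped.
    """
    design = meta.for_samples(alpha.index.tolist())
    rows = []
    for fac in factors:
        col = FACTOR_COLUMNS[fac]
        g = design[col].to_numpy()
        if fac == "AC":
            g = bin_algal_change(design[col], stable_band=stable_band)
        keep = pd.notna(g)
        for idx in indices:
            vals = alpha[idx].to_numpy()[keep]
            grp = g[keep]
            if np.unique(grp[~np.isnan(vals)]).size < 2:
                continue
            r = one_way_anova(vals, grp, response=idx, factor=fac)
            rows.append(r.__dict__)
    return pd.DataFrame(rows)
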