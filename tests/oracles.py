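"""Independent brute-force oracles used to verify the package.

Everything here is written as plain loops directly from the definitions,
deliberately sharing no code path with fraclift itself.
"""

from __future__ import annotations

import itertools

import numpy as np


def rarity_oracle(counts, upper, lower):
    """Per-OTU abundant/rare/intermediate labels by per-sample rule checks."""
    depths = {s: counts[s].sum() for s in counts.columns}
    labels = {}
    for otu in counts.index:
        reaches_upper = False
        below_lower = False
        always_ge_lower = True
        always_lt_upper = True
        for s in counts.columns:
            rel = counts.at[otu, s] / depths[s]
            if rel >= upper:
                reaches_upper = True
                always_lt_upper = False
            if rel < lower:
                below_lower = True
                always_ge_lower = False
        if reaches_upper and always_ge_lower:
            labels[otu] = "abundant"
        elif below_lower and always_lt_upper:
            labels[otu] = "rare"
        else:
            labels[otu] = "intermediate"
    return labels


def sensitive_oracle(counts, design, fold, eps=1e-6, stratify_by=("fraction", "treatment")):
    """(otu, stratum) -> (max pairwise ratio over period means, is_sensitive)."""
    depths = {s: counts[s].sum() for s in counts.columns}
    strata = sorted(
        {tuple(design.loc[s, c] for c in stratify_by) for s in counts.columns}
    )
    out = {}
    for stratum in strata:
        samples = [
            s
            for s in counts.columns
            if tuple(design.loc[s, c] for c in stratify_by) == stratum
        ]
        periods = sorted({design.loc[s, "period"] for s in samples})
        if len(periods) < 2:
            continue
        for otu in counts.index:
            means = {}
            for p in periods:
                vals = [
                    counts.at[otu, s] / depths[s]
                    for s in samples
                    if design.loc[s, "period"] == p
                ]
                means[p] = sum(vals) / len(vals)
            max_ratio = 0.0
            for p, q in itertools.permutations(periods, 2):
                ratio = (means[p] + eps) / (means[q] + eps)
                max_ratio = max(max_ratio, ratio)
            detected = sum(1 for p in periods if means[p] > 0)
            out[(otu, stratum)] = (max_ratio, max_ratio > fold and detected >= 2)
    return out


def pan_oracle(counts, fractions, min_sequences=10, weight="relative"):
    """Per-OTU abundance-weighted mean of the PA indicator, by loops."""
    depths = {s: counts[s].sum() for s in counts.columns}
    out = {}
    for otu in counts.index:
        total = sum(counts.at[otu, s] for s in counts.columns)
        if total <= min_sequences:
            continue
        num = 0.0
        den = 0.0
        for s in counts.columns:
            w = counts.at[otu, s] / depths[s] if weight == "relative" else counts.at[otu, s]
            den += w
            if fractions[s] == "PA":
                num += w
        if den > 0:
            out[otu] = num / den
    return out


def bray_curtis_oracle(x, y):
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


def average_ranks(values):
    """Average ranks (1-based) computed by explicit sorting, ties averaged."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def anosim_oracle(dmat, groups):
    """Clarke's R from first principles with hand-rolled average ranks."""
    n = len(groups)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    dists = [dmat[i][j] for i, j in pairs]
    ranks = average_ranks(dists)
    within = [ranks[k] for k, (i, j) in enumerate(pairs) if groups[i] == groups[j]]
    between = [ranks[k] for k, (i, j) in enumerate(pairs) if groups[i] != groups[j]]
    m = n * (n - 1) / 2
    return (np.mean(between) - np.mean(within)) / (m / 2)


def permanova_f_oracle(dmat, groups):
    """Pseudo-F via the Gower-centered inner-product matrix (trace form)."""
    d = np.asarray(dmat, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    levels = sorted(set(groups))
    k = len(levels)
    h = np.zeros((n, n))
    for lv in levels:
        idx = [i for i, gr in enumerate(groups) if gr == lv]
        for a in idx:
            for b in idx:
                h[a, b] = 1.0 / len(idx)
    ss_a = np.trace(h @ g @ h)
    ss_w = np.trace((np.eye(n) - h) @ g @ (np.eye(n) - h))
    return (ss_a / (k - 1)) / (ss_w / (n - k))


def shannon_oracle(counts, base=np.e):
    p = [c / sum(counts) for c in counts if c > 0]
    return -sum(pi * np.log(pi) / np.log(base) for pi in p)


def nmds_stress_reference(dmat, seed, n_init=8):
    """Best nonmetric stress-1 from scikit-learn's SMACOF implementation."""
    from sklearn.manifold import MDS

    mds = MDS(
        n_components=2,
        metric=False,
        dissimilarity="precomputed",
        n_init=n_init,
        max_iter=500,
        random_state=seed,
        normalized_stress=True,
    )
    mds.fit(np.asarray(dmat))
    return float(mds.stress_)
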