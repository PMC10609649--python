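"""Community-composition inference: Bray–Curtis, NMDS, PERMANOVA, ANOSIM.

All four pieces are implemented directly on top of numpy/scipy:

* :func:`bray_curtis` — the compositional dissimilarity
  d(a, b) = sum|x_a − x_b| / sum(x_a + x_b), in [0, 1] for non-negative
  profiles (Hellinger-transformed counts by default upstream).
* :func:`nmds` — non-metric multidimensional scaling minimizing Kruskal
  stress-1 by alternating monotone (isotonic) regression of the
  configuration distances on the dissimilarity order with a Guttman
  majorization update; best of ``n_restarts`` random starts plus a
  classical-scaling start.  Stress ≥ 0.20 is flagged as unreliable.
* :func:`permanova` — one-factor permutational multivariate ANOVA:
  pseudo-F from the among/within decomposition of squared distances
  (equivalently the Gower-centered inner-product matrix), R² =
  SS_among / SS_total, p from label permutations.
* :func:`anosim` — Clarke's rank-based R = (mean between-group rank −
  mean within-group rank) / (M/2) with the same permutation scheme.

Permutation p-values use (1 + #{stat_perm ≥ stat_obs}) / (1 + n_perm)
and are therefore floored at 1/(n_perm + 1); all randomness is driven by
an explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .io import ConfigError

#: stress above which a 2-D ordination is conventionally not interpreted
STRESS_THRESHOLD = 0.20


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    ids: tuple
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ConfigError("distance matrix must be square")
        if len(self.ids) != d.shape[0]:
            raise ConfigError("ids do not match matrix dimension")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ConfigError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ConfigError("distance matrix diagonal must be zero")
        if (d < -1e-12).any():
            raise ConfigError("negative dissimilarities")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.ids), columns=list(self.ids))


def bray_curtis(profiles: pd.DataFrame | np.ndarray) -> DistanceMatrix:
    """Bray–Curtis dissimilarities between sample columns.

    ``profiles`` holds one column per sample (rows are OTUs/features),
    with non-negative entries — relative abundances or their Hellinger
    transform.  A pair of all-zero samples has no defined dissimilarity
    and raises.
    """
    if isinstance(profiles, pd.DataFrame):
        ids = tuple(profiles.columns)
        x = profiles.to_numpy(dtype=float)
    else:
        x = np.asarray(profiles, dtype=float)
        ids = tuple(range(x.shape[1]))
    if (x < 0).any():
        raise ConfigError("negative entries in abundance profiles")
    xt = x.T  # samples × features
    num = np.abs(xt[:, None, :] - xt[None, :, :]).sum(axis=2)
    den = (xt[:, None, :] + xt[None, :, :]).sum(axis=2)
    if np.any((den == 0) & ~np.eye(len(ids), dtype=bool)):
        raise ConfigError("a pair of all-zero samples has undefined dissimilarity")
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# NMDS


@dataclass(frozen=True)
class NmdsResult:
    """A 2-D (or k-D) non-metric ordination."""

    coordinates: pd.DataFrame  # samples × axes, centered, principal axes
    stress: float  # Kruskal stress-1 of the best restart
    converged: bool
    n_restarts: int

    @property
    def reliable(self) -> bool:
        """Whether stress clears the conventional < 0.20 criterion."""
        return self.stress < STRESS_THRESHOLD


def _stress_and_disparities(delta_order: np.ndarray, d: np.ndarray):
    """Kruskal stress-1 and monotone disparities for one configuration.

    ``delta_order`` pre-sorts pairs by dissimilarity (primary approach:
    within dissimilarity ties, pairs are left free, approximated here by
    breaking ties on the current configuration distances).
    """
    dhat = np.empty_like(d)
    dhat[delta_order] = isotonic_regression(d[delta_order]).x
    ss_d = float((d**2).sum())
    if ss_d == 0:
        return 0.0, dhat
    stress = np.sqrt(((d - dhat) ** 2).sum() / ss_d)
    return float(stress), dhat


def _nmds_single(delta: np.ndarray, x0: np.ndarray, max_iter: int, tol: float):
    n, k = x0.shape
    x = x0 - x0.mean(axis=0)
    prev_stress = np.inf
    stress = np.inf
    converged = False
    for _ in range(max_iter):
        d = pdist(x)
        if (d == 0).any():  # coincident points: nudge off each other
            d = np.where(d == 0, 1e-12, d)
        order = np.lexsort((d, delta))
        stress, dhat = _stress_and_disparities(order, d)
        if abs(prev_stress - stress) < tol:
            converged = True
            break
        prev_stress = stress
        # Guttman transform with the disparities
        ratio = squareform(dhat / d, checks=False)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x = b @ x / n
        x -= x.mean(axis=0)
    return x, stress, converged


def _classical_scaling(dmat: np.ndarray, k: int) -> np.ndarray:
    n = dmat.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (dmat**2) @ j
    w, v = np.linalg.eigh(g)
    idx = np.argsort(w)[::-1][:k]
    lam = np.clip(w[idx], 0.0, None)
    return v[:, idx] * np.sqrt(lam)


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
) -> NmdsResult:
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    The first start is classical (metric) scaling of the dissimilarities;
    the remaining ``n_restarts - 1`` are random Gaussian configurations.
    The restart with the lowest final stress wins.  Coordinates are
    centered and rotated to principal axes (deterministic up to the sign
    convention that each axis's largest-magnitude loading is positive).
    """
    if seed is None:
        raise ConfigError("nmds requires an explicit seed")
    if d.n < 4:
        raise ConfigError("nmds needs at least 4 samples")
    if n_restarts < 1:
        raise ConfigError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    delta = d.condensed()
    best = (np.inf, None, False)
    for r in range(n_restarts):
        if r == 0:
            x0 = _classical_scaling(d.data, k)
            if not np.isfinite(x0).all() or np.allclose(x0, 0):
                x0 = rng.normal(size=(d.n, k))
        else:
            x0 = rng.normal(size=(d.n, k))
        x, stress, conv = _nmds_single(delta, x0, max_iter, tol)
        if stress < best[0]:
            best = (stress, x, conv)
    stress, x, converged = best
    # principal-axis rotation for reproducible orientation
    u, s, vt = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
    coords = u * s
    for a in range(coords.shape[1]):
        if coords[np.abs(coords[:, a]).argmax(), a] < 0:
            coords[:, a] = -coords[:, a]
    if stress >= STRESS_THRESHOLD:
        warnings.warn(
            f"NMDS stress {stress:.3f} >= {STRESS_THRESHOLD}: ordination "
            "should not be interpreted",
            stacklevel=2,
        )
    elif stress < 1e-3 and d.n > 4:
        # unconstrained disparities can shrink stress to ~0 by collapsing
        # strongly clustered data onto a few points (vegan warns likewise)
        warnings.warn(
            f"NMDS stress {stress:.2g} is (nearly) zero: solution may be "
            "perfect or degenerate (e.g. strongly clustered samples)",
            stacklevel=2,
        )
    frame = pd.DataFrame(
        coords, index=list(d.ids), columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return NmdsResult(frame, float(stress), bool(converged), n_restarts)


# ---------------------------------------------------------------------------
# permutation tests


@dataclass(frozen=True)
class PermutationTestResult:
    """Effect size, pseudo-statistic and permutation p-value."""

    method: str  # "PERMANOVA" or "ANOSIM"
    effect: float  # R^2 (PERMANOVA) or R (ANOSIM)
    statistic: float  # pseudo-F or R
    p: float
    n_permutations: int
    seed: int


def _check_groups(d: DistanceMatrix, groups) -> np.ndarray:
    groups = np.asarray(groups)
    if groups.size != d.n:
        raise ConfigError("one group label per sample required")
    levels, counts = np.unique(groups, return_counts=True)
    if levels.size < 2:
        raise ConfigError("need at least two groups")
    if (counts < 2).any():
        warnings.warn(
            f"groups with a single sample: "
            f"{levels[counts < 2].tolist()}; test may be unstable",
            stacklevel=3,
        )
    return groups


def _permanova_ss(d2: np.ndarray, groups: np.ndarray):
    """(SS_among, SS_within, SS_total) from squared distances."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for lv in np.unique(groups):
        idx = np.flatnonzero(groups == lv)
        if idx.size < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    return ss_total - ss_within, ss_within, ss_total


def permanova(
    d: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """One-factor PERMANOVA on a distance matrix.

    Pseudo-F = (SS_among / (k−1)) / (SS_within / (n−k)); R² =
    SS_among / SS_total; significance by permuting sample labels.
    """
    if seed is None:
        raise ConfigError("permanova requires an explicit seed")
    groups = _check_groups(d, groups)
    n = d.n
    k = np.unique(groups).size
    d2 = d.data**2
    ss_a, ss_w, ss_t = _permanova_ss(d2, groups)
    if ss_w <= 0:
        warnings.warn("zero within-group variation; pseudo-F is singular", stacklevel=2)
        f_obs = np.inf if ss_a > 0 else 0.0
    else:
        f_obs = (ss_a / (k - 1)) / (ss_w / (n - k))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(groups)
        pa, pw, _ = _permanova_ss(d2, perm)
        f_perm = np.inf if pw <= 0 and pa > 0 else (
            0.0 if pw <= 0 else (pa / (k - 1)) / (pw / (n - k))
        )
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    r2 = ss_a / ss_t if ss_t > 0 else 0.0
    return PermutationTestResult(
        "PERMANOVA", float(r2), float(f_obs), float(p), n_permutations, seed
    )


def _anosim_r(ranks: np.ndarray, within: np.ndarray, m: int) -> float:
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return float((rb - rw) / (m / 2.0))


def anosim(
    d: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """Clarke's analysis of similarities (the conventional "global R").

    Dissimilarities are rank-transformed once (average ranks for ties);
    R contrasts mean between- and within-group ranks, scaled by M/2 with
    M = n(n−1)/2, so R ∈ [−1, 1] and R ≈ 0 under exchangeable labels.
    """
    if seed is None:
        raise ConfigError("anosim requires an explicit seed")
    groups = _check_groups(d, groups)
    n = d.n
    m = n * (n - 1) // 2
    ranks = rankdata(d.condensed())
    iu, ju = np.triu_indices(n, 1)
    within = groups[iu] == groups[ju]
    if within.all() or not within.any():
        raise ConfigError("degenerate grouping for ANOSIM")
    r_obs = _anosim_r(ranks, within, m)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(groups)
        w = perm[iu] == perm[ju]
        if w.all() or not w.any():
            continue
        if _anosim_r(ranks, w, m) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return PermutationTestResult(
        "ANOSIM", float(r_obs), float(r_obs), float(p), n_permutations, seed
    )
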