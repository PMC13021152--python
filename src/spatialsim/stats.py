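"""Univariate spatial summary statistics and the permutation clustering test.

Three classical point-process summaries, each against its complete spatial
randomness (CSR) reference:

* Ripley's K(r) with translation edge correction; CSR reference pi r^2.
* Nearest-neighbour G(r) with the reduced-sample (border) correction; CSR
  reference 1 - exp(-lambda pi r^2) with lambda estimated as n / |W|.
* Pair correlation g(r), an Epanechnikov-kernel-smoothed pair-distance
  density with translation edge correction, normalized so the CSR reference
  is 1.  Undefined at r = 0.

Significance of clustering for a labelled cell table is assessed by a label
permutation test: the statistic on the positive cells is compared against its
distribution when the same number of positive labels is scattered uniformly
over all cell locations.  The "degree of clustering" is the observed curve
minus the permutation mean, and the one-sided add-one p-value
(1 + #{perm >= obs}) / (1 + n_perm) is never exactly zero.

All three estimators share one O(n^2) pair-distance core, used identically
for observed and permuted labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Window

__all__ = [
    "StatCurve",
    "PermutationResult",
    "ripleys_k",
    "nn_g",
    "pair_correlation",
    "permutation_test",
    "permutation_envelope",
    "nn_cooccurrence",
]

STAT_NAMES = ("K", "G", "g")


@dataclass
class StatCurve:
    """A spatial summary function estimate on a radius grid.

    ``theoretical`` is the CSR reference curve for the same radii.
    """

    radii: np.ndarray
    estimate: np.ndarray
    theoretical: np.ndarray

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.estimate = np.asarray(self.estimate, dtype=float)
        self.theoretical = np.asarray(self.theoretical, dtype=float)
        if not (self.radii.ndim == 1 and np.all(np.diff(self.radii) > 0)):
            raise ValueError("radii must be strictly increasing")
        if self.estimate.shape != self.radii.shape:
            raise ValueError("estimate must parallel radii")


@dataclass
class PermutationResult:
    """Observed statistic versus its label-permutation null, per radius."""

    stat: str
    radii: np.ndarray
    observed: np.ndarray
    null_mean: np.ndarray
    null_lo: np.ndarray
    null_hi: np.ndarray
    degree_of_clustering: np.ndarray
    p_value: np.ndarray
    n_perm: int
    n_positive: int
    evaluable: bool = True

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        """Boolean per radius: one-sided clustering p-value below alpha."""
        with np.errstate(invalid="ignore"):
            return self.p_value < alpha


# ---------------------------------------------------------------------------
# shared pair-distance core


def _validate_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    return pts


def _validate_radii(radii, window: Window | None = None, for_k: bool = False) -> np.ndarray:
    r = np.asarray(radii, dtype=float)
    if r.ndim != 1 or np.any(np.diff(r) <= 0) or np.any(r < 0):
        raise ValueError("radii must be a strictly increasing 1-d array of values >= 0")
    if for_k and window is not None:
        rmax = min(window.width, window.height) / 2.0
        if np.any(r > rmax + 1e-12):
            raise ValueError(f"radii must not exceed min window side / 2 = {rmax}")
    return r


class _PairData:
    """Pairwise distances, translation weights and border distances.

    Built once per point set; permutation subsets index into it.
    Diagonal entries carry d = +inf and w = 0 so self-pairs never count.
    """

    def __init__(self, pts: np.ndarray, window: Window):
        self.window = window
        self.n = pts.shape[0]
        dx = np.abs(pts[:, 0, None] - pts[None, :, 0])
        dy = np.abs(pts[:, 1, None] - pts[None, :, 1])
        self.d = np.hypot(dx, dy)
        # translation weights: |W| / overlap area of W with W shifted by the
        # pair separation; >= 1, equal to 1 only for coincident points
        overlap = (window.width - dx) * (window.height - dy)
        with np.errstate(divide="ignore"):
            self.w = window.area / overlap
        np.fill_diagonal(self.d, np.inf)
        np.fill_diagonal(self.w, 0.0)
        self.border = np.minimum.reduce([
            pts[:, 0] - window.xmin,
            window.xmax - pts[:, 0],
            pts[:, 1] - window.ymin,
            window.ymax - pts[:, 1],
        ])

    def subset(self, idx: np.ndarray) -> "_PairSubset":
        return _PairSubset(self, idx)


class _PairSubset:
    """Sorted pair distances for one index subset, ready for estimation."""

    def __init__(self, pairs: _PairData, idx: np.ndarray):
        sel = np.ix_(idx, idx)
        d = pairs.d[sel].ravel()
        w = pairs.w[sel].ravel()
        order = np.argsort(d, kind="stable")
        self.d_sorted = d[order]
        self.w_sorted = w[order]
        self.w_cumsum = np.cumsum(self.w_sorted)
        self.m = idx.size
        self.area = pairs.window.area
        # nearest-neighbour distance within the subset (diag is +inf)
        self.nnd = pairs.d[sel].min(axis=1) if idx.size else np.empty(0)
        self.border = pairs.border[idx]


def _k_from_subset(sub: _PairSubset, radii: np.ndarray) -> np.ndarray:
    m = sub.m
    if m < 2:
        return np.full(radii.shape, np.nan)
    hi = np.searchsorted(sub.d_sorted, radii, side="right")
    csum = np.concatenate([[0.0], sub.w_cumsum])
    return sub.area / (m * (m - 1)) * csum[hi]


def _g_nn_from_subset(sub: _PairSubset, radii: np.ndarray) -> np.ndarray:
    if sub.m < 2:
        return np.full(radii.shape, np.nan)
    keep = sub.border[:, None] > radii[None, :]
    denom = keep.sum(axis=0)
    num = ((sub.nnd[:, None] <= radii[None, :]) & keep).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, num / np.maximum(denom, 1), np.nan)


def _pcf_from_subset(sub: _PairSubset, radii: np.ndarray, half_width: float) -> np.ndarray:
    m = sub.m
    if m < 2:
        return np.full(radii.shape, np.nan)
    out = np.empty(radii.shape)
    h = half_width
    for j, r in enumerate(radii):
        if r <= 0:
            out[j] = np.nan
            continue
        lo = np.searchsorted(sub.d_sorted, r - h, side="left")
        hi = np.searchsorted(sub.d_sorted, r + h, side="right")
        t = (r - sub.d_sorted[lo:hi]) / h
        kern = 0.75 / h * (1.0 - t * t)
        total = float(kern @ sub.w_sorted[lo:hi])
        out[j] = total * sub.area / (2.0 * np.pi * r * m * (m - 1))
    return out


def _pcf_half_width(bandwidth, m: int, area: float) -> float:
    """Epanechnikov support half-width; "auto" is Stoyan's rule 0.15/sqrt(lambda)
    interpreted as the kernel standard deviation (half-width = sd * sqrt(5))."""
    if bandwidth == "auto":
        lam_hat = m / area
        bw = 0.15 / np.sqrt(lam_hat)
    else:
        bw = float(bandwidth)
        if bw <= 0:
            raise ValueError("bandwidth must be > 0")
    return bw * np.sqrt(5.0)


# ---------------------------------------------------------------------------
# public estimators


def ripleys_k(points, radii, window: Window) -> StatCurve:
    """Translation-corrected Ripley's K.

    K_hat(r) = |W| / (n (n-1)) * sum_{i != j} 1{d_ij <= r} w_ij with
    w_ij = |W| / ((W_x - |dx|)(W_y - |dy|)).  Under CSR, E K(r) = pi r^2.
    Fewer than two points yields an all-NaN curve.
    """
    pts = _validate_points(points)
    r = _validate_radii(radii, window, for_k=True)
    theo = np.pi * r**2
    if pts.shape[0] < 2:
        return StatCurve(r, np.full(r.shape, np.nan), theo)
    sub = _PairData(pts, window).subset(np.arange(pts.shape[0]))
    return StatCurve(r, _k_from_subset(sub, r), theo)


def nn_g(points, radii, window: Window) -> StatCurve:
    """Border-corrected nearest-neighbour distance distribution G.

    Among points farther than r from the window boundary, the fraction whose
    nearest neighbour lies within r.  CSR reference 1 - exp(-lambda pi r^2)
    with lambda = n / |W|.
    """
    pts = _validate_points(points)
    r = _validate_radii(radii)
    n = pts.shape[0]
    lam_hat = n / window.area
    theo = 1.0 - np.exp(-lam_hat * np.pi * r**2)
    if n < 2:
        return StatCurve(r, np.full(r.shape, np.nan), theo)
    sub = _PairData(pts, window).subset(np.arange(n))
    return StatCurve(r, _g_nn_from_subset(sub, r), theo)


def pair_correlation(points, radii, window: Window, bandwidth="auto") -> StatCurve:
    """Translation-corrected pair correlation function g.

    Kernel-smoothed density of pair distances normalized so the CSR
    expectation is 1; entries at r = 0 are reported missing.
    """
    pts = _validate_points(points)
    r = _validate_radii(radii)
    theo = np.ones(r.shape)
    n = pts.shape[0]
    if n < 2:
        return StatCurve(r, np.full(r.shape, np.nan), theo)
    h = _pcf_half_width(bandwidth, n, window.area)
    sub = _PairData(pts, window).subset(np.arange(n))
    return StatCurve(r, _pcf_from_subset(sub, r, h), theo)


_STAT_FUNCS = {"K": ripleys_k, "G": nn_g, "g": pair_correlation}


# ---------------------------------------------------------------------------
# permutation test


def _eval_stats(sub: _PairSubset, stats, radii, half_width) -> dict[str, np.ndarray]:
    out = {}
    for s in stats:
        if s == "K":
            out[s] = _k_from_subset(sub, radii)
        elif s == "G":
            out[s] = _g_nn_from_subset(sub, radii)
        elif s == "g":
            out[s] = _pcf_from_subset(sub, radii, half_width)
        else:
            raise ValueError(f"unknown statistic {s!r}; expected K, G or g")
    return out


def permutation_test(
    points,
    positive,
    window: Window,
    radii,
    stats=STAT_NAMES,
    n_perm: int = 100,
    rng: np.random.Generator | int | None = None,
    bandwidth="auto",
) -> dict[str, PermutationResult]:
    """Label-permutation clustering test for one sample, all statistics at once.

    Parameters
    ----------
    points : (n, 2) array
        Locations of every cell in the sample.
    positive : (n,) boolean or 0/1 array
        Which cells carry the phenotype under test.
    stats : iterable of {"K", "G", "g"}
        Statistics to evaluate; one shared set of permutations serves all.
    n_perm : int
        Number of label permutations; each scatters the same number of
        positive labels uniformly over all cell locations.

    Notes
    -----
    The positive count is identical in every permutation, so the test is
    conditional on abundance.  Samples with fewer than two positive cells are
    returned with ``evaluable=False`` and all-NaN curves.
    """
    pts = _validate_points(points)
    pos = np.asarray(positive).astype(bool)
    if pos.shape != (pts.shape[0],):
        raise ValueError("positive must be a length-n label array")
    r = _validate_radii(radii, window, for_k="K" in stats)
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    stats = tuple(stats)
    n = pts.shape[0]
    m = int(pos.sum())
    if m < 2:
        nanr = np.full(r.shape, np.nan)
        return {
            s: PermutationResult(s, r, nanr.copy(), nanr.copy(), nanr.copy(),
                                 nanr.copy(), nanr.copy(), nanr.copy(),
                                 n_perm, m, evaluable=False)
            for s in stats
        }
    pairs = _PairData(pts, window)
    half_width = _pcf_half_width(bandwidth, m, window.area)

    observed = _eval_stats(pairs.subset(np.flatnonzero(pos)), stats, r, half_width)
    null = {s: np.empty((n_perm, r.size)) for s in stats}
    for p in range(n_perm):
        idx = rng.choice(n, size=m, replace=False)
        vals = _eval_stats(pairs.subset(idx), stats, r, half_width)
        for s in stats:
            null[s][p] = vals[s]

    results = {}
    for s in stats:
        obs = observed[s]
        perm = null[s]
        with np.errstate(invalid="ignore"):
            valid = np.isfinite(perm)
            n_valid = valid.sum(axis=0)
            ge = np.nansum((perm >= obs[None, :]) & valid, axis=0)
            p_value = np.where(
                np.isfinite(obs) & (n_valid > 0),
                (1.0 + ge) / (1.0 + n_valid),
                np.nan,
            )
            null_mean = np.nanmean(np.where(valid, perm, np.nan), axis=0)
            null_lo = np.nanpercentile(np.where(valid, perm, np.nan), 2.5, axis=0)
            null_hi = np.nanpercentile(np.where(valid, perm, np.nan), 97.5, axis=0)
        results[s] = PermutationResult(
            stat=s, radii=r, observed=obs,
            null_mean=null_mean, null_lo=null_lo, null_hi=null_hi,
            degree_of_clustering=obs - null_mean,
            p_value=p_value, n_perm=n_perm, n_positive=m,
        )
    return results


def permutation_envelope(
    table: pd.DataFrame,
    marker_column: str,
    stat: str,
    radii,
    window: Window,
    n_perm: int = 100,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    bandwidth="auto",
) -> PermutationResult:
    """Permutation clustering test for one statistic on an exported cell table.

    ``table`` needs ``x``/``y`` columns and a binary ``marker_column``;
    significance at a radius means the one-sided p-value is below ``alpha``
    (query via ``result.significant(alpha)``).
    """
    if marker_column not in table.columns:
        raise ValueError(f"marker column {marker_column!r} not in table")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    pts = table[["x", "y"]].to_numpy(dtype=float)
    pos = table[marker_column].to_numpy()
    res = permutation_test(pts, pos, window, radii, stats=(stat,),
                           n_perm=n_perm, rng=rng, bandwidth=bandwidth)
    return res[stat]


def nn_cooccurrence(points_a, points_b, radius: float) -> float:
    """Fraction of type-a cells with a type-b cell within ``radius``.

    A simple bivariate nearest-neighbour co-occurrence index used to gauge
    colocalization between two phenotypes; NaN when either set is empty.
    """
    a = _validate_points(points_a)
    b = _validate_points(points_b)
    if a.shape[0] == 0 or b.shape[0] == 0:
        return float("nan")
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    nn = np.sqrt(d2.min(axis=1))
    return float((nn <= radius).mean())
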