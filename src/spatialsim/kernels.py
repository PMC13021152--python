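"""Gaussian-kernel probability surfaces.

A surface is a set of isotropic Gaussian bumps, each with unit peak; the raw
field at a point is the pointwise MAX over bumps, which lies in [0, 1] with
the supremum 1 attained exactly at every kernel centre.  An affine map then
rescales [0, 1] onto [prob_min, prob_max], so the bounds are exact by
construction rather than empirical, and overlapping clusters can never push a
probability above prob_max.  (Combining by max rather than sum is the one
place this implementation fixes a rule the surface description leaves open.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Window

__all__ = [
    "GaussianKernel",
    "KernelSet",
    "sample_kernels",
    "evaluate_surface",
    "shift_kernels",
    "density_grid",
]


@dataclass(frozen=True)
class GaussianKernel:
    """Isotropic Gaussian bump with unit peak at (x0, y0) and bandwidth sd."""

    x0: float
    y0: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("kernel sd must be > 0")


@dataclass(frozen=True)
class KernelSet:
    """A probability surface: kernels plus the [prob_min, prob_max] scaling."""

    kernels: tuple[GaussianKernel, ...]
    prob_min: float
    prob_max: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "kernels", tuple(self.kernels))
        if not (0.0 <= self.prob_min <= self.prob_max <= 1.0):
            raise ValueError(
                f"need 0 <= prob_min <= prob_max <= 1, got "
                f"({self.prob_min}, {self.prob_max})"
            )

    @property
    def k(self) -> int:
        return len(self.kernels)

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        return evaluate_surface(self, points)


def _validate_prob_range(prob_range) -> tuple[float, float]:
    lo, hi = float(prob_range[0]), float(prob_range[1])
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"prob_range must be ordered within [0, 1], got ({lo}, {hi})")
    return lo, hi


def sample_kernels(
    k: int,
    window: Window,
    sdmin: float,
    sdmax: float,
    prob_range: tuple[float, float],
    rng: np.random.Generator,
) -> KernelSet:
    """Draw ``k`` kernels with uniform centres and sd ~ Uniform(sdmin, sdmax).

    ``k = 0`` is allowed and yields a constant surface at ``prob_min``.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if not (0 < sdmin <= sdmax):
        raise ValueError(f"need 0 < sdmin <= sdmax, got ({sdmin}, {sdmax})")
    lo, hi = _validate_prob_range(prob_range)
    kernels = []
    for _ in range(k):
        x0 = rng.uniform(window.xmin, window.xmax)
        y0 = rng.uniform(window.ymin, window.ymax)
        sd = rng.uniform(sdmin, sdmax)
        kernels.append(GaussianKernel(x0, y0, sd))
    return KernelSet(tuple(kernels), lo, hi)


def evaluate_surface(kset: KernelSet, points: np.ndarray) -> np.ndarray:
    """Evaluate the scaled probability surface at an (n, 2) array of points.

    p(x, y) = prob_min + (prob_max - prob_min) * max_j exp(-d_j^2 / (2 sd_j^2))
    where d_j is the distance to kernel j's centre.  With no kernels the
    surface is constant at prob_min.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[-1] != 2:
        raise ValueError("points must be an (n, 2) array of x, y coordinates")
    if kset.k == 0:
        return np.full(pts.shape[0], kset.prob_min)
    s = np.zeros(pts.shape[0])
    for ker in kset.kernels:
        d2 = (pts[:, 0] - ker.x0) ** 2 + (pts[:, 1] - ker.y0) ** 2
        np.maximum(s, np.exp(-d2 / (2.0 * ker.sd**2)), out=s)
    return kset.prob_min + (kset.prob_max - kset.prob_min) * s


def shift_kernels(
    kset: KernelSet,
    shift: float,
    window: Window,
    rng: np.random.Generator,
) -> KernelSet:
    """Translate each kernel centre to decouple a second cell type's surface.

    Every centre moves by a displacement of magnitude ``shift * width / 2`` in
    an independently drawn uniform random direction, then wraps torus-style
    back into the window.  ``shift=0`` shares the surface exactly (centres are
    returned bit-identical); ``shift=1`` displaces by half the domain width —
    far beyond typical cluster bandwidths, destroying colocalization.
    """
    if not (0.0 <= shift <= 1.0):
        raise ValueError(f"shift must lie in [0, 1], got {shift}")
    if shift == 0.0:
        return KernelSet(kset.kernels, kset.prob_min, kset.prob_max)
    mag = shift * window.width / 2.0
    moved = []
    for ker in kset.kernels:
        theta = rng.uniform(0.0, 2.0 * np.pi)
        x = ker.x0 + mag * np.cos(theta)
        y = ker.y0 + mag * np.sin(theta)
        # torus wrap into the window
        x = window.xmin + (x - window.xmin) % window.width
        y = window.ymin + (y - window.ymin) % window.height
        moved.append(GaussianKernel(x, y, ker.sd))
    return KernelSet(tuple(moved), kset.prob_min, kset.prob_max)


def density_grid(
    kset: KernelSet,
    window: Window,
    resolution: int,
) -> np.ndarray:
    """Probability surface on a resolution x resolution grid of cell centres.

    Returns a structured view for export: an (resolution**2, 3) array of
    (x, y, probability) rows, evaluated with the same code path as
    :func:`evaluate_surface` so the two agree exactly on grid nodes.
    Row-major over y then x (y varies slowest).
    """
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    dx = window.width / resolution
    dy = window.height / resolution
    xc = window.xmin + dx * (np.arange(resolution) + 0.5)
    yc = window.ymin + dy * (np.arange(resolution) + 0.5)
    yy, xx = np.meshgrid(yc, xc, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    p = evaluate_surface(kset, pts)
    return np.column_stack([pts, p])
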