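"""Simulation state and homogeneous Poisson point-pattern generation.

The simulation is built stepwise: first a point pattern per sample (every
point a prospective cell), then probability surfaces assign tissue
compartments, holes and phenotype positivity on top of it.  ``SimObject``
accumulates all of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream

__all__ = [
    "Window",
    "PointPattern",
    "SimObject",
    "create_simulation_object",
    "generate_spatial_pattern",
]


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular observation window.

    Coordinates are in arbitrary spatial units (the same units as kernel
    bandwidths and statistic radii).
    """

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(
                f"degenerate window: need xmax > xmin and ymax > ymin, got "
                f"({self.xmin}, {self.xmax}) x ({self.ymin}, {self.ymax})"
            )

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Inclusive-bounds membership test."""
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        return (
            (xs >= self.xmin)
            & (xs <= self.xmax)
            & (ys >= self.ymin)
            & (ys <= self.ymax)
        )


@dataclass
class PointPattern:
    """One sample's point locations inside a window."""

    sample_id: int
    xs: np.ndarray
    ys: np.ndarray
    window: Window

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        if self.sample_id < 1:
            raise ValueError("sample_id must be >= 1")
        if self.xs.shape != self.ys.shape or self.xs.ndim != 1:
            raise ValueError("xs and ys must be parallel 1-d arrays")
        if not np.all(self.window.contains(self.xs, self.ys)):
            raise ValueError("all points must lie inside the window")

    def __len__(self) -> int:
        return self.xs.size

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array."""
        return np.column_stack([self.xs, self.ys])


@dataclass
class SimObject:
    """Accumulating simulation state for one scenario.

    Holds the window, the number of independent samples (``n_sims``), the
    number of cell phenotypes to simulate, and — as the pipeline stages run —
    the point patterns, the kernel sets behind each probability surface, and
    the per-cell assignments.  One cell type benchmarks clustering; two or
    more benchmark colocalization.
    """

    window: Window
    n_sims: int
    n_cell_types: int = 1
    seed: int = 0
    lam: float | None = None
    patterns: list[PointPattern] | None = None
    # per-sample kernel sets (surfaces), filled by the assignment stages
    tissue_kernels: list = field(default=None, repr=False)
    hole_kernels: list = field(default=None, repr=False)
    cell_kernels: list = field(default=None, repr=False)  # [sample][cell_type]
    # per-sample assignment arrays
    tissue: list | None = field(default=None, repr=False)  # str arrays
    holes: list | None = field(default=None, repr=False)  # bool arrays
    positivity: list | None = field(default=None, repr=False)  # (n, n_types) int
    marker_values: list | None = field(default=None, repr=False)  # (n, n_types) float
    drop_holes: bool = False

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be a positive integer")
        if self.n_cell_types < 1:
            raise ValueError("n_cell_types must be a positive integer")

    def require_patterns(self) -> list[PointPattern]:
        if self.patterns is None:
            raise RuntimeError(
                "no point patterns yet: call generate_spatial_pattern() first"
            )
        return self.patterns


def create_simulation_object(
    n_sims: int,
    window: Window,
    n_cell_types: int = 1,
    seed: int = 0,
) -> SimObject:
    """Create the empty simulation state for a scenario.

    Parameters
    ----------
    n_sims : int
        Number of independent samples (tissue cores) to simulate.
    window : Window
        Rectangular simulation window shared by all samples.
    n_cell_types : int
        Number of phenotypes whose positivity will be simulated.
    seed : int
        Master seed; every stage and sample derives its own substream.
    """
    if not isinstance(window, Window):
        window = Window(*window)
    return SimObject(window=window, n_sims=int(n_sims),
                     n_cell_types=int(n_cell_types), seed=int(seed))


def generate_spatial_pattern(
    obj: SimObject,
    lam: float,
    seed: int | None = None,
    overwrite: bool = False,
) -> SimObject:
    """Draw a homogeneous Poisson point pattern for every sample.

    Each sample's point count is Poisson(lam * window area) and point
    locations are independent uniforms over the window, so the patterns are
    complete spatial randomness (CSR) before any labelling.

    Parameters
    ----------
    lam : float
        Intensity in points (cells) per unit area.
    seed : int, optional
        Overrides the object's master seed for this and later stages.
    overwrite : bool
        Allow regeneration over existing patterns.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if obj.patterns is not None and not overwrite:
        raise RuntimeError(
            "patterns already generated; pass overwrite=True to regenerate"
        )
    if seed is not None:
        obj.seed = int(seed)
    w = obj.window
    mean_count = lam * w.area
    patterns = []
    for i in range(obj.n_sims):
        rng = substream(obj.seed, "pattern", i)
        n = rng.poisson(mean_count)
        xs = rng.uniform(w.xmin, w.xmax, size=n)
        ys = rng.uniform(w.ymin, w.ymax, size=n)
        patterns.append(PointPattern(sample_id=i + 1, xs=xs, ys=ys, window=w))
    obj.patterns = patterns
    obj.lam = float(lam)
    return obj
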