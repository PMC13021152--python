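"""Label assignment stages: tissue compartments, holes, phenotype positivity,
and continuous marker values.

Every stage follows the same mechanism: sample a fresh kernel surface per
sample, evaluate the surface probability at each cell, and draw an
independent Bernoulli label per cell.  Tissue assignment is therefore
stochastic rather than a hard threshold — low-probability regions are only
*likely* to become "Tissue 2" — mirroring the positivity mechanism.  The
tissue, hole and phenotype surfaces are sampled independently of each other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .core import SimObject
from .kernels import KernelSet, sample_kernels, shift_kernels

__all__ = [
    "DistributionSpec",
    "assign_tissue",
    "assign_holes",
    "assign_cell_positivity",
    "assign_continuous",
]

TISSUE_POSITIVE = "Tissue 1"
TISSUE_NEGATIVE = "Tissue 2"

# Module defaults for the auxiliary surfaces.  Tissue compartments are broad
# relative to a 2x2 window (few kernels, large bandwidth); holes are a single
# localized non-cellular gap (necrosis, tissue fold).
TISSUE_DEFAULTS = dict(k=2, sdmin=0.5, sdmax=1.0, prob_range=(0.2, 0.8))
HOLE_DEFAULTS = dict(k=1, sdmin=0.2, sdmax=0.4, prob_range=(0.1, 0.3))


@dataclass(frozen=True)
class DistributionSpec:
    """Gaussian marker-value model conditional on positivity.

    Units are arbitrary (fluorescence intensity, expression).  There are no
    default parameters: the positive/negative separation is the experimental
    condition under study and must be stated explicitly.
    """

    mean_pos: float
    sd_pos: float
    mean_neg: float
    sd_neg: float
    family: str = "normal"

    def __post_init__(self) -> None:
        if self.family != "normal":
            raise ValueError("only the normal family is supported")
        if self.sd_pos < 0 or self.sd_neg < 0:
            raise ValueError("standard deviations must be >= 0")


def _bernoulli_stage(
    obj: SimObject,
    stage: str,
    k: int,
    sdmin: float,
    sdmax: float,
    prob_range,
):
    """Shared surface-then-Bernoulli machinery for tissue and holes."""
    patterns = obj.require_patterns()
    ksets, labels = [], []
    for i, pat in enumerate(patterns):
        rng = substream(obj.seed, stage, i)
        kset = sample_kernels(k, obj.window, sdmin, sdmax, prob_range, rng)
        p = kset.evaluate(pat.xy) if len(pat) else np.empty(0)
        u = rng.uniform(size=len(pat))
        ksets.append(kset)
        labels.append(u < p)
    return ksets, labels


def assign_tissue(
    obj: SimObject,
    k: int = TISSUE_DEFAULTS["k"],
    sdmin: float = TISSUE_DEFAULTS["sdmin"],
    sdmax: float = TISSUE_DEFAULTS["sdmax"],
    prob_range=TISSUE_DEFAULTS["prob_range"],
) -> SimObject:
    """Assign each cell to "Tissue 1" or "Tissue 2" via a fresh surface.

    High-probability regions of the sampled surface tend to "Tissue 1";
    low-probability regions tend to "Tissue 2".
    """
    ksets, flags = _bernoulli_stage(obj, "tissue", k, sdmin, sdmax, prob_range)
    obj.tissue_kernels = ksets
    obj.tissue = [
        np.where(f, TISSUE_POSITIVE, TISSUE_NEGATIVE) for f in flags
    ]
    return obj


def assign_holes(
    obj: SimObject,
    k: int = HOLE_DEFAULTS["k"],
    sdmin: float = HOLE_DEFAULTS["sdmin"],
    sdmax: float = HOLE_DEFAULTS["sdmax"],
    prob_range=HOLE_DEFAULTS["prob_range"],
    drop: bool = False,
) -> SimObject:
    """Flag cells falling in non-cellular "hole" regions.

    Holes model violations of stationarity (necrotic regions, tissue folds).
    With ``drop=True`` flagged cells are excluded from exported tables; the
    default keeps them as a flag so downstream tools decide.
    """
    ksets, flags = _bernoulli_stage(obj, "holes", k, sdmin, sdmax, prob_range)
    obj.hole_kernels = ksets
    obj.holes = [np.asarray(f, dtype=bool) for f in flags]
    obj.drop_holes = bool(drop)
    return obj


def assign_cell_positivity(
    obj: SimObject,
    k: int = 5,
    sdmin: float = 0.1,
    sdmax: float = 0.3,
    prob_range=(0.01, 0.75),
    shift: float = 0.0,
) -> SimObject:
    """Draw phenotype positivity for every cell type from kernel surfaces.

    Cell type 1 gets a freshly sampled kernel set per sample; each further
    type t reuses type t-1's kernels translated by :func:`shift_kernels`, so
    ``shift=0`` makes all types share one surface (maximal colocalization)
    and ``shift=1`` decouples them.  Positivity is an independent Bernoulli
    draw per cell and type from that type's surface value at the cell.

    Defaults are a five-cluster, tight-bandwidth, high-abundance scenario in
    a window of width 2.
    """
    patterns = obj.require_patterns()
    if obj.n_cell_types == 1 and shift != 0.0:
        warnings.warn("shift has no effect with a single cell type; ignored",
                      stacklevel=2)
        shift = 0.0
    elif not (0.0 <= shift <= 1.0):
        raise ValueError(f"shift must lie in [0, 1], got {shift}")
    all_ksets, all_pos = [], []
    for i, pat in enumerate(patterns):
        rng = substream(obj.seed, "cells", i)
        ksets: list[KernelSet] = []
        pos = np.zeros((len(pat), obj.n_cell_types), dtype=np.int8)
        for t in range(obj.n_cell_types):
            if t == 0:
                kset = sample_kernels(k, obj.window, sdmin, sdmax, prob_range, rng)
            else:
                kset = shift_kernels(ksets[t - 1], shift, obj.window, rng)
            p = kset.evaluate(pat.xy) if len(pat) else np.empty(0)
            pos[:, t] = rng.uniform(size=len(pat)) < p
            ksets.append(kset)
        all_ksets.append(ksets)
        all_pos.append(pos)
    obj.cell_kernels = all_ksets
    obj.positivity = all_pos
    return obj


def assign_continuous(
    obj: SimObject,
    specs: DistributionSpec | list[DistributionSpec],
) -> SimObject:
    """Draw a continuous marker value per cell and type, given positivity.

    Positive cells draw from Normal(mean_pos, sd_pos), negative cells from
    Normal(mean_neg, sd_neg), independently across cells and types.
    """
    if obj.positivity is None:
        raise RuntimeError(
            "positivity not assigned: call assign_cell_positivity() first"
        )
    if isinstance(specs, DistributionSpec):
        specs = [specs] * obj.n_cell_types
    if len(specs) != obj.n_cell_types:
        raise ValueError(
            f"need one DistributionSpec per cell type "
            f"({obj.n_cell_types}), got {len(specs)}"
        )
    values = []
    for i, pos in enumerate(obj.positivity):
        rng = substream(obj.seed, "distributions", i)
        vals = np.empty(pos.shape, dtype=float)
        for t, spec in enumerate(specs):
            n = pos.shape[0]
            draw_pos = rng.normal(spec.mean_pos, spec.sd_pos, size=n)
            draw_neg = rng.normal(spec.mean_neg, spec.sd_neg, size=n)
            vals[:, t] = np.where(pos[:, t] == 1, draw_pos, draw_neg)
        values.append(vals)
    obj.marker_values = values
    return obj
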