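"""Seed-substream discipline.

One master seed; every (stage, sample) pair gets an independent generator
derived by counter, so regenerating a later pipeline stage never perturbs an
earlier one, and samples never share generator state.
"""

from __future__ import annotations

import numpy as np

# stable stage codes; never renumber
STAGES = {
    "pattern": 1,
    "tissue": 2,
    "holes": 3,
    "cells": 4,
    "distributions": 5,
    "permutation": 6,
}


def substream(seed: int, stage: str, sample: int = 0) -> np.random.Generator:
    """Return the generator for one (stage, sample) cell of the seed table."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {sorted(STAGES)}")
    return np.random.default_rng([int(seed), STAGES[stage], int(sample)])
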