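"""Latin-hypercube sampling of a fractional hypercube around a center vector.

The search region around a starting guess is a per-parameter interval
[center*(1-fraction), center*(1+fraction)] (e.g. fraction 0.4 for a
"±40%" cube), clamped below at 0.  Sampling is stratified: each dimension's
range is split into n equal subintervals and each of the n samples occupies
exactly one subinterval per dimension, with an independent random
permutation per dimension and a uniform position inside each cell.  Frozen
parameters keep the center value exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .model import StrainModel
from .parameters import ParameterVector
from .protocol import VIABLE, ProtocolSettings, wt_bootstrap

logger = logging.getLogger(__name__)

__all__ = ["Hypercube", "lh_sample", "filter_by_constraint", "wt_viable"]


@dataclass(frozen=True)
class Hypercube:
    """A fractional box around a center vector, minus frozen dimensions."""

    center: ParameterVector
    fraction: float
    frozen: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must lie in (0, 1]")

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-parameter (lower, upper); frozen dimensions collapse to center."""
        c = self.center.values
        lo = np.maximum(0.0, c * (1.0 - self.fraction))
        hi = c * (1.0 + self.fraction)
        for name in self.frozen:
            i = self.center.space.index(name)
            lo[i] = hi[i] = c[i]
        return lo, hi


def lh_sample(cube: Hypercube, n: int, seed: int) -> list[ParameterVector]:
    """Draw n Latin-hypercube samples from the cube, reproducibly.

    Per non-degenerate dimension, sample k lands in subinterval perm[k] of n
    equal cells, at a uniform position inside the cell.  A zero-width range
    (center 0, or a frozen name) is sampled as the constant center value.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = cube.bounds()
    d = len(lo)
    samples = np.empty((n, d))
    for i in range(d):
        if hi[i] == lo[i]:
            if hi[i] == 0.0 and cube.center.space.names[i] not in cube.frozen:
                logger.info(
                    "parameter %s has a degenerate zero-width range; sampled as 0",
                    cube.center.space.names[i],
                )
            samples[:, i] = lo[i]
            continue
        perm = rng.permutation(n)
        u = rng.uniform(size=n)
        samples[:, i] = lo[i] + (hi[i] - lo[i]) * (perm + u) / n
    space = cube.center.space
    return [ParameterVector(space, row) for row in samples]


def wt_viable(
    model: StrainModel, params: ParameterVector, settings: ProtocolSettings
) -> bool:
    """Does this vector reproduce wild-type viability?"""
    call, _ = wt_bootstrap(model, params, settings)
    return call.call == VIABLE


def filter_by_constraint(
    samples: Sequence[ParameterVector],
    model: StrainModel,
    settings: ProtocolSettings,
    constraint: Optional[Callable[[StrainModel, ParameterVector, ProtocolSettings], bool]] = None,
) -> tuple[list[ParameterVector], list[ParameterVector]]:
    """Partition samples by a constraint (default: wild-type viability).

    Returns (kept, rejected); the partition is exhaustive and disjoint and
    preserves sample order.
    """
    if not samples:
        raise ValueError("samples must be non-empty")
    if constraint is None:
        constraint = wt_viable
    kept: list[ParameterVector] = []
    rejected: list[ParameterVector] = []
    for v in samples:
        (kept if constraint(model, v, settings) else rejected).append(v)
    return kept, rejected
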