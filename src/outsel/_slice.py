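"""Univariate slice sampling (stepping-out and shrinkage, Neal 2003).

Used for the scale parameters tau, sigma_k and sigma_r, whose log-normal
priors break conjugacy with the Gaussian likelihood.  Sampling is done on the
log scale, where the target is smooth and unimodal in practice and no
step-size tuning is needed.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np


class SliceStats:
    """Running count of target-density evaluations, for diagnostics."""

    __slots__ = ("evals",)

    def __init__(self) -> None:
        self.evals = 0


def slice_sample(
    x0: float,
    logf: Callable[[float], float],
    rng: np.random.Generator,
    width: float = 1.0,
    max_steps: int = 50,
    stats: SliceStats | None = None,
) -> float:
    """One slice-sampling transition leaving the density exp(logf) invariant.

    Stepping-out with initial interval ``width`` and at most ``max_steps``
    expansions per side, then shrinkage on rejection.  ``x0`` must have
    finite log-density.
    """
    fx0 = logf(x0)
    if stats is not None:
        stats.evals += 1
    if not math.isfinite(fx0):
        raise ValueError("slice sampler started at a point of zero density")
    logy = fx0 - rng.exponential()

    # stepping out
    u = rng.uniform(0.0, width)
    left, right = x0 - u, x0 + (width - u)
    steps = 0
    while steps < max_steps and logf(left) > logy:
        left -= width
        steps += 1
    if stats is not None:
        stats.evals += steps + 1
    steps = 0
    while steps < max_steps and logf(right) > logy:
        right += width
        steps += 1
    if stats is not None:
        stats.evals += steps + 1

    # shrinkage
    while True:
        x1 = rng.uniform(left, right)
        fx1 = logf(x1)
        if stats is not None:
            stats.evals += 1
        if fx1 > logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
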