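"""Univariate slice sampling (stepping-out with shrinkage).

The trajectory model's joint posterior factorizes by conditional
independence: measure parameters are independent across measures given the
subject latents, and subject latents are independent across subjects given
the measure parameters. Each sweep therefore updates small parameter blocks
coordinate-wise with Neal's slice sampler, which is tuning-robust (only a
step-width scale per coordinate) and always accepts.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["slice_sample", "split_rhat"]


def slice_sample(x0: float, logf, w: float, rng: np.random.Generator, max_steps: int = 6) -> float:
    """One slice-sampling update of a scalar coordinate.

    ``logf`` is the conditional log density (up to a constant); ``w`` the
    initial bracket width. Returns the new value. Uses stepping-out limited
    to ``max_steps`` doublings per side, then shrinkage.
    """
    f0 = logf(x0)
    if not math.isfinite(f0):
        raise ValueError("slice sampler started outside the support")
    logy = f0 + math.log(rng.random() + 1e-300)
    u = rng.random()
    left = x0 - w * u
    right = left + w
    j = max_steps
    while j > 0 and logf(left) > logy:
        left -= w
        j -= 1
    j = max_steps
    while j > 0 and logf(right) > logy:
        right += w
        j -= 1
    while True:
        x1 = rng.uniform(left, right)
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
        if right - left < 1e-12:
            return x0


def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat over draws shaped (n_chains, n_draws)."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 1:
        chains = chains[None, :]
    n = chains.shape[1] // 2
    if n < 2:
        return float("nan")
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    w = halves.var(axis=1, ddof=1).mean()
    b = n * halves.mean(axis=1).var(ddof=1)
    if w <= 1e-300:
        return 1.0
    return float(np.sqrt((n - 1) / n + b / (w * n)))
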