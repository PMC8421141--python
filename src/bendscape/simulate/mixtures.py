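"""Sample bend-angle datasets from a background + modes mixture.

Angles live on [0, 180] degrees, so every Gaussian component is truncated
to that interval (and renormalised); the reported component parameters
are the untruncated (mu, sigma), matching the model fitted downstream.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.stats import truncnorm

__all__ = ["sample_angle_mixture"]


def sample_angle_mixture(n: int,
                         components: Sequence[tuple[float, float, float]],
                         seed: Optional[int] = None,
                         rng: Optional[np.random.Generator] = None,
                         bounds: tuple[float, float] = (0.0, 180.0),
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` angles from a mixture of truncated Gaussians.

    ``components`` lists (weight, mean_deg, sd_deg); weights must sum
    to 1. Returns (values, component labels).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    weights = np.array([w for w, _, _ in components], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("component weights must sum to 1")
    lo, hi = bounds
    labels = rng.choice(len(components), size=n, p=weights)
    values = np.empty(n)
    for k, (_, mu, sd) in enumerate(components):
        sel = labels == k
        if not sel.any():
            continue
        a, b = (lo - mu) / sd, (hi - mu) / sd
        values[sel] = truncnorm.rvs(a, b, loc=mu, scale=sd, size=sel.sum(),
                                    random_state=rng)
    return values, labels
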