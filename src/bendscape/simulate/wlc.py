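"""2D worm-like-chain generation for surface-deposited DNA.

Molecules equilibrated on a surface are modelled as planar chains whose
tangent angle performs a Gaussian random walk. For a chain with (3D)
persistence length P the 2D tangent correlation is

    <cos(theta(s) - theta(0))> = exp(-s / 2P),

which requires per-step angle variance rise/P (only one transverse bending
mode survives in the plane). An optional protein-induced kink is a single
discrete tangent rotation at one position, with the kink angle drawn from
a small discrete mixture of bending states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["KinkSpec", "generate_wlc_trace", "wlc_mean_square_end_to_end"]


@dataclass
class KinkSpec:
    """A protein-induced kink: position, bending-state mixture, blob height.

    ``states`` lists (angle_deg, weight) pairs; weights must sum to 1 and
    angles lie in [0, 180] (0 = no bend). The kink position must be strictly
    inside the molecule. ``protein_height_nm`` is the apparent height of the
    bound-protein blob rendered at the kink.
    """

    position_bp: int
    states: Sequence[tuple[float, float]]
    protein_height_nm: float = 2.0

    def __post_init__(self) -> None:
        weights = [w for _, w in self.states]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("kink state weights must sum to 1")
        if any(w < 0 for w in weights):
            raise ValueError("kink state weights must be non-negative")
        if any(not (0.0 <= a <= 180.0) for a, _ in self.states):
            raise ValueError("kink angles must lie in [0, 180] degrees")

    def sample_state(self, rng: np.random.Generator) -> tuple[int, float]:
        """Draw a state index and its angle."""
        weights = np.array([w for _, w in self.states])
        idx = int(rng.choice(len(self.states), p=weights / weights.sum()))
        return idx, float(self.states[idx][0])


def generate_wlc_trace(n_bp: int,
                       rise_nm_per_bp: float = 0.30,
                       persistence_nm: Optional[float] = 50.0,
                       kink: Optional[KinkSpec] = None,
                       seed: Optional[int] = None,
                       rng: Optional[np.random.Generator] = None,
                       ) -> tuple[np.ndarray, Optional[int], Optional[float]]:
    """Generate one planar WLC backbone polyline.

    Parameters
    ----------
    n_bp
        Number of backbone points (>= 2); segment length is ``rise_nm_per_bp``.
    persistence_nm
        Persistence length in nm; ``None`` or ``inf`` gives a straight rod.
    kink
        Optional protein kink; applied as one extra deterministic tangent
        rotation (random sign) at ``kink.position_bp``.

    Returns
    -------
    (points, state_index, kink_angle_deg)
        ``points`` is an (n_bp, 2) array in nm starting at the origin with a
        random initial direction (fixed direction 0 when persistence is
        infinite and no rng randomness is involved in the backbone).
    """
    if n_bp < 2:
        raise ValueError("n_bp must be >= 2")
    if persistence_nm is not None and not np.isinf(persistence_nm) and persistence_nm <= 0:
        raise ValueError("persistence_nm must be positive or infinite")
    if kink is not None and not (0 < kink.position_bp < n_bp - 1):
        raise ValueError("kink position must be strictly inside the molecule")
    if rng is None:
        rng = np.random.default_rng(seed)

    n_steps = n_bp - 1
    straight = persistence_nm is None or np.isinf(persistence_nm)
    if straight:
        dtheta = np.zeros(n_steps)
        theta0 = 0.0
    else:
        sigma = np.sqrt(rise_nm_per_bp / persistence_nm)
        dtheta = rng.normal(0.0, sigma, size=n_steps)
        dtheta[0] = 0.0  # first step sets the initial direction
        theta0 = rng.uniform(0.0, 2 * np.pi)

    state_idx: Optional[int] = None
    kink_angle: Optional[float] = None
    if kink is not None:
        state_idx, kink_angle = kink.sample_state(rng)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        dtheta[kink.position_bp] += sign * np.radians(kink_angle)

    theta = theta0 + np.cumsum(dtheta)
    steps = rise_nm_per_bp * np.column_stack([np.cos(theta), np.sin(theta)])
    points = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return points, state_idx, kink_angle


def wlc_mean_square_end_to_end(contour_nm: float, persistence_nm: float) -> float:
    """Closed-form <R^2> of a 2D worm-like chain.

    With tangent correlation exp(-s/2P) the mean-square end-to-end distance
    of a chain of contour length L is 4P L - 8 P^2 (1 - exp(-L/2P)).
    """
    lam = 2.0 * persistence_nm
    return 2.0 * lam * contour_nm - 2.0 * lam**2 * (1.0 - np.exp(-contour_nm / lam))
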