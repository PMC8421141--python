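"""Exact Boltzmann sampling of umbrella-sampling windows.

Windows are drawn by inverse-CDF sampling from the biased density

    p_i(x) proportional to exp(-[U(x) + k/2 (x - x_i)^2] / k_B T)

on a fine grid over the potential's domain. Exact i.i.d. sampling (rather
than Langevin dynamics) removes autocorrelation, so downstream WHAM tests
compare against the analytic potential cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np

from bendscape.constants import DEFAULT_TEMPERATURE_K, K_B_KCAL
from bendscape.fes import UmbrellaWindow

__all__ = ["PotentialSpec", "sample_umbrella_windows"]

#: grid points per window domain for inverse-CDF sampling
_GRID_N = 10_000


@dataclass
class PotentialSpec:
    """An analytic 1D potential standing in for an unknown true PMF.

    Forms
    -----
    ``harmonic``        params (k, x0): U = k/2 (x-x0)^2
    ``double_well``     params (a, x0, x1): U = a (x-x0)^2 (x-x1)^2
    ``piecewise_table`` params (xs, us): linear interpolation through a table
    ``flat``            params (): U = 0
    """

    form: str
    params: tuple
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError("domain min must be < max")
        u = self(np.linspace(lo, hi, 101))
        if not np.all(np.isfinite(u)):
            raise ValueError("potential must be finite on its domain")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "harmonic":
            k, x0 = self.params
            return 0.5 * k * (x - x0) ** 2
        if self.form == "double_well":
            a, x0, x1 = self.params
            return a * (x - x0) ** 2 * (x - x1) ** 2
        if self.form == "piecewise_table":
            xs, us = self.params
            return np.interp(x, np.asarray(xs, float), np.asarray(us, float))
        if self.form == "flat":
            return np.zeros_like(x)
        raise ValueError(f"unknown potential form {self.form!r}")


def sample_umbrella_windows(potential: Union[PotentialSpec, Callable],
                            centers: Sequence[float],
                            spring_k: float = 2.0,
                            n_per_window: int = 10_000,
                            temperature_K: float = DEFAULT_TEMPERATURE_K,
                            seed: Optional[int] = None,
                            rng: Optional[np.random.Generator] = None,
                            domain: Optional[tuple[float, float]] = None,
                            ) -> list[UmbrellaWindow]:
    """Draw i.i.d. samples from each biased window density.

    Parameters
    ----------
    potential
        A :class:`PotentialSpec` or any callable U(x) in kcal/mol (then
        ``domain`` must be given).
    centers
        Window centres x_i in Angstrom (must lie inside the domain).
    spring_k
        Harmonic bias spring constant in kcal mol^-1 A^-2 (k >= 0).
    n_per_window
        Samples per window (>= 1).
    """
    if isinstance(potential, PotentialSpec):
        dom = potential.domain
    else:
        if domain is None:
            raise ValueError("domain required for a bare callable potential")
        dom = domain
    if n_per_window < 1:
        raise ValueError("n_per_window must be >= 1")
    if spring_k < 0:
        raise ValueError("spring_k must be >= 0")
    lo, hi = dom
    for c in centers:
        if not lo <= c <= hi:
            raise ValueError(f"window centre {c} outside domain {dom}")
    if rng is None:
        rng = np.random.default_rng(seed)

    beta = 1.0 / (K_B_KCAL * temperature_K)
    x = np.linspace(lo, hi, _GRID_N)
    u0 = np.asarray(potential(x), dtype=float)
    windows: list[UmbrellaWindow] = []
    for c in centers:
        w = u0 + 0.5 * spring_k * (x - c) ** 2
        logp = -beta * (w - w.min())
        p = np.exp(logp)
        z = np.trapezoid(p, x)
        if not np.isfinite(z) or z <= 0:
            raise ValueError(f"biased density for centre {c} is not normalizable")
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(x))])
        cdf /= cdf[-1]
        # strictly increasing support for interpolation
        u = rng.uniform(0.0, 1.0, size=n_per_window)
        samples = np.interp(u, cdf, x)
        windows.append(UmbrellaWindow(samples=samples, center=float(c),
                                      spring_k=float(spring_k),
                                      temperature_K=float(temperature_K)))
    return windows
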