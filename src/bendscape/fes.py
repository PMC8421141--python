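"""Free-energy reconstruction from umbrella-sampling windows.

The stages mirror the standard workflow for a two-arm wrapping reaction:

1. :func:`wham_1d` — the weighted histogram analysis method turns biased
   window samples into an unbiased 1D potential of mean force (PMF).
2. :func:`remap_coordinate` — a linear fit translates a raw two-atom
   distance onto a centre-of-mass reaction coordinate.
3. :func:`align_offsets` — PMFs measured under different conditions are
   put on a common energy scale by matching their means over the plateau
   of the unbent state.
4. :func:`build_landscape` — for each arm, PMFs measured with the other
   arm bound and held away are linearly interpolated as a function of the
   other arm's coordinate; the 2D landscape is the sum of the two arm
   terms.
5. :func:`boltzmann_probabilities` / :func:`state_probabilities` — the
   landscape is translated into P = exp(-F / k_B T) and conformational
   states are integrated over it using per-cell occupancy weights.

Energies are kcal/mol, coordinates Angstrom, temperatures Kelvin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from bendscape.constants import DEFAULT_TEMPERATURE_K, K_B_KCAL

__all__ = [
    "UmbrellaWindow",
    "PMF",
    "CoordinateMap",
    "FreeEnergySurface",
    "ProbabilitySurface",
    "wham_1d",
    "remap_coordinate",
    "align_offsets",
    "build_landscape",
    "boltzmann_probabilities",
    "state_probabilities",
    "free_energy_difference",
]


@dataclass
class UmbrellaWindow:
    """Samples of a reaction coordinate under one harmonic bias.

    ``samples`` are coordinate values in Angstrom, biased by
    k/2 (x - center)^2 with ``spring_k`` in kcal mol^-1 A^-2.
    """

    samples: np.ndarray
    center: float
    spring_k: float
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.spring_k < 0:
            raise ValueError("spring_k must be >= 0")

    def bias_energy(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * self.spring_k * (np.asarray(x, float) - self.center) ** 2


@dataclass
class PMF:
    """A binned free-energy profile along one reaction coordinate."""

    grid: np.ndarray            # bin centres, Angstrom, uniform
    F: np.ndarray               # kcal/mol, zeroed at the minimum
    offset: float = 0.0         # cumulative offset applied by alignment
    arm: str = ""               # e.g. "left"/"right"
    condition: str = ""         # "bound" | "held_away"
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.grid.shape != self.F.shape:
            raise ValueError("grid and F must have matching shapes")
        if self.grid.size >= 2:
            steps = np.diff(self.grid)
            if not np.allclose(steps, steps[0], rtol=1e-6):
                raise ValueError("PMF bins must be uniform")

    def zeroed(self) -> "PMF":
        """Copy with min F = 0."""
        return PMF(self.grid.copy(), self.F - np.nanmin(self.F),
                   offset=self.offset, arm=self.arm,
                   condition=self.condition, temperature_K=self.temperature_K)

    def interp(self, x: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(x, float), self.grid, self.F)


@dataclass
class CoordinateMap:
    """Linear map x_target = a * x_raw + b from paired observations."""

    slope: float
    intercept: float
    residual_rms: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be nonzero")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x, float) + self.intercept


@dataclass
class FreeEnergySurface:
    """2D free-energy landscape F(x_left, x_right) on a uniform grid."""

    x_left: np.ndarray
    x_right: np.ndarray
    F: np.ndarray               # shape (len(x_left), len(x_right))
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        self.x_left = np.asarray(self.x_left, dtype=float)
        self.x_right = np.asarray(self.x_right, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != (self.x_left.size, self.x_right.size):
            raise ValueError("F shape must be (len(x_left), len(x_right))")

    @property
    def cell_area(self) -> float:
        dl = self.x_left[1] - self.x_left[0] if self.x_left.size > 1 else 1.0
        dr = self.x_right[1] - self.x_right[0] if self.x_right.size > 1 else 1.0
        return float(dl * dr)


@dataclass
class ProbabilitySurface:
    """Boltzmann twin of a landscape: P = exp(-F/k_B T), normalised.

    ``P`` holds per-cell probabilities summing to 1; ``density`` is
    P / cell_area so that sum(density * cell area) = 1.
    """

    x_left: np.ndarray
    x_right: np.ndarray
    P: np.ndarray
    temperature_K: float = DEFAULT_TEMPERATURE_K
    cell_area: float = 1.0

    def __post_init__(self) -> None:
        self.x_left = np.asarray(self.x_left, dtype=float)
        self.x_right = np.asarray(self.x_right, dtype=float)
        self.P = np.asarray(self.P, dtype=float)

    @property
    def density(self) -> np.ndarray:
        return self.P / self.cell_area


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

def wham_1d(windows: Sequence[UmbrellaWindow],
            bin_width: float = 0.2,
            tol: float = 1e-6,
            max_iter: int = 100_000,
            temperature_K: Optional[float] = None) -> PMF:
    """Self-consistent WHAM estimate of the unbiased PMF.

    Iterates the window free-energy shifts f_i of the standard WHAM
    equations until the largest change is below ``tol`` (kcal/mol):

        P(b) = sum_i h_i(b) / sum_i N_i exp((f_i - w_i(b)) / k_B T)
        f_i  = -k_B T ln sum_b P(b) exp(-w_i(b) / k_B T)

    The PMF is -k_B T ln P, zeroed at its minimum. Adjacent windows whose
    histograms share no occupied bin trigger a warning (the profile is
    then only determined up to independent offsets per connected block).
    """
    if not windows:
        raise ValueError("need at least one window")
    T = temperature_K if temperature_K is not None else windows[0].temperature_K
    beta = 1.0 / (K_B_KCAL * T)

    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.array([np.histogram(w.samples, bins=edges)[0] for w in windows],
                      dtype=float)                       # (n_win, n_bins)
    n_samples = counts.sum(axis=1)

    # overlap check between windows ordered by centre
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((counts[a] > 0) & (counts[b] > 0)):
            warnings.warn(
                f"windows centred at {windows[a].center} and {windows[b].center} "
                "share no occupied bin; PMF may be disconnected", RuntimeWarning)

    bias = np.array([w.bias_energy(centers) for w in windows])   # (n_win, n_bins)
    expw = np.exp(-beta * bias)
    total = counts.sum(axis=0)                                   # (n_bins,)

    f = np.zeros(len(windows))
    for it in range(max_iter):
        denom = (n_samples[:, None] * np.exp(beta * f)[:, None] * expw).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, total / denom, 0.0)
        z = (p[None, :] * expw).sum(axis=1)
        f_new = -np.log(z) / beta
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    else:
        raise RuntimeError(f"WHAM did not converge in {max_iter} iterations")

    denom = (n_samples[:, None] * np.exp(beta * f)[:, None] * expw).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom > 0, total / denom, 0.0)
    occupied = p > 0
    F = np.full_like(p, np.inf)
    F[occupied] = -np.log(p[occupied]) / beta
    F -= F[occupied].min()
    # uniform grid: trim empty edge bins, keep interior gaps as +inf
    idx = np.flatnonzero(occupied)
    sl = slice(idx[0], idx[-1] + 1)
    return PMF(grid=centers[sl], F=F[sl], temperature_K=T)


# ---------------------------------------------------------------------------
# Coordinate remapping and offset alignment
# ---------------------------------------------------------------------------

def remap_coordinate(obj, pairs: Sequence[tuple[float, float]]):
    """Fit x_target = a x_raw + b and transform windows or a PMF.

    ``pairs`` are paired (raw, target) observations, e.g. a raw two-atom
    distance against the corresponding centre-of-mass distance. Returns
    (remapped object, :class:`CoordinateMap`). For windows the samples,
    centre and spring constant are transformed (k' = k / a^2 preserves
    bias energies); for a PMF only the grid is remapped.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 2:
        raise ValueError("need >= 2 paired observations")
    raw, target = pairs[:, 0], pairs[:, 1]
    if np.ptp(raw) == 0:
        raise ValueError("raw coordinates are degenerate (all equal)")
    a, b = np.polyfit(raw, target, 1)
    resid = target - (a * raw + b)
    cmap = CoordinateMap(slope=float(a), intercept=float(b),
                         residual_rms=float(np.sqrt(np.mean(resid**2))))

    if isinstance(obj, PMF):
        grid = cmap(obj.grid)
        if a < 0:
            grid, F = grid[::-1], obj.F[::-1]
        else:
            F = obj.F
        return PMF(grid=grid, F=F.copy(), offset=obj.offset, arm=obj.arm,
                   condition=obj.condition, temperature_K=obj.temperature_K), cmap
    if isinstance(obj, UmbrellaWindow):
        obj = [obj]
    remapped = [UmbrellaWindow(samples=cmap(w.samples), center=float(cmap(w.center)),
                               spring_k=w.spring_k / a**2,
                               temperature_K=w.temperature_K) for w in obj]
    return remapped, cmap


def align_offsets(pmf_a: PMF, pmf_b: PMF,
                  plateau_range: tuple[float, float]) -> tuple[PMF, PMF, float]:
    """Shift pmf_b so both PMFs agree over the unbent-state plateau.

    The shift equals mean_a(plateau) - mean_b(plateau); returns
    (pmf_a, shifted pmf_b, shift).
    """
    lo, hi = plateau_range
    sel_a = (pmf_a.grid >= lo) & (pmf_a.grid <= hi)
    sel_b = (pmf_b.grid >= lo) & (pmf_b.grid <= hi)
    if not sel_a.any() or not sel_b.any():
        raise ValueError("plateau range does not overlap both PMF grids")
    shift = float(pmf_a.F[sel_a].mean() - pmf_b.F[sel_b].mean())
    shifted = PMF(pmf_b.grid.copy(), pmf_b.F + shift,
                  offset=pmf_b.offset + shift, arm=pmf_b.arm,
                  condition=pmf_b.condition, temperature_K=pmf_b.temperature_K)
    return pmf_a, shifted, shift


# ---------------------------------------------------------------------------
# 2D landscape
# ---------------------------------------------------------------------------

def build_landscape(left: tuple[PMF, PMF], right: tuple[PMF, PMF],
                    bound_ref: tuple[float, float],
                    unbound_ref: tuple[float, float],
                    grid_res: float = 1.0,
                    domain_left: Optional[tuple[float, float]] = None,
                    domain_right: Optional[tuple[float, float]] = None,
                    ) -> FreeEnergySurface:
    """Combine per-arm bound/held-away PMFs into a 2D landscape.

    For each grid point (x_L, x_R) the left-arm term interpolates between
    the left PMF measured with the right arm bound and held away,

        lambda_R = clamp((x_R - bound_ref_R) / (unbound_ref_R - bound_ref_R), 0, 1)
        F_L = (1 - lambda_R) F_L^bound(x_L) + lambda_R F_L^away(x_L)

    and symmetrically for the right arm; F = F_L + F_R (simple addition of
    energies). ``bound_ref``/``unbound_ref`` give per-arm anchor
    coordinates (A): typically the bound-state minimum and the held-away
    threshold.
    """
    lb, la = left
    rb, ra = right
    if domain_left is None:
        lo = max(lb.grid.min(), la.grid.min())
        hi = min(lb.grid.max(), la.grid.max())
        domain_left = (lo, hi)
    if domain_right is None:
        lo = max(rb.grid.min(), ra.grid.min())
        hi = min(rb.grid.max(), ra.grid.max())
        domain_right = (lo, hi)
    for name, (lo, hi) in (("left", domain_left), ("right", domain_right)):
        if hi <= lo:
            raise ValueError(f"{name} PMF grids do not overlap on the requested domain")

    x_l = np.arange(domain_left[0], domain_left[1] + grid_res / 2, grid_res)
    x_r = np.arange(domain_right[0], domain_right[1] + grid_res / 2, grid_res)

    def lam(x, ref_bound, ref_unbound):
        return np.clip((x - ref_bound) / (ref_unbound - ref_bound), 0.0, 1.0)

    lam_r = lam(x_r, bound_ref[1], unbound_ref[1])      # weight for the LEFT arm
    lam_l = lam(x_l, bound_ref[0], unbound_ref[0])      # weight for the RIGHT arm

    f_l = ((1 - lam_r)[None, :] * lb.interp(x_l)[:, None]
           + lam_r[None, :] * la.interp(x_l)[:, None])
    f_r = ((1 - lam_l)[:, None] * rb.interp(x_r)[None, :]
           + lam_l[:, None] * ra.interp(x_r)[None, :])
    T = lb.temperature_K
    return FreeEnergySurface(x_left=x_l, x_right=x_r, F=f_l + f_r, temperature_K=T)


def boltzmann_probabilities(surface: FreeEnergySurface,
                            temperature_K: Optional[float] = None
                            ) -> ProbabilitySurface:
    """Translate a landscape into a normalised probability surface.

    P(cell) proportional to exp(-F / k_B T); cells sum to 1 and the
    associated density integrates to 1 over the grid area.
    """
    T = temperature_K if temperature_K is not None else surface.temperature_K
    beta = 1.0 / (K_B_KCAL * T)
    F = surface.F
    finite = np.isfinite(F)
    if not finite.any():
        raise ValueError("all free energies are infinite")
    logp = np.where(finite, -beta * (F - F[finite].min()), -np.inf)
    P = np.exp(logp)
    P /= P.sum()
    return ProbabilitySurface(x_left=surface.x_left, x_right=surface.x_right,
                              P=P, temperature_K=T, cell_area=surface.cell_area)


def _cell_indices(psurface: ProbabilitySurface,
                  points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map (x_L, x_R) points to nearest grid cells; out-of-grid -> dropped."""
    points = np.asarray(points, dtype=float)
    dl = psurface.x_left[1] - psurface.x_left[0] if psurface.x_left.size > 1 else 1.0
    dr = psurface.x_right[1] - psurface.x_right[0] if psurface.x_right.size > 1 else 1.0
    i = np.round((points[:, 0] - psurface.x_left[0]) / dl).astype(int)
    j = np.round((points[:, 1] - psurface.x_right[0]) / dr).astype(int)
    ok = ((i >= 0) & (i < psurface.x_left.size)
          & (j >= 0) & (j < psurface.x_right.size))
    return i[ok], j[ok]


def state_probabilities(psurface: ProbabilitySurface,
                        cluster_points: dict,
                        hard_assignment: bool = False) -> dict:
    """Integrate per-state occupancies over the probability landscape.

    ``cluster_points`` maps state name -> (n, 2) array of (x_L, x_R)
    coordinates of the frames belonging to that state. Each grid cell
    receives per-state weights from the states' 2D histograms at grid
    resolution, normalised per cell (or winner-takes-all when
    ``hard_assignment``); the state probability is
    sum_cells P(cell) * weight_state(cell), renormalised to 100%.
    """
    shape = (psurface.x_left.size, psurface.x_right.size)
    occ = {}
    for name, pts in cluster_points.items():
        pts = np.asarray(pts, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 1:
            raise ValueError(f"state {name!r} has no points")
        i, j = _cell_indices(psurface, pts)
        if i.size == 0:
            raise ValueError(f"state {name!r} has no points inside the grid")
        h = np.zeros(shape)
        np.add.at(h, (i, j), 1.0)
        occ[name] = h
    total = np.sum(list(occ.values()), axis=0)
    probs = {}
    for name, h in occ.items():
        if hard_assignment:
            winners = np.zeros(shape)
            stack = np.stack([occ[k] for k in occ])
            names = list(occ)
            arg = np.argmax(stack, axis=0)
            winners = ((arg == names.index(name)) & (total > 0)).astype(float)
            weight = winners
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                weight = np.where(total > 0, h / total, 0.0)
        probs[name] = float((psurface.P * weight).sum())
    norm = sum(probs.values())
    if norm <= 0:
        raise ValueError("no probability mass in any state region")
    return {k: 100.0 * v / norm for k, v in probs.items()}


def free_energy_difference(surface, region_a, region_b,
                           temperature_K: Optional[float] = None) -> float:
    """Free-energy difference -k_B T ln(P_b / P_a) between two regions.

    ``surface`` is a :class:`FreeEnergySurface` or :class:`PMF`; regions
    are boolean masks over the grid (or index arrays). Probabilities come
    from the Boltzmann weights of the cells.
    """
    if isinstance(surface, PMF):
        T = temperature_K if temperature_K is not None else surface.temperature_K
        F = surface.F
    else:
        T = temperature_K if temperature_K is not None else surface.temperature_K
        F = surface.F
    beta = 1.0 / (K_B_KCAL * T)
    w = np.exp(-beta * (F - np.nanmin(F[np.isfinite(F)])))
    pa = w[region_a].sum()
    pb = w[region_b].sum()
    if pa <= 0 or pb <= 0:
        raise ValueError("empty region")
    return float(-np.log(pb / pa) / beta)
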