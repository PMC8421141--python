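"""Bend-angle distribution statistics: background + Gaussian-mode mixtures.

AFM bend angles of protein-bound DNA mix an irreducible naked-DNA
background (thermal bending plus unbound molecules) with discrete
protein-induced bending modes. The decomposition here freezes the
background *shape* on the bare-DNA sample (a single truncated Gaussian on
[0, 180] deg) and fits only its weight jointly with up to
``max_components`` extra Gaussian modes to the histogram of the
protein-present sample, by weighted least squares with Poisson errors.
Model order is chosen by a reduced chi-square goodness-of-fit criterion.

All angles are degrees in [0, 180]; 0 = straight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "AngleSample",
    "MixtureFitResult",
    "density_estimate",
    "fit_background_mixture",
    "reduced_chi_square",
    "ks_two_sample",
    "state_proportions",
]

_BOUNDS = (0.0, 180.0)


@dataclass
class AngleSample:
    """A labelled sample of bend angles (degrees in [0, 180])."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (self.values.min() < 0 or self.values.max() > 180):
            raise ValueError("angles must lie in [0, 180] degrees")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class MixtureFitResult:
    """Fitted background weight plus Gaussian binding-mode components.

    ``components`` lists (weight, mean_deg, sd_deg) for the modes;
    ``background_weight`` w0 completes the unit sum. ``warning`` is set
    when no model order met the primary goodness-of-fit criterion and the
    parsimonious fallback decided the order.
    """

    background_weight: float
    background_params: tuple[float, float]       # (mu, sigma) of the bare shape
    components: list[tuple[float, float, float]]
    reduced_chi2: float
    dof: int
    p_value: float
    bins: np.ndarray
    warning: bool = False
    candidates: dict = field(default_factory=dict)  # m -> p-value

    @property
    def n_components(self) -> int:
        return len(self.components)


# ---------------------------------------------------------------------------
# Densities and simple tests
# ---------------------------------------------------------------------------

def density_estimate(values: np.ndarray, bandwidth: Optional[float] = None,
                     grid: Optional[np.ndarray] = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density estimate on a stated grid.

    Returns (grid, density) with the density renormalised to integrate to
    1 over the grid. Used for e.g. radius-of-gyration distributions.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if np.std(values) == 0:
        raise ValueError("zero-variance sample has no kernel density")
    kde = stats.gaussian_kde(values, bw_method=bandwidth)
    if grid is None:
        span = values.max() - values.min()
        grid = np.linspace(values.min() - 0.5 * span, values.max() + 0.5 * span, 512)
    dens = kde(grid)
    dens = dens / np.trapezoid(dens, grid)
    return grid, dens


def ks_two_sample(a: AngleSample, b: AngleSample) -> tuple[float, float]:
    """Two-sided Kolmogorov-Smirnov test (asymptotic p)."""
    res = stats.ks_2samp(a.values, b.values, alternative="two-sided",
                         method="asymp")
    return float(res.statistic), float(res.pvalue)


def reduced_chi_square(observed: np.ndarray, expected: np.ndarray,
                       n_free_params: int) -> tuple[float, float, int]:
    """Pearson goodness-of-fit with sigma = sqrt(max(observed, 1)).

    Adjacent bins are merged until every expectation is >= 1. Returns
    (chi2/nu, p-value, nu) where p = P(chi2_nu >= observed statistic).
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    obs_m, exp_m = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= 1.0:
            obs_m.append(acc_o)
            exp_m.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and obs_m:
        obs_m[-1] += acc_o
        exp_m[-1] += acc_e
    obs_m = np.asarray(obs_m)
    exp_m = np.asarray(exp_m)
    nu = len(obs_m) - n_free_params
    if nu < 1:
        raise ValueError(f"not enough bins for {n_free_params} free parameters")
    chi2 = float((((obs_m - exp_m) ** 2) / np.maximum(obs_m, 1.0)).sum())
    p = float(stats.chi2.sf(chi2, nu))
    return chi2 / nu, p, nu


# ---------------------------------------------------------------------------
# Mixture decomposition
# ---------------------------------------------------------------------------

def _trunc_bin_mass(edges: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Bin masses of a [0,180]-truncated Gaussian."""
    lo, hi = _BOUNDS
    z = stats.norm(mu, sigma)
    norm = z.cdf(hi) - z.cdf(lo)
    if norm <= 0:
        return np.zeros(len(edges) - 1)
    return np.diff(z.cdf(edges)) / norm


def _fit_truncated_gaussian(values: np.ndarray) -> tuple[float, float]:
    """MLE of a [0,180]-truncated Gaussian (mu, sigma)."""
    lo, hi = _BOUNDS

    def nll(theta):
        mu, sigma = theta
        if sigma <= 0.5:
            return 1e12
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        return -np.sum(stats.truncnorm.logpdf(values, a, b, loc=mu, scale=sigma))

    x0 = np.array([values.mean(), max(values.std(), 1.0)])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8})
    return float(res.x[0]), float(res.x[1])


def _histogram_peaks(counts: np.ndarray, centers: np.ndarray) -> list[float]:
    """Centers of local maxima, ties broken by angle order."""
    peaks = []
    ext = np.concatenate([[-1.0], counts, [-1.0]])
    for i in range(len(counts)):
        if ext[i + 1] > ext[i] and ext[i + 1] >= ext[i + 2]:
            peaks.append(centers[i])
    peaks.sort()
    return peaks


def _model_counts(params: np.ndarray, m: int, n_total: float,
                  edges: np.ndarray, bg: tuple[float, float]) -> np.ndarray:
    ws = params[:m]
    mus = params[m:2 * m]
    sds = params[2 * m:3 * m]
    w0 = 1.0 - ws.sum()
    model = w0 * _trunc_bin_mass(edges, *bg)
    for w, mu, sd in zip(ws, mus, sds):
        model = model + w * _trunc_bin_mass(edges, mu, sd)
    return n_total * model


def _fit_m_components(counts: np.ndarray, edges: np.ndarray, m: int,
                      bg: tuple[float, float],
                      peak_means: list[float]) -> tuple[np.ndarray, float]:
    """Weighted least squares for one model order; multi-start over peaks."""
    n_total = counts.sum()
    sigma = np.sqrt(np.maximum(counts, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    if m == 0:
        return np.empty(0), float((((counts - _model_counts(
            np.empty(0), 0, n_total, edges, bg)) / sigma) ** 2).sum())

    def residuals(params):
        ws = params[:m]
        res = (_model_counts(params, m, n_total, edges, bg) - counts) / sigma
        overflow = max(0.0, ws.sum() - 1.0)
        return np.concatenate([res, [1e3 * overflow]])

    starts: list[np.ndarray] = []
    pool = peak_means if len(peak_means) >= m else list(peak_means) + list(
        np.linspace(30, 160, m))
    for combo in list(combinations(sorted(pool), m))[:12]:
        starts.append(np.concatenate([np.full(m, 0.3 / m), combo,
                                      np.full(m, 10.0)]))
    starts.append(np.concatenate([np.full(m, 0.3 / m),
                                  np.linspace(40, 150, m), np.full(m, 15.0)]))

    lower = np.concatenate([np.zeros(m), np.zeros(m), np.full(m, 2.0)])
    upper = np.concatenate([np.ones(m), np.full(m, 180.0), np.full(m, 60.0)])
    best_params, best_chi2 = None, np.inf
    for x0 in starts:
        x0 = np.clip(x0, lower + 1e-9, upper - 1e-9)
        try:
            sol = optimize.least_squares(residuals, x0, bounds=(lower, upper),
                                         xtol=1e-10, ftol=1e-10, max_nfev=2000)
        except Exception:
            continue
        chi2 = float((sol.fun[:-1] ** 2).sum())
        if chi2 < best_chi2 - 1e-12:
            best_chi2, best_params = chi2, sol.x
    if best_params is None:
        raise RuntimeError(f"mixture fit failed for m={m}")
    return best_params, best_chi2


def fit_background_mixture(sample_plus: AngleSample,
                           sample_bare: AngleSample,
                           max_components: int = 3,
                           bin_width: float = 10.0,
                           p_select: float = 0.99,
                           p_fallback: float = 0.05) -> MixtureFitResult:
    """Decompose a bend-angle distribution into background + Gaussian modes.

    The background shape is a single truncated Gaussian fitted (MLE) to
    the bare-DNA sample and then frozen; only its weight w0 is free in the
    joint fit. For each model order m = 0..``max_components``, m extra
    truncated-Gaussian modes are fitted to the 10-deg histogram of
    ``sample_plus`` by weighted least squares with Poisson errors
    (sigma = sqrt(max(observed, 1))), multi-started from histogram local
    maxima.

    Order selection: the smallest m whose goodness-of-fit p-value exceeds
    ``p_select`` (0.99). When no order attains that strict criterion the
    parsimonious fallback picks the smallest m whose fit is statistically
    acceptable (p > ``p_fallback``), flagged by ``warning=True``; if none
    is acceptable the order with the largest p-value is returned.
    """
    if sample_plus.n == 0 or sample_bare.n == 0:
        raise ValueError("both samples must be non-empty")
    bg = _fit_truncated_gaussian(sample_bare.values)
    edges = np.arange(_BOUNDS[0], _BOUNDS[1] + bin_width / 2, bin_width)
    counts, _ = np.histogram(sample_plus.values, bins=edges)
    counts = counts.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak_means = _histogram_peaks(counts, centers)

    fits: dict[int, tuple[np.ndarray, float, float, int, float]] = {}
    for m in range(max_components + 1):
        params, _ = _fit_m_components(counts, edges, m, bg, peak_means)
        model = _model_counts(params, m, counts.sum(), edges, bg)
        n_free = 3 * m
        try:
            red, p, nu = reduced_chi_square(counts, model, n_free)
        except ValueError:
            continue
        fits[m] = (params, red, p, nu, counts.sum())

    if not fits:
        raise RuntimeError("no model order could be evaluated")
    pvals = {m: fits[m][2] for m in fits}
    selected, warning = None, False
    for m in sorted(fits):
        if pvals[m] > p_select:
            selected = m
            break
    if selected is None:
        warning = True
        for m in sorted(fits):
            if pvals[m] > p_fallback:
                selected = m
                break
    if selected is None:
        selected = max(pvals, key=pvals.get)

    params, red, p, nu, _ = fits[selected]
    m = selected
    ws = params[:m]
    comps = sorted(
        [(float(w), float(mu), float(sd))
         for w, mu, sd in zip(ws, params[m:2 * m], params[2 * m:3 * m])],
        key=lambda c: c[1])
    return MixtureFitResult(
        background_weight=float(1.0 - ws.sum()) if m else 1.0,
        background_params=bg,
        components=comps,
        reduced_chi2=float(red),
        dof=int(nu),
        p_value=float(p),
        bins=edges,
        warning=warning,
        candidates=pvals,
    )


def state_proportions(fit: MixtureFitResult) -> list[float]:
    """Binding-mode percentages among bound molecules.

    Non-background component weights renormalised to sum to 100%.
    """
    if not fit.components:
        raise ValueError("fit has no non-background components")
    ws = np.array([w for w, _, _ in fit.components])
    if ws.sum() <= 0:
        raise ValueError("all non-background weights are zero")
    return list(100.0 * ws / ws.sum())
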