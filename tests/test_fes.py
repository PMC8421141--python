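"""Free-energy reconstruction: WHAM against analytic potentials and a
brute-force fixed-point oracle, coordinate remapping, offset alignment,
2D landscape assembly and Boltzmann state probabilities."""

import numpy as np
import pytest

from bendscape.constants import K_B_KCAL
from bendscape.fes import (PMF, FreeEnergySurface, UmbrellaWindow,
                           align_offsets, boltzmann_probabilities,
                           build_landscape, free_energy_difference,
                           remap_coordinate, state_probabilities, wham_1d)
from bendscape.simulate import PotentialSpec, sample_umbrella_windows

KT300 = K_B_KCAL * 300.0


def brute_force_wham(windows, bin_width, n_iter=60_000):
    """Independent fixed-point WHAM solver, written without reference to
    the package implementation: scalar loops over bins and windows."""
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    n_bins = int(np.ceil((hi - lo) / bin_width))
    edges = [lo + bin_width * i for i in range(n_bins + 1)]
    centers = [0.5 * (edges[i] + edges[i + 1]) for i in range(n_bins)]
    beta = 1.0 / (K_B_KCAL * windows[0].temperature_K)
    hist = []
    for w in windows:
        counts = [0] * n_bins
        for x in w.samples:
            b = min(int((x - lo) / bin_width), n_bins - 1)
            counts[b] += 1
        hist.append(counts)
    f = [0.0] * len(windows)
    for _ in range(n_iter):
        p = []
        for b in range(n_bins):
            num = sum(hist[i][b] for i in range(len(windows)))
            den = 0.0
            for i, w in enumerate(windows):
                bias = 0.5 * w.spring_k * (centers[b] - w.center) ** 2
                den += len(w.samples) * np.exp(beta * (f[i] - bias))
            p.append(num / den if den > 0 else 0.0)
        new_f = []
        for i, w in enumerate(windows):
            z = sum(p[b] * np.exp(-beta * 0.5 * w.spring_k
                                  * (centers[b] - w.center) ** 2)
                    for b in range(n_bins))
            new_f.append(-np.log(z) / beta)
        shift = new_f[0]
        new_f = [v - shift for v in new_f]
        if max(abs(a - b) for a, b in zip(new_f, f)) < 1e-10:
            f = new_f
            break
        f = new_f
    p = []
    for b in range(n_bins):
        num = sum(hist[i][b] for i in range(len(windows)))
        den = 0.0
        for i, w in enumerate(windows):
            bias = 0.5 * w.spring_k * (centers[b] - w.center) ** 2
            den += len(w.samples) * np.exp(beta * (f[i] - bias))
        p.append(num / den if den > 0 else 0.0)
    occupied = [b for b in range(n_bins) if p[b] > 0]
    F = {b: -np.log(p[b]) / beta for b in occupied}
    fmin = min(F.values())
    return np.array([centers[b] for b in occupied]), \
        np.array([F[b] - fmin for b in occupied])


class TestWham1D:
    def test_flat_unbiased_window_gives_flat_pmf(self):
        pot = PotentialSpec("flat", (), (0.0, 10.0))
        windows = sample_umbrella_windows(pot, [5.0], spring_k=0.0,
                                          n_per_window=100_000, seed=1)
        pmf = wham_1d(windows, bin_width=0.5)
        assert np.max(np.abs(pmf.F)) < 0.05

    def test_harmonic_potential_recovered(self):
        pot = PotentialSpec("harmonic", (1.0, 35.0), (28.0, 42.0))
        centers = [30.0, 32.0, 34.0, 36.0, 38.0, 40.0]
        windows = sample_umbrella_windows(pot, centers, spring_k=2.0,
                                          n_per_window=10_000, seed=2)
        pmf = wham_1d(windows, bin_width=0.2)
        interior = (pmf.grid > 31.0) & (pmf.grid < 39.0)
        truth = 0.5 * (pmf.grid[interior] - 35.0) ** 2
        resid = pmf.F[interior] - truth
        resid -= resid.mean()            # PMF defined up to a constant
        assert np.max(np.abs(resid)) < 0.2

    def test_matches_brute_force_fixed_point_solver(self):
        pot = PotentialSpec("harmonic", (0.8, 5.0), (2.0, 8.0))
        windows = sample_umbrella_windows(pot, [4.0, 6.0], spring_k=1.5,
                                          n_per_window=400, seed=3)
        pmf = wham_1d(windows, bin_width=0.5, tol=1e-10)
        grid_o, F_o = brute_force_wham(windows, bin_width=0.5)
        np.testing.assert_allclose(pmf.grid, grid_o, atol=1e-12)
        np.testing.assert_allclose(pmf.F, F_o, atol=1e-6)

    def test_bin_width_halving_stability(self):
        pot = PotentialSpec("harmonic", (1.0, 35.0), (28.0, 42.0))
        centers = [30.0, 32.0, 34.0, 36.0, 38.0, 40.0]
        windows = sample_umbrella_windows(pot, centers, spring_k=2.0,
                                          n_per_window=10_000, seed=4)
        pmf_a = wham_1d(windows, bin_width=0.2)
        pmf_b = wham_1d(windows, bin_width=0.1)
        Fb = np.interp(pmf_a.grid, pmf_b.grid, pmf_b.F)
        sel = (pmf_a.grid > 31) & (pmf_a.grid < 39)
        diff = pmf_a.F[sel] - Fb[sel]
        assert np.max(np.abs(diff - diff.mean())) < 0.05

    def test_disjoint_windows_warn(self):
        w1 = UmbrellaWindow(np.linspace(0, 1, 50), 0.5, 2.0)
        w2 = UmbrellaWindow(np.linspace(9, 10, 50), 9.5, 2.0)
        with pytest.warns(RuntimeWarning, match="share no occupied bin"):
            wham_1d([w1, w2], bin_width=0.2)

    def test_two_basin_free_energy_difference(self):
        # pipeline recovery: double-well potential, basin dF vs analytic
        a, x0, x1 = 0.08, 3.0, 7.0
        tilt = 0.35
        xs = np.linspace(0.0, 10.0, 400)
        us = a * (xs - x0) ** 2 * (xs - x1) ** 2 + tilt * xs
        pot = PotentialSpec("piecewise_table", (xs, us), (0.0, 10.0))
        centers = np.arange(1.0, 9.5, 0.5)
        windows = sample_umbrella_windows(pot, list(centers), spring_k=3.0,
                                          n_per_window=4000, seed=5)
        pmf = wham_1d(windows, bin_width=0.1)
        beta = 1.0 / KT300
        left = pmf.grid < 5.0
        right = pmf.grid >= 5.0
        dF = free_energy_difference(pmf, left, right)
        # analytic: integrate Boltzmann weights of the true potential
        u_grid = np.interp(pmf.grid, xs, us)
        w = np.exp(-beta * u_grid)
        dF_true = -np.log(w[right].sum() / w[left].sum()) / beta
        assert dF == pytest.approx(dF_true, abs=0.2)


class TestRemapCoordinate:
    def test_identity_pairs(self):
        pmf = PMF(np.linspace(0, 10, 11), np.zeros(11))
        out, cmap = remap_coordinate(pmf, [(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)])
        assert cmap.slope == pytest.approx(1.0)
        assert cmap.intercept == pytest.approx(0.0)

    def test_exact_affine_recovered(self):
        raw = np.linspace(10, 20, 7)
        pairs = list(zip(raw, 0.9 * raw + 2.0))
        pmf = PMF(raw, np.zeros(7))
        out, cmap = remap_coordinate(pmf, pairs)
        assert cmap.slope == pytest.approx(0.9, abs=1e-12)
        assert cmap.intercept == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(out.grid, 0.9 * raw + 2.0)

    def test_noisy_slope_within_3se(self, rng):
        n = 200
        raw = rng.uniform(0, 50, n)
        noise = rng.normal(0, 0.5, n)
        pairs = list(zip(raw, 1.3 * raw - 4.0 + noise))
        _, cmap = remap_coordinate(PMF(np.linspace(0, 50, 11), np.zeros(11)),
                                   pairs)
        se = 0.5 / np.sqrt(np.sum((raw - raw.mean()) ** 2))
        assert abs(cmap.slope - 1.3) < 3 * se

    def test_window_spring_constant_rescaled(self):
        w = UmbrellaWindow(np.array([10.0, 11.0, 12.0]), 11.0, 2.0)
        (out,), cmap = remap_coordinate(w, [(10.0, 20.0), (12.0, 24.0)])
        assert cmap.slope == pytest.approx(2.0)
        assert out.spring_k == pytest.approx(0.5)   # k / a^2
        assert out.center == pytest.approx(22.0)

    def test_degenerate_raw_rejected(self):
        with pytest.raises(ValueError):
            remap_coordinate(PMF(np.arange(3.0), np.zeros(3)),
                             [(5.0, 1.0), (5.0, 2.0)])


class TestAlignOffsets:
    def test_identical_pmfs_zero_shift(self):
        grid = np.linspace(30, 45, 16)
        p = PMF(grid, np.sin(grid))
        _, _, shift = align_offsets(p, PMF(grid, np.sin(grid)), (40.0, 45.0))
        assert shift == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_removed(self):
        grid = np.linspace(30, 45, 16)
        a = PMF(grid, np.cos(grid))
        b = PMF(grid, np.cos(grid) + 3.0)
        _, b2, shift = align_offsets(a, b, (38.0, 44.0))
        assert shift == pytest.approx(-3.0)
        np.testing.assert_allclose(b2.F, a.F, atol=1e-12)

    def test_plateau_mean_difference(self):
        grid = np.linspace(0, 10, 11)
        a = PMF(grid, np.where(grid < 5, 2.0, 1.0))
        b = PMF(grid, np.where(grid < 5, 7.0, 4.5))
        _, b2, shift = align_offsets(a, b, (6.0, 10.0))
        assert shift == pytest.approx(1.0 - 4.5)
        assert b2.F[-1] == pytest.approx(1.0)

    def test_no_overlap_rejected(self):
        grid = np.linspace(0, 10, 11)
        with pytest.raises(ValueError):
            align_offsets(PMF(grid, grid), PMF(grid, grid), (20.0, 30.0))


def _pmf(grid, values, **kw):
    return PMF(np.asarray(grid, float), np.asarray(values, float), **kw)


class TestBuildLandscape:
    GRID = np.arange(30.0, 45.0, 1.0)

    def test_degenerate_interpolation_is_simple_sum(self):
        fl = _pmf(self.GRID, np.sin(self.GRID))
        fr = _pmf(self.GRID, np.cos(self.GRID))
        surf = build_landscape((fl, fl), (fr, fr), bound_ref=(34.0, 31.0),
                               unbound_ref=(40.0, 40.0))
        expected = fl.interp(surf.x_left)[:, None] + fr.interp(surf.x_right)[None, :]
        np.testing.assert_allclose(surf.F, expected, atol=1e-12)

    def test_bound_endpoint_reproduces_bound_pmf(self):
        fl_b = _pmf(self.GRID, np.sin(self.GRID))
        fl_a = _pmf(self.GRID, np.sin(self.GRID) + 2.0)
        fr = _pmf(self.GRID, np.zeros(len(self.GRID)))
        surf = build_landscape((fl_b, fl_a), (fr, fr), bound_ref=(34.0, 31.0),
                               unbound_ref=(40.0, 40.0))
        j = int(np.argmin(np.abs(surf.x_right - 31.0)))   # x_R at bound ref
        np.testing.assert_allclose(surf.F[:, j], fl_b.interp(surf.x_left),
                                   atol=1e-12)

    def test_midpoint_is_arithmetic_mean(self):
        fl_b = _pmf(self.GRID, np.linspace(0, 5, len(self.GRID)))
        fl_a = _pmf(self.GRID, np.linspace(5, 0, len(self.GRID)))
        fr = _pmf(self.GRID, np.zeros(len(self.GRID)))
        surf = build_landscape((fl_b, fl_a), (fr, fr), bound_ref=(34.0, 30.0),
                               unbound_ref=(40.0, 40.0))
        j = int(np.argmin(np.abs(surf.x_right - 35.0)))   # lambda_R = 0.5
        expected = 0.5 * (fl_b.interp(surf.x_left) + fl_a.interp(surf.x_left))
        np.testing.assert_allclose(surf.F[:, j], expected, atol=1e-12)


class TestBoltzmann:
    def test_flat_surface_uniform(self):
        surf = FreeEnergySurface(np.arange(5.0), np.arange(4.0),
                                 np.zeros((5, 4)))
        ps = boltzmann_probabilities(surf)
        assert np.allclose(ps.P, 1.0 / 20)
        assert ps.P.sum() == pytest.approx(1.0, abs=1e-12)
        assert (ps.density * ps.cell_area).sum() == pytest.approx(1.0, abs=1e-9)

    def test_kbt_ln2_gives_ratio_two(self):
        F = np.array([[0.0, KT300 * np.log(2)]])
        surf = FreeEnergySurface(np.array([0.0]), np.array([0.0, 1.0]), F)
        ps = boltzmann_probabilities(surf, temperature_K=300.0)
        assert ps.P[0, 0] / ps.P[0, 1] == pytest.approx(2.0, rel=1e-12)

    def test_deep_well_dominates(self):
        F = np.full((10, 10), 50.0)
        F[3, 4] = 0.0
        surf = FreeEnergySurface(np.arange(10.0), np.arange(10.0), F)
        ps = boltzmann_probabilities(surf)
        assert 1.0 - ps.P[3, 4] < 1e-30

    def test_all_infinite_rejected(self):
        surf = FreeEnergySurface(np.arange(3.0), np.arange(3.0),
                                 np.full((3, 3), np.inf))
        with pytest.raises(ValueError):
            boltzmann_probabilities(surf)


class TestStateProbabilities:
    @staticmethod
    def _uniform_psurface(n=10):
        surf = FreeEnergySurface(np.arange(float(n)), np.arange(float(n)),
                                 np.zeros((n, n)))
        return boltzmann_probabilities(surf)

    def test_single_state_covering_grid_is_100(self):
        ps = self._uniform_psurface()
        pts = np.array([[i, j] for i in range(10) for j in range(10)],
                       dtype=float)
        probs = state_probabilities(ps, {"all": pts})
        assert probs["all"] == pytest.approx(100.0)

    def test_disjoint_supports_proportional_to_area(self):
        ps = self._uniform_psurface()
        a = np.array([[i, j] for i in range(3) for j in range(10)], dtype=float)
        b = np.array([[i, j] for i in range(3, 10) for j in range(10)],
                     dtype=float)
        probs = state_probabilities(ps, {"a": a, "b": b})
        assert probs["a"] == pytest.approx(30.0, abs=1e-9)
        assert probs["b"] == pytest.approx(70.0, abs=1e-9)

    def test_matches_brute_force_cell_summation(self, rng):
        n = 12
        F = rng.uniform(0, 3, size=(n, n))
        surf = FreeEnergySurface(np.arange(float(n)), np.arange(float(n)), F)
        ps = boltzmann_probabilities(surf)
        clouds = {
            "s1": rng.normal([3, 3], 1.2, size=(200, 2)),
            "s2": rng.normal([8, 4], 1.0, size=(150, 2)),
            "s3": rng.normal([5, 9], 1.1, size=(250, 2)),
        }
        probs = state_probabilities(ps, clouds)
        # independent cell-by-cell summation
        hists = {}
        for name, pts in clouds.items():
            hmat = np.zeros((n, n))
            for x, y in pts:
                i, j = int(round(x)), int(round(y))
                if 0 <= i < n and 0 <= j < n:
                    hmat[i, j] += 1
            hists[name] = hmat
        tot = sum(hists.values())
        raw = {}
        for name, hmat in hists.items():
            acc = 0.0
            for i in range(n):
                for j in range(n):
                    if tot[i, j] > 0:
                        acc += ps.P[i, j] * hmat[i, j] / tot[i, j]
            raw[name] = acc
        norm = sum(raw.values())
        for name in clouds:
            assert probs[name] == pytest.approx(100 * raw[name] / norm,
                                                abs=1e-9)
        assert sum(probs.values()) == pytest.approx(100.0, abs=0.01)

    def test_state_outside_grid_rejected(self):
        ps = self._uniform_psurface()
        with pytest.raises(ValueError, match="far"):
            state_probabilities(ps, {"far": np.array([[100.0, 100.0]])})


class TestFreeEnergyDifference:
    def test_same_region_zero(self):
        pmf = PMF(np.arange(10.0), np.linspace(0, 3, 10))
        region = pmf.grid < 5
        assert free_energy_difference(pmf, region, region) == pytest.approx(0.0)

    def test_two_single_cells_definition(self):
        pmf = PMF(np.arange(2.0), np.array([0.0, 5.0]))
        dF = free_energy_difference(pmf, np.array([True, False]),
                                    np.array([False, True]))
        assert dF == pytest.approx(5.0, rel=1e-9)

    def test_multi_cell_basins_hand_summed(self):
        F = np.array([0.0, 0.5, 4.0, 3.5])
        pmf = PMF(np.arange(4.0), F)
        a = np.array([True, True, False, False])
        b = np.array([False, False, True, True])
        beta = 1.0 / KT300
        expected = -np.log((np.exp(-beta * 4.0) + np.exp(-beta * 3.5))
                           / (np.exp(-beta * 0.0) + np.exp(-beta * 0.5))) / beta
        assert free_energy_difference(pmf, a, b) == pytest.approx(expected,
                                                                  rel=1e-9)

    def test_empty_region_rejected(self):
        pmf = PMF(np.arange(4.0), np.zeros(4))
        with pytest.raises(ValueError):
            free_energy_difference(pmf, np.zeros(4, bool), np.ones(4, bool))
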