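"""Reweighting weights, weighted free-energy histograms, persistence-based
minima detection and convergence diagnostics."""

import numpy as np
import pytest

from essmeta.constants import KB
from essmeta.fes import (FESProfile, convergence_series, find_minima,
                         frame_weights, weighted_fes)
from essmeta.metad import HillsLog

T = 310.0
KT = KB * T


class TestFrameWeights:
    def test_zero_bias_uniform(self):
        w = frame_weights(np.linspace(-1, 1, 10), np.linspace(0, 9, 10),
                          HillsLog(), T)
        assert np.allclose(w, 0.1)

    def test_kbt_difference_gives_ratio_e(self):
        # single hill of height kBT at s=0: V(0)=kBT, V(far)≈0
        hills = HillsLog([1.0], [0.0], [0.1], [KT])
        w = frame_weights(np.array([0.0, 50.0]), np.array([0.5, 1.0]), hills, T)
        assert w[0] / w[1] == pytest.approx(np.e, rel=1e-12)

    def test_weights_positive_and_normalized(self):
        rng = np.random.default_rng(1)
        hills = HillsLog(np.arange(20) + 1.0, rng.uniform(-1, 1, 20),
                         np.full(20, 0.1), rng.uniform(0.05, 0.2, 20))
        s = rng.uniform(-1, 1, 100)
        t = np.sort(rng.uniform(0, 20, 100))
        w = frame_weights(s, t, hills, T)
        assert np.all(w > 0)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_frame_time_outside_span_rejected(self):
        hills = HillsLog([1.0, 2.0], [0.0, 0.1], [0.1, 0.1], [0.2, 0.2])
        with pytest.raises(ValueError, match="time span"):
            frame_weights(np.array([0.0]), np.array([100.0]), hills, T)

    def test_running_scheme_agrees_with_final_on_converged_run(
            self, benchmark_run, benchmark):
        w_final = frame_weights(benchmark_run.cv, benchmark_run.times,
                                benchmark_run.hills, T, scheme="final")
        w_run = frame_weights(benchmark_run.cv, benchmark_run.times,
                              benchmark_run.hills, T, scheme="running")
        f1 = weighted_fes(benchmark_run.cv, w_final, T, bins=60)
        f2 = weighted_fes(benchmark_run.cv, w_run, T, bins=60)
        both = f1.mask & f2.mask & (f1.values < 10)
        # profiles are defined up to an additive constant
        d = f1.values[both] - f2.values[both]
        assert np.abs(d - d.mean()).max() < 1.0

    def test_reweighted_mean_matches_unbiased_oracle(self, benchmark_run,
                                                     benchmark):
        from essmeta.metad import MetadParams, run_wtmetad
        w = frame_weights(benchmark_run.cv, benchmark_run.times,
                          benchmark_run.hills, T)
        mean_biased = float(w @ benchmark_run.cv)
        unb = run_wtmetad(benchmark,
                          params=MetadParams(deposition_rate=0.0,
                                             temperature=T),
                          n_steps=benchmark_run.theta_full.size, seed=99,
                          stride=40, dt=0.002, friction=10.0)
        x = unb.theta_full[::40]
        se = x.std() / np.sqrt(200.0)  # generous effective-sample estimate
        assert abs(mean_biased - x.mean()) < 3 * max(se, 0.02)


class TestWeightedFes:
    def test_symmetric_bimodal_equal_minima(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(-1, 0.15, 40000),
                            rng.normal(1, 0.15, 40000)])
        prof = weighted_fes(x, np.full(x.size, 1 / x.size), T, bins=60)
        grid = prof.axes[0][1]
        left = prof.values[prof.mask & (grid < 0)].min()
        right = prof.values[prof.mask & (grid > 0)].min()
        assert abs(left - right) < 0.3

    def test_boltzmann_sample_recovers_potential(self):
        # exact Boltzmann draw from a known 1D potential
        rng = np.random.default_rng(3)
        grid = np.linspace(-1.8, 1.8, 601)
        u = 4.0 * (grid ** 2 - 1) ** 2
        p = np.exp(-u / KT)
        p /= p.sum()
        x = rng.choice(grid, size=400_000, p=p)
        x = x + rng.uniform(-0.003, 0.003, x.size)  # de-discretize
        prof = weighted_fes(x, np.full(x.size, 1 / x.size), T, bins=80)
        centers = prof.axes[0][1]
        exact = 4.0 * (centers ** 2 - 1) ** 2
        exact -= exact.min()
        sel = prof.mask & (exact < 10)
        assert np.abs(prof.values[sel] - exact[sel]).max() < 0.5

    def test_2d_separable_marginals(self):
        rng = np.random.default_rng(4)
        # independent Boltzmann coordinates: quartic in x, harmonic in y
        gx = np.linspace(-1.6, 1.6, 401)
        ux = 6.0 * (gx ** 2 - 1) ** 2
        px = np.exp(-ux / KT)
        px /= px.sum()
        x = rng.choice(gx, 300_000, p=px) + rng.uniform(-0.004, 0.004, 300_000)
        ky = 80.0
        y = rng.normal(0.0, np.sqrt(KT / ky), 300_000)
        prof = weighted_fes(np.column_stack([x, y]),
                            np.full(x.size, 1 / x.size), T, bins=(40, 40))
        # marginalize the 2D probability back to 1D free energies
        pxy = np.where(prof.mask, np.exp(-prof.values / KT), 0.0)
        fx = -KT * np.log(pxy.sum(axis=1))
        fx -= fx.min()
        cx = prof.axes[0][1]
        exact_x = 6.0 * (cx ** 2 - 1) ** 2
        exact_x -= exact_x.min()
        sel = (exact_x < 8) & np.isfinite(fx)
        assert np.abs(fx[sel] - exact_x[sel]).max() < 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_fes(np.ones(5), np.ones(4), T)

    def test_min_is_zero_and_masked_cells_flagged(self):
        x = np.array([0.0, 0.0, 1.0])
        prof = weighted_fes(x, np.full(3, 1 / 3), T, bins=10)
        assert prof.values[prof.mask].min() == 0.0
        assert not prof.mask.all()


class TestFindMinima:
    def test_single_parabola(self):
        x = np.linspace(-1, 1, 81)
        prof = FESProfile([("x", x)], 30.0 * x ** 2, np.ones_like(x, bool))
        report = find_minima(prof, min_depth=2.0, smooth_sigma=0.0)
        assert len(report) == 1
        assert report[0].location[0] == pytest.approx(0.0, abs=0.03)
        assert report[0].value == 0.0

    def test_planted_double_well_depths(self, domain):
        """The planted 36/4 kJ/mol hinge landscape is recovered exactly on
        an analytic grid."""
        th = np.linspace(np.radians(50), np.radians(112), 400)
        f = domain.potential.energy(th)
        prof = FESProfile([("theta_deg", np.degrees(th))], f - f.min(),
                          np.ones_like(f, bool))
        report = find_minima(prof, min_depth=2.0, smooth_sigma=0.0)
        assert len(report) == 2
        deepest, second = report[0], report[1]
        assert deepest.location[0] == pytest.approx(63.0, abs=0.2)
        assert deepest.depth == pytest.approx(36.0, abs=0.2)
        assert second.location[0] == pytest.approx(100.0, abs=0.2)
        assert second.depth == pytest.approx(4.0, abs=0.2)

    def test_threshold_above_all_depths_empty(self, domain):
        th = np.linspace(np.radians(50), np.radians(112), 200)
        f = domain.potential.energy(th)
        prof = FESProfile([("theta_deg", np.degrees(th))], f - f.min(),
                          np.ones_like(f, bool))
        assert len(find_minima(prof, min_depth=50.0, smooth_sigma=0.0)) == 0

    def test_2d_double_well(self):
        x = np.linspace(-1.5, 1.5, 61)
        y = np.linspace(-1.0, 1.0, 41)
        xx, yy = np.meshgrid(x, y, indexing="ij")
        f = 10.0 * (xx ** 2 - 1) ** 2 + 3.0 * xx + 15.0 * yy ** 2
        f -= f.min()
        prof = FESProfile([("x", x), ("y", y)], f, np.ones_like(f, bool))
        report = find_minima(prof, min_depth=2.0, smooth_sigma=0.0)
        assert len(report) == 2
        assert report[0].location[0] == pytest.approx(-1.0, abs=0.15)
        assert report[1].location[0] == pytest.approx(1.0, abs=0.15)
        # wells separated by the saddle at x≈0: depth of the shallow well
        # ≈ barrier − asymmetry
        assert report[1].depth == pytest.approx(
            (10.0 * 1 + 3.0 * 0) - 3.0 * 1 - (10.0 * 0), abs=1.0)


class TestConvergence:
    def _toy_hills(self):
        # stationary bias: same hill repeated
        n = 30
        return HillsLog(np.arange(n) + 1.0, np.zeros(n), np.full(n, 0.3),
                        np.full(n, 0.1), bias_factor=20.0)

    def test_stationary_bias_constant_delta_f(self):
        # basin bounds padded off the grid nodes so both basins contain
        # exactly mirrored grid points
        df = convergence_series(self._toy_hills(), 20.0, (-1.205, -0.795),
                                (0.795, 1.205), np.array([10.0, 20.0, 30.0]),
                                grid=np.linspace(-1.5, 1.5, 301))
        vals = df["delta_f"].to_numpy()
        # hills pile up at 0, symmetric wells stay degenerate
        assert np.abs(np.diff(vals)).max() < 1e-9
        assert df.attrs["converged"]

    def test_swapping_basins_flips_sign(self):
        hills = self._toy_hills()
        grid = np.linspace(-1.5, 1.5, 301)
        cps = np.array([10.0, 30.0])
        a = convergence_series(hills, 20.0, (-1.205, -0.795), (0.795, 1.205),
                               cps, grid=grid)["delta_f"].to_numpy()
        b = convergence_series(hills, 20.0, (0.795, 1.205), (-1.205, -0.795),
                               cps, grid=grid)["delta_f"].to_numpy()
        assert np.allclose(a, -b)

    def test_benchmark_delta_f_converges_to_asymmetry(self, benchmark_run):
        """A single finite run's ΔF(t) oscillates around the planted
        asymmetry; the seed-averaged final estimate lands within ±1."""
        from essmeta.metad import MetadParams, run_wtmetad
        from essmeta.surrogate import benchmark_double_well

        finals = []
        runs = [benchmark_run]
        bench = benchmark_double_well(15.0, 3.0)
        for seed in (12, 13):
            runs.append(run_wtmetad(
                bench, params=benchmark_run.params, n_steps=600_000,
                seed=seed, stride=40, dt=0.002, friction=10.0))
        for run in runs:
            t_max = run.hills.times.max()
            df = convergence_series(run.hills, 20.0, (0.7, 1.3), (-1.3, -0.7),
                                    np.linspace(t_max / 5, t_max, 5))
            finals.append(df["delta_f"].iloc[-1])
        assert np.mean(finals) == pytest.approx(3.0, abs=1.0)

    def test_unsampled_basin_rejected(self):
        with pytest.raises(ValueError, match="basin"):
            convergence_series(self._toy_hills(), 20.0, (5.0, 6.0), (0, 1),
                               np.array([10.0, 30.0]),
                               grid=np.linspace(-1.5, 1.5, 301))
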