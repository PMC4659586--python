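"""FES estimators: bias integration, reweighting offset, basin dG."""
import numpy as np
import pytest
from scipy import integrate

import ptmetad as pm
from ptmetad.fes import FreeEnergySurface
from ptmetad.hills import HillsLog
from ptmetad.units import KB, kj_to_kcal


def empty_hills(d=1, temperature=305.0):
    return HillsLog(times=np.empty(0), centers=np.empty((0, d)),
                    widths=np.empty((0, d)), heights=np.empty(0),
                    bias_factor=5.0, temperature=temperature,
                    cv_names=tuple(f"x{i}" for i in range(d)))


class TestFesFromBias:
    def test_two_node_algebra(self):
        # gamma 5 and V = {0, 4} at two nodes -> F = {5, 0} after min shift
        log = HillsLog(times=[1.0], centers=[[1.0]], widths=[[1e-4]],
                       heights=[4.0], bias_factor=5.0, temperature=305.0)
        axes = [np.array([0.0, 1.0])]
        f = pm.fes_from_bias(log, axes)
        assert f.values == pytest.approx([5.0, 0.0], abs=1e-12)

    def test_uniform_bias_flat_surface(self):
        log = HillsLog(times=[1.0], centers=[[0.0]], widths=[[1e6]],
                       heights=[2.0], bias_factor=5.0, temperature=305.0)
        f = pm.fes_from_bias(log, [np.linspace(-1, 1, 11)])
        assert np.all(np.abs(f.values) < 1e-9)

    def test_rejects_gamma_below_one(self):
        with pytest.raises(ValueError):
            pm.fes_from_bias(empty_hills(), [np.linspace(-1, 1, 5)],
                             gamma=1.0)

    def test_recovers_double_well_profile_and_delta_g(self, double_well_run):
        pot, res, axes = double_well_run
        f = pm.fes_from_bias(res.hills, axes)
        x = axes[0]
        u = pot.energy(x[:, None])
        ref = u - u.min()
        m = ref < 8.0      # compare over the thermally relevant region
        shift = np.mean(f.values[m] - ref[m])
        assert np.max(np.abs(f.values[m] - ref[m] - shift)) < 1.5
        # basin free-energy difference against the quadrature oracle
        basins = pm.basins_from_ground_truth(pot)
        dg = pm.basin_delta_g(f, basins["in"], basins["out"])
        exact = -kj_to_kcal(pot.ground_truth["delta_f"](305.0))
        assert dg == pytest.approx(exact, abs=kj_to_kcal(1.0))


class TestRctOffset:
    def test_zero_bias_gives_zero(self):
        assert pm.rct_offset(empty_hills(), [np.linspace(-1, 1, 21)],
                             time=10.0) == 0.0

    def test_constant_bias_gives_bias_value(self):
        log = HillsLog(times=[1.0], centers=[[0.0]], widths=[[1e6]],
                       heights=[3.3], bias_factor=5.0, temperature=305.0)
        c = pm.rct_offset(log, [np.linspace(-0.5, 0.5, 41)], time=2.0)
        assert c == pytest.approx(3.3, abs=1e-9)

    def test_matches_quadrature_of_definition(self):
        rng = np.random.default_rng(5)
        n = 8
        log = HillsLog(times=np.arange(1.0, n + 1),
                       centers=rng.uniform(-1, 1, (n, 1)),
                       widths=np.full((n, 1), 0.4),
                       heights=rng.uniform(0.5, 1.5, n),
                       bias_factor=5.0, temperature=305.0)
        lo, hi = -2.0, 2.0
        axes = [np.linspace(lo, hi, 4001)]
        c = pm.rct_offset(log, axes, time=n + 1.0)
        b = 1.0 / (KB * 305.0)
        g = 5.0 / 4.0

        def vfun(x):
            return pm.evaluate_bias(log, np.array([x]))

        num, _ = integrate.quad(lambda x: np.exp(g * b * vfun(x)), lo, hi,
                                limit=400)
        den, _ = integrate.quad(lambda x: np.exp(b * vfun(x) / 4.0), lo, hi,
                                limit=400)
        # the grid-node sum and the integral share the constant cell factor
        expected = (np.log(num) - np.log(den)) / b
        assert c == pytest.approx(expected, abs=1e-6)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            pm.rct_series(empty_hills(), [])


class TestReweight:
    def test_unbiased_input_reduces_to_histogram(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(4000) * 0.5
        times = np.arange(4000.0)
        axes = [np.linspace(-2, 2, 41)]
        f = pm.reweight_fes(x[:, None], times, empty_hills(), x[:, None],
                            axes)
        edges = np.concatenate([axes[0] - 0.05, [axes[0][-1] + 0.05]])
        hist, _ = np.histogram(x, bins=edges)
        with np.errstate(divide="ignore"):
            ref = -KB * 305.0 * np.log(hist.astype(float))
        ref[hist == 0] = np.inf
        finite = np.isfinite(ref)
        assert np.allclose(f.values[finite],
                           (ref - ref[finite].min())[finite], atol=1e-10)
        assert np.all(~np.isfinite(f.values[~finite]))

    def test_agrees_with_bias_integration(self, double_well_run):
        pot, res, axes = double_well_run
        basins = pm.basins_from_ground_truth(pot)
        fb = pm.fes_from_bias(res.hills, axes)
        fr = pm.reweight_fes(res.cv_series, res.trajectory.times, res.hills,
                             res.cv_series, axes)
        dg_b = pm.basin_delta_g(fb, basins["in"], basins["out"])
        dg_r = pm.basin_delta_g(fr, basins["in"], basins["out"])
        assert abs(dg_b - dg_r) < 0.3     # kcal/mol, the S11-style cross-check

    def test_orthogonal_cv_of_separable_system(self):
        # bias x of U(x) + U(y); reweight onto y must give the y free energy
        dw = pm.make_double_well(8.0, 2.0)
        k = 6.0

        def energy(v):
            xy = np.asarray(v, dtype=float)
            return dw.energy(xy[..., :1]) + 0.5 * k * xy[..., 1] ** 2

        def gradient(v):
            xy = np.asarray(v, dtype=float)
            g = np.empty_like(xy)
            g[..., :1] = dw.gradient(xy[..., :1])
            g[..., 1] = k * xy[..., 1]
            return g

        pot = pm.ModelPotential(
            dimension=2, energy=energy, gradient=gradient,
            domain=(np.array([-2.5, -3.0]), np.array([2.5, 3.0])),
            ground_truth={"minima": [np.array([-1.0, 0.0])]})
        params = pm.MetadParams(height=1.2, widths=(0.1,),
                                deposition_stride=500, bias_factor=8.0,
                                temperature=305.0)
        cfg = pm.SamplerConfig(temperature=305.0, n_steps=400_000, seed=31,
                               save_stride=50)
        res = pm.run_wtmetad(pot, [pm.CoordinateCV(0)], params, cfg,
                             grid_bounds=(np.array([-2.5]), np.array([2.5])))
        y = res.trajectory.positions[:, 1]
        axes_y = [np.linspace(-1.5, 1.5, 61)]
        f = pm.reweight_fes(res.cv_series, res.trajectory.times, res.hills,
                            y[:, None], axes_y)
        ref = 0.5 * k * axes_y[0] ** 2
        m = np.isfinite(f.values) & (ref < 6.0)
        shift = np.mean(f.values[m] - ref[m])
        assert np.max(np.abs(f.values[m] - ref[m] - shift)) < 0.3 * 4.184

    def test_frames_without_bias_values_rejected(self):
        with pytest.raises(ValueError):
            pm.reweight_fes(np.zeros((5, 1)), np.arange(4.0), empty_hills(),
                            np.zeros((5, 1)), [np.linspace(-1, 1, 5)])


class TestBasinDeltaG:
    def _fes_from_potential(self, pot, axes, T=300.0):
        u = pot.energy(axes[0][:, None])
        return FreeEnergySurface(axes=tuple(axes), values=u - u.min(),
                                 temperature=T, estimator="analytic")

    def test_symmetric_double_well_zero(self):
        pot = pm.make_double_well(10.0, 0.0)
        axes = [np.linspace(-2.4, 2.4, 481)]
        f = self._fes_from_potential(pot, axes)
        basins = pm.basins_from_ground_truth(pot)
        dg = pm.basin_delta_g(f, basins["in"], basins["out"], 300.0)
        assert dg == pytest.approx(0.0, abs=1e-6)

    def test_curvature_ratio_four_gives_analytic_entropy(self):
        # equal minima, curvature ratio 4 -> dG = (kB 300/2) ln 4
        pot = pm.make_entropy_pair(pm.TwoBasinSpec(width_ratio=4.0,
                                                   delta_e=0.0))
        axes = [np.linspace(pot.domain[0][0], pot.domain[1][0], 2001)]
        f = self._fes_from_potential(pot, axes)
        basins = pm.basins_from_ground_truth(pot)
        dg = pm.basin_delta_g(f, basins["narrow"], basins["wide"], 300.0)
        assert dg == pytest.approx(kj_to_kcal(0.5 * KB * 300 * np.log(4.0)),
                                   abs=0.01)

    def test_gauge_invariance(self):
        rng = np.random.default_rng(1)
        axes = (np.linspace(-1, 1, 51),)
        vals = rng.uniform(0, 10, 51)
        a = pm.BasinSpec("a", {0: (-1.0, -0.2)})
        b = pm.BasinSpec("b", {0: (0.2, 1.0)})
        f1 = FreeEnergySurface(axes, vals, 300.0, "x")
        f2 = FreeEnergySurface(axes, vals + 123.456, 300.0, "x")
        assert pm.basin_delta_g(f1, a, b) == pytest.approx(
            pm.basin_delta_g(f2, a, b), abs=1e-10)

    def test_empty_basin_error_names_basin(self):
        axes = (np.linspace(-1, 1, 11),)
        vals = np.full(11, np.inf)
        vals[:3] = 0.0
        f = FreeEnergySurface(axes, vals, 300.0, "x")
        a = pm.BasinSpec("sampled", {0: (-1.0, -0.5)})
        b = pm.BasinSpec("unsampled", {0: (0.5, 1.0)})
        with pytest.raises(ValueError, match="unsampled"):
            pm.basin_delta_g(f, a, b)

    def test_grid_refinement_stability(self, double_well_run):
        pot, res, _ = double_well_run
        basins = pm.basins_from_ground_truth(pot)
        dgs = []
        for n in (221, 441):
            f = pm.fes_from_bias(res.hills, [np.linspace(-2.2, 2.2, n)])
            dgs.append(pm.basin_delta_g(f, basins["in"], basins["out"]))
        assert abs(dgs[0] - dgs[1]) < 0.05


class TestConvergence:
    def test_converged_run_reported_converged(self, double_well_run):
        pot, res, axes = double_well_run
        basins = pm.basins_from_ground_truth(pot)
        rep = pm.convergence_profile(res.hills, res.cv_series,
                                     res.trajectory.times, axes,
                                     basins["in"], basins["out"],
                                     interval=800.0)
        assert rep.converged
        assert rep.spread_bias < 0.3
        assert rep.spread_reweight < 0.3
        assert rep.agreement < 0.3

    def test_truncated_run_not_converged(self, double_well_run):
        pot, res, axes = double_well_run
        basins = pm.basins_from_ground_truth(pot)
        t_cut = res.trajectory.times[-1] * 0.05
        keep = res.trajectory.times <= t_cut
        n_h = int(np.searchsorted(res.hills.times, t_cut))
        hills = HillsLog(times=res.hills.times[:n_h],
                         centers=res.hills.centers[:n_h],
                         widths=res.hills.widths[:n_h],
                         heights=res.hills.heights[:n_h],
                         bias_factor=res.hills.bias_factor,
                         temperature=res.hills.temperature,
                         cv_names=res.hills.cv_names)
        rep = pm.convergence_profile(hills, res.cv_series[keep],
                                     res.trajectory.times[keep], axes,
                                     basins["in"], basins["out"],
                                     interval=t_cut / 5.0)
        assert not rep.converged

    def test_basin_visit_counts(self, double_well_run):
        pot, res, _ = double_well_run
        basins = pm.basins_from_ground_truth(pot)
        counts = pm.count_basin_visits(res.cv_series,
                                       list(basins.values()))
        assert all(v >= 3 for v in counts.values())


def test_fes_surface_validation():
    with pytest.raises(ValueError):
        FreeEnergySurface((np.linspace(0, 1, 5),), np.zeros(4), 300.0, "x")
    with pytest.raises(ValueError):
        FreeEnergySurface((np.linspace(0, 1, 3),), np.full(3, np.inf),
                          300.0, "x")
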