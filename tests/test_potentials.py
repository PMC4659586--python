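"""Model potentials: gradient consistency, quadrature oracles, determinism."""
import numpy as np
import pytest
from scipy import integrate

import ptmetad as pm
from ptmetad.potentials import finite_difference_gradient
from ptmetad.units import KB


def _factory_zoo():
    return {
        "double_well": pm.make_double_well(10.0, 4.0),
        "entropy_pair": pm.make_entropy_pair(),
        "dihedral_flip": pm.make_dihedral_flip_system(
            3, [0.0, 0.5, 1.0], [np.pi, 0.5 + np.pi, 1.0 + np.pi],
            coupling=1.0, asymmetry=5.0),
        "two_channel": pm.make_two_channel_binding_potential(),
    }


@pytest.mark.parametrize("name", list(_factory_zoo()))
def test_gradient_matches_finite_difference(name):
    pot = _factory_zoo()[name]
    rng = np.random.default_rng(42)
    lo, hi = pot.domain
    pts = rng.uniform(lo, hi, size=(25, pot.dimension))
    g = pot.gradient(pts)
    fd = np.array([finite_difference_gradient(pot, p) for p in pts])
    scale = np.maximum(np.abs(fd), 1.0)
    assert np.all(np.abs(g - fd) / scale < 1e-5)


@pytest.mark.parametrize("name", list(_factory_zoo()))
def test_energy_finite_and_confined(name):
    pot = _factory_zoo()[name]
    rng = np.random.default_rng(7)
    lo, hi = pot.domain
    pts = rng.uniform(lo, hi, size=(200, pot.dimension))
    assert np.all(np.isfinite(pot.energy(pts)))
    if not any(pot.periodic):
        # outside the domain the energy climbs (confining growth)
        inside = pot.energy(0.5 * (lo + hi))
        outside = pot.energy(hi + 0.5 * (hi - lo))
        assert outside > inside + 10.0


class TestDoubleWell:
    def test_symmetric_delta_f_zero(self):
        pot = pm.make_double_well(10.0, 0.0)
        for t in (280.0, 305.0, 400.0):
            assert abs(pot.ground_truth["delta_f"](t)) < 1e-9

    def test_minima_positions_and_energy(self):
        pot = pm.make_double_well(10.0, 0.0)
        for x in (-1.0, 1.0):
            assert pot.energy(np.array([x])) == pytest.approx(0.0, abs=1e-12)
            assert abs(pot.gradient(np.array([x]))[0]) < 1e-12

    def test_delta_f_matches_independent_riemann_oracle(self):
        # independent oracle: plain Riemann sum, not the packaged quad-based one
        pot = pm.make_double_well(10.0, 4.0)
        T = 305.0
        sep = pot.ground_truth["separatrix"]
        x = np.linspace(-2.5, 2.5, 200001)
        w = np.exp(-pot.energy(x[:, None]) / (KB * T))
        za = w[x < sep].sum()
        zb = w[x >= sep].sum()
        expected = -KB * T * np.log(zb / za)
        assert pot.ground_truth["delta_f"](T) == pytest.approx(
            expected, abs=1e-4)
        assert pot.ground_truth["delta_f_table"][T] == pytest.approx(
            expected, abs=1e-4)

    def test_rejects_nonpositive_barrier(self):
        with pytest.raises(ValueError, match="barrier_height"):
            pm.make_double_well(-1.0)


class TestEntropyPair:
    def test_identical_basins_give_zero_delta_f(self):
        pot = pm.make_entropy_pair(pm.TwoBasinSpec(width_ratio=1.0,
                                                   delta_e=0.0))
        for t in (280.0, 305.0, 400.0):
            assert abs(pot.ground_truth["delta_f"](t)) < 5e-3

    def test_width_ratio_entropy_harmonic_value(self):
        # width ratio 4, equal minima: dF(300) = (kB 300/2) ln 4
        pot = pm.make_entropy_pair(pm.TwoBasinSpec(width_ratio=4.0,
                                                   delta_e=0.0))
        expected = 0.5 * KB * 300.0 * np.log(4.0)
        assert pot.ground_truth["delta_f"](300.0) == pytest.approx(
            expected, abs=0.05)
        assert pot.ground_truth["delta_s_harmonic"] == pytest.approx(
            -0.5 * KB * np.log(4.0))

    def test_quadrature_line_recovers_enthalpy_entropy(self):
        pot = pm.make_entropy_pair()   # delta_e 8.368 kJ/mol, ratio 4
        ts = np.array([305.0, 328.75, 352.5, 376.25, 400.0])
        dfs = np.array([pot.ground_truth["delta_f"](t) for t in ts])
        slope, intercept = np.polyfit(ts, dfs, 1)
        assert intercept == pytest.approx(8.368, abs=0.1)
        assert slope * 305.0 == pytest.approx(
            0.5 * KB * 305.0 * np.log(4.0), abs=0.1)

    def test_oracle_reproducible_against_quad(self):
        pot = pm.make_entropy_pair()
        gt = pot.ground_truth
        T = 330.0
        sep = gt["separatrix"]
        lo, hi = pot.domain[0][0], pot.domain[1][0]

        def boltz(x):
            return np.exp(-pot.energy(np.array([x])) / (KB * T))

        za, _ = integrate.quad(boltz, lo, sep, limit=300)
        zb, _ = integrate.quad(boltz, sep, hi, limit=300)
        assert gt["delta_f"](T) == pytest.approx(
            -KB * T * np.log(zb / za), abs=0.01)

    def test_rejects_bad_width_ratio(self):
        with pytest.raises(ValueError, match="width_ratio"):
            pm.TwoBasinSpec(width_ratio=-1.0)


class TestDihedralFlip:
    def test_reference_states_are_exact_minima(self):
        ref_in = np.array([0.0, 0.5, 1.0])
        ref_out = ref_in + np.pi
        pot = pm.make_dihedral_flip_system(3, ref_in, ref_out,
                                           coupling=1.0, asymmetry=5.0)
        for ref in (ref_in, ref_out):
            assert np.max(np.abs(pot.gradient(ref))) < 1e-8

    def test_periodic_in_every_angle(self):
        pot = pm.make_dihedral_flip_system(2, [0.2, -0.4], [2.0, 2.6],
                                           coupling=0.7)
        rng = np.random.default_rng(5)
        th = rng.uniform(-np.pi, np.pi, size=(20, 2))
        for k in range(2):
            shifted = th.copy()
            shifted[:, k] += 2 * np.pi
            assert np.allclose(pot.energy(th), pot.energy(shifted),
                               atol=1e-10)

    def test_uncoupled_density_factorizes(self):
        # marginal in-well population equals the 1D quadrature per dihedral
        ref_in = np.array([0.0, 1.0])
        ref_out = ref_in + np.pi
        pot = pm.make_dihedral_flip_system(2, ref_in, ref_out,
                                           coupling=0.0, asymmetry=4.0)
        T = 305.0
        ax = np.linspace(-np.pi, np.pi, 721, endpoint=False)
        mesh = np.stack(np.meshgrid(ax, ax, indexing="ij"), axis=-1)
        w2 = np.exp(-(pot.energy(mesh)) / (KB * T))
        in_mask0 = np.abs(np.angle(np.exp(1j * (mesh[..., 0] - ref_in[0])))
                          ) < np.pi / 2
        p_joint = w2[in_mask0].sum() / w2.sum()
        # 1D marginal by quadrature of the factorized single-dihedral term
        pot1 = pm.make_dihedral_flip_system(1, [ref_in[0]], [ref_out[0]],
                                            coupling=0.0, asymmetry=2.0)
        w1 = np.exp(-pot1.energy(ax[:, None]) / (KB * T))
        mask1 = np.abs(np.angle(np.exp(1j * (ax - ref_in[0])))) < np.pi / 2
        p_marginal = w1[mask1].sum() / w1.sum()
        assert p_joint == pytest.approx(p_marginal, abs=1e-6)

    def test_cv3_is_3_at_in_and_0_at_out(self):
        ref_in = np.array([0.3, -1.2, 2.0])
        pot = pm.make_dihedral_flip_system(3, ref_in, ref_in + np.pi)
        cv = pm.DihedralSimilarityCV(ref_in)
        assert cv.value(pot.ground_truth["ref_in"]) == pytest.approx(3.0)
        assert cv.value(pot.ground_truth["ref_out"]) == pytest.approx(
            0.0, abs=1e-12)

    def test_rejects_unequal_angle_lists(self):
        with pytest.raises(ValueError):
            pm.make_dihedral_flip_system(2, [0.0], [np.pi, 0.0])


class TestTwoChannelBinding:
    def test_saddle_heights_match_requested_barriers(self):
        pot = pm.make_two_channel_binding_potential(barrier_1=15.0,
                                                    barrier_2=18.0)
        s1, s2 = pm.channel_saddle_heights(pot)
        assert s1 == pytest.approx(15.0, abs=0.1)
        assert s2 == pytest.approx(18.0, abs=0.1)

    def test_infinite_second_barrier_gives_single_channel(self):
        pot = pm.make_two_channel_binding_potential(barrier_2=np.inf)
        assert len(pot.ground_truth["channel_angles"]) == 1
        # the ridge opposite the remaining channel stays wall-high
        p = np.array([-3.0, 0.0])
        assert pot.energy(p) > 40.0

    def test_basin_delta_g_near_depth_difference(self):
        pot = pm.make_two_channel_binding_potential(depth_bound=20.0,
                                                    depth_external=8.0)
        dg = pot.ground_truth["delta_f"](305.0)   # F[external] - F[bound]
        assert 9.0 < dg < 13.0     # 12 kJ/mol minus the entropic width term

    def test_oracle_against_independent_quadrature(self):
        pot = pm.make_two_channel_binding_potential()
        T = 305.0
        gt = pot.ground_truth
        ax = np.linspace(-5.3, 5.3, 901)
        mesh = np.stack(np.meshgrid(ax, ax, indexing="ij"), axis=-1)
        w = np.exp(-pot.energy(mesh) / (KB * T))

        def z(b):
            m = ((mesh[..., 0] >= b[0][0]) & (mesh[..., 0] <= b[0][1])
                 & (mesh[..., 1] >= b[1][0]) & (mesh[..., 1] <= b[1][1]))
            return w[m].sum()

        expected = -KB * T * np.log(z(gt["basins"]["external"])
                                    / z(gt["basins"]["bound"]))
        assert gt["delta_f"](T) == pytest.approx(expected, abs=0.02)

    def test_rejects_nonpositive_depth(self):
        with pytest.raises(ValueError, match="depth_bound"):
            pm.make_two_channel_binding_potential(depth_bound=-2.0)


class TestFluctuationTrajectory:
    def test_zero_sigma_frames_identical(self):
        spec = pm.FluctuationTrajectorySpec(n_atoms=5, per_atom_sigma=0.0,
                                            n_frames=10, seed=1)
        tr = pm.make_fluctuation_trajectory(spec)
        assert np.all(tr.positions == tr.positions[0])

    def test_rmsf_is_sqrt3_sigma(self):
        spec = pm.FluctuationTrajectorySpec(n_atoms=50, per_atom_sigma=0.5,
                                            n_frames=20000, seed=2)
        tr = pm.make_fluctuation_trajectory(spec)
        mean = tr.positions.mean(axis=0)
        rmsf = np.sqrt(((tr.positions - mean) ** 2).sum(axis=2).mean(axis=0))
        assert rmsf.mean() == pytest.approx(np.sqrt(3) * 0.5, abs=0.01)

    def test_planted_mode_recovered_by_eigendecomposition(self):
        mode = pm.collective_mode(20, range(1, 11), amplitude=2.0)
        spec = pm.FluctuationTrajectorySpec(
            n_atoms=20, per_atom_sigma=0.1, mode_vectors=[mode],
            n_frames=4000, seed=3)
        tr = pm.make_fluctuation_trajectory(spec)
        x = (tr.positions - tr.positions.mean(axis=0)).reshape(4000, -1)
        _, _, vt = np.linalg.svd(x, full_matrices=False)
        cos = abs(vt[0] @ mode.direction.ravel())
        assert cos >= 0.99

    def test_deterministic_given_seed(self):
        spec = pm.FluctuationTrajectorySpec(n_atoms=8, n_frames=50, seed=9)
        a = pm.make_fluctuation_trajectory(spec)
        b = pm.make_fluctuation_trajectory(spec)
        assert np.array_equal(a.positions, b.positions)

    def test_rejects_degenerate_spec(self):
        with pytest.raises(ValueError):
            pm.FluctuationTrajectorySpec(n_atoms=0, n_frames=10, seed=1)
        with pytest.raises(ValueError):
            pm.FluctuationTrajectorySpec(n_atoms=3, n_frames=1, seed=1)


def test_quadrature_oracle_grid_convergence():
    """Halving the integration step changes dF by far less than 1e-3 kJ/mol."""
    pot = pm.make_entropy_pair()
    T = 330.0
    sep = pot.ground_truth["separatrix"]
    lo, hi = pot.domain[0][0], pot.domain[1][0]

    def riemann(n):
        x = np.linspace(lo, hi, n)
        w = np.exp(-pot.energy(x[:, None]) / (KB * T))
        return -KB * T * np.log(w[x >= sep].sum() / w[x < sep].sum())

    assert abs(riemann(40001) - riemann(80001)) < 1e-3
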