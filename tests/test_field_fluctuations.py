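"""Damped fields, Monte Carlo variances, and the quadrature oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation
from scipy.special import gammainc

import solvdisp as sd
from solvdisp.model_systems import ConfigurationSample


class TestDamping:
    def test_invalid_b_rejected(self):
        with pytest.raises(ValueError):
            sd.DampingSpec(0.0)
        with pytest.raises(ValueError):
            sd.DampingSpec(-1.0)

    def test_matches_incomplete_gamma(self):
        """The order-2 damping equals the regularized incomplete gamma P(3, b r)."""
        dm = sd.DampingSpec(1.7)
        r = np.geomspace(1e-5, 30.0, 200)
        assert np.allclose(dm.factor(r), gammainc(3, 1.7 * r), rtol=1e-8)

    def test_bounds_and_limits(self):
        dm = sd.DampingSpec(2.0)
        f = dm.factor(np.geomspace(1e-6, 100, 100))
        assert np.all((f >= 0) & (f <= 1))
        assert dm.factor(100.0) == pytest.approx(1.0, abs=1e-12)


class TestDampedField:
    def test_long_range_undamped_limit(self):
        dm = sd.DampingSpec(1.6)
        E = sd.damped_field(np.zeros((1, 3)), [0.0, 0.0, 50.0], dm)
        assert np.linalg.norm(E) == pytest.approx(1.0 / 50.0**2, rel=1e-10)
        assert E[2] < 0  # field points toward the electron (negative charge)

    def test_coincident_electron_regularized(self):
        dm = sd.DampingSpec(1.6)
        E = sd.damped_field(np.array([[1.0, 2.0, 3.0]]), [1.0, 2.0, 3.0], dm)
        assert np.allclose(E, 0.0)

    def test_equals_undamped_times_damping_factor(self):
        """Single electron: |E| = f2(b r)/r^2 with f2 evaluated independently."""
        b, r = 1.3, 2.4
        dm = sd.DampingSpec(b)
        E = sd.damped_field(np.zeros((1, 3)), [0.0, 0.0, r], dm)
        f2_independent = float(gammainc(3, b * r))
        assert np.linalg.norm(E) == pytest.approx(f2_independent / r**2, rel=1e-9)


class TestFieldVariance:
    def test_frozen_electron_zero_variance(self, damping):
        snaps = np.tile(np.array([[0.3, -0.2, 0.1]]), (10, 1, 1))
        s = ConfigurationSample(snaps, seed=0, n_kept=10,
                                acceptance_rate=0.5, decorrelation_stride=1)
        fp = sd.field_variance(s, [0, 0, 4.0], np.zeros(3), damping)
        assert fp.s2 == pytest.approx(0.0, abs=1e-28)
        assert np.allclose(fp.sigma2, 0.0)

    def test_transverse_rotation_invariance(self, damping, gauss_wf):
        """sigma_T1^2 + sigma_T2^2 is invariant under rotating the
        transverse pair about the longitudinal axis."""
        s = sd.sample_configurations(gauss_wf, 4000, seed=9)
        probe = np.array([0.0, 0.0, 5.0])
        E = sd.damped_field(s.snapshots, probe, damping)
        L, T1, T2 = sd.probe_triad(probe, np.zeros(3))
        for ang in (0.3, 1.1):
            T1r = np.cos(ang) * T1 + np.sin(ang) * T2
            T2r = -np.sin(ang) * T1 + np.cos(ang) * T2
            v0 = (E @ T1).var(ddof=1) + (E @ T2).var(ddof=1)
            vr = (E @ T1r).var(ddof=1) + (E @ T2r).var(ddof=1)
            assert vr == pytest.approx(v0, rel=1e-12)

    def test_requires_two_snapshots(self, damping):
        s = ConfigurationSample(np.zeros((1, 1, 3)), seed=0, n_kept=1,
                                acceptance_rate=0.5, decorrelation_stride=1)
        with pytest.raises(ValueError):
            sd.field_variance(s, [0, 0, 4.0], np.zeros(3), damping)

    def test_matches_oracle_hydrogen(self, hydrogen_wf, hydrogen_sample, damping):
        """MC S^2 at an exterior probe agrees with the quadrature oracle
        within 3 jackknife standard errors at 10^5 snapshots."""
        probe = [0.0, 0.0, 4.0]
        fp = sd.field_variance(hydrogen_sample, probe, np.zeros(3), damping)
        oracle = sd.s2_oracle(hydrogen_wf, probe, damping)
        assert abs(fp.s2 - oracle) < 3 * fp.mc_error


class TestOracle:
    def test_point_density_zero_fluctuation(self, damping):
        wf = sd.ModelWavefunction(marginals=[sd.GaussianOrbital(1e-4)])
        assert sd.s2_oracle(wf, [0, 0, 5.0], damping) < 1e-10

    def test_asymptotic_power_law(self, gauss_wf, damping):
        """log-log slope of S^2(r) at long range: the field variance of a
        bound charge distribution decays as r^-6 (dipole fluctuations)."""
        r = np.geomspace(20.0, 200.0, 8)
        s2 = np.array([sd.s2_oracle(gauss_wf, [0, 0, ri], damping) for ri in r])
        slope = np.polyfit(np.log(r), np.log(s2), 1)[0]
        assert slope == pytest.approx(-6.0, abs=0.05)
        # and the amplitude approaches 2<dmu^2> = 2 * 3 sigma^2
        assert s2[-1] * r[-1] ** 6 == pytest.approx(6.0, rel=0.01)

    def test_transverse_isotropy_on_axis(self, gauss_wf, damping):
        fp = sd.s2_oracle(gauss_wf, [0, 0, 3.0], damping, return_probe=True)
        assert fp.sigma2[1] == pytest.approx(fp.sigma2[2], rel=1e-12)
        assert fp.s2 == pytest.approx(fp.sigma2.sum(), rel=1e-12)

    def test_quadrature_order_convergence(self, gauss_wf, damping):
        a = sd.s2_oracle(gauss_wf, [0.4, -0.3, 4.0], damping,
                         n_radial=80, n_theta=80)
        b = sd.s2_oracle(gauss_wf, [0.4, -0.3, 4.0], damping,
                         n_radial=160, n_theta=160)
        assert a == pytest.approx(b, rel=1e-8)

    def test_non_analytic_density_rejected(self, damping):
        wf = sd.ModelWavefunction(density=lambda x: np.ones(x.shape[:-2]),
                                  n_electrons=1)
        with pytest.raises(ValueError, match="analytic"):
            sd.s2_oracle(wf, [0, 0, 3.0], damping)

    @settings(deadline=None, derandomize=True, max_examples=10)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rigid_rotation_invariance(self, seed):
        """S^2 is unchanged when density centers and probe rotate together."""
        rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
        dm = sd.DampingSpec(1.6)
        c = np.array([0.5, -0.2, 0.8])
        probe = np.array([1.0, 2.0, 4.0])
        wf = sd.ModelWavefunction(marginals=[sd.GaussianOrbital(0.9, c)])
        wf_rot = sd.ModelWavefunction(marginals=[sd.GaussianOrbital(0.9, rot @ c)])
        s2 = sd.s2_oracle(wf, probe, dm)
        s2r = sd.s2_oracle(wf_rot, rot @ probe, dm)
        assert s2r == pytest.approx(s2, rel=1e-9)


class TestEvaluatorAndGrid:
    def test_evaluator_matches_direct_oracle(self, gauss_wf, damping):
        """Profile-interpolated S^2 reproduces the direct quadrature."""
        ev = sd.S2Evaluator(gauss_wf, damping, d_max=60.0)
        pts = np.array([[0, 0, 3.0], [2.0, 2.0, 2.0], [0, 5.0, 0],
                        [0, 0, 30.0], [10.0, -10.0, 5.0]])
        direct = np.array([sd.s2_oracle(gauss_wf, p, damping) for p in pts])
        assert np.allclose(ev.s2(pts), direct, rtol=1e-5)

    def test_singleton_grid_equals_field_variance(self, gauss_wf, damping):
        s = sd.sample_configurations(gauss_wf, 3000, seed=21)
        grid = sd.fluctuation_grid(gauss_wf, [[0, 0, 4.0]], damping, sample=s)
        fp = sd.field_variance(s, [0, 0, 4.0], gauss_wf.center_of_charge, damping)
        assert grid.probes[0].s2 == pytest.approx(fp.s2, rel=1e-14)
        assert grid.provenance["n"] == 3000

    def test_mirror_symmetric_points_agree(self, gauss_wf, damping):
        s = sd.sample_configurations(gauss_wf, 20_000, seed=22)
        grid = sd.fluctuation_grid(gauss_wf, [[0, 0, 5.0], [0, 0, -5.0]],
                                   damping, sample=s)
        a, b = grid.probes
        assert abs(a.s2 - b.s2) < 3 * np.hypot(a.mc_error, b.mc_error)

    def test_excited_dominates_ground_outside(self, two_state_pair, damping):
        g, e = two_state_pair
        pts = [[0, 0, z] for z in (5.0, 7.0, 10.0)] + [[5.0, 5.0, 0]]
        gg = sd.fluctuation_grid(g, pts, damping)
        ge = sd.fluctuation_grid(e, pts, damping)
        assert gg.provenance["source"] == "quadrature-oracle"
        for pg, pe in zip(gg.probes, ge.probes):
            assert pe.s2 > pg.s2

    def test_empty_point_list_rejected(self, gauss_wf, damping):
        with pytest.raises(ValueError):
            sd.fluctuation_grid(gauss_wf, np.empty((0, 3)), damping)

    def test_table_export(self, gauss_wf, damping, tmp_path):
        grid = sd.fluctuation_grid(gauss_wf, [[0, 0, 4.0], [0, 0, 6.0]], damping)
        df = grid.to_table()
        assert list(df.columns) == ["x", "y", "z", "s2", "err"]
        out = tmp_path / "grid.tsv"
        grid.to_text(out)
        assert out.read_text().startswith("x\t")
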