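"""Tests for convolution, the Wilson-Cowan right-hand side, integration and
the level-change operators."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from padicwc import (
    BallPulse,
    Field,
    IntegrationError,
    PadicGrid,
    RadialExpKernel,
    Sigmoid,
    WCModel,
    coarse_project,
    group_convolve,
    integral_operator,
    integrate,
    refine_embed,
    wc_rhs,
)
from conftest import direct_convolve

ZERO_SIGMOIDS = dict(s_e=Sigmoid(1.0, 1.0), s_i=Sigmoid(1.0, 1.0))


def _zero_couplings(grid):
    z = np.zeros(grid.size)
    return dict(w_ee=z, w_ei=z, w_ie=z, w_ii=z)


class TestGroupConvolve:
    def test_two_site_example(self):
        grid = PadicGrid(2, 1)
        out = group_convolve(Field(grid, [2.0, 4.0]), Field(grid, [1.0, 3.0]))
        assert out.values == pytest.approx([7.0, 5.0], abs=0)

    def test_identity_indicator(self, grid_3_2):
        w = np.zeros(9)
        w[0] = 1.0
        phi = np.arange(9.0)
        out = group_convolve(Field(grid_3_2, w), Field(grid_3_2, phi))
        assert out.values == pytest.approx(phi / 9.0)

    def test_constant_kernel(self, grid_2_3):
        phi = np.array([1.0, -2.0, 3.0, 0.5, 0.0, 2.0, -1.0, 4.0])
        out = group_convolve(Field(grid_2_3, np.full(8, 3.0)), Field(grid_2_3, phi))
        assert out.values == pytest.approx(np.full(8, 3.0 * phi.sum() / 8.0))

    @pytest.mark.parametrize("p,l", [(2, 1), (2, 4), (2, 6), (3, 3), (5, 2), (7, 1)])
    def test_matches_direct_sum(self, p, l):
        grid = PadicGrid(p, l)
        rng = np.random.default_rng(p * 100 + l)
        for _ in range(5):
            w = rng.normal(size=grid.size)
            phi = rng.normal(size=grid.size)
            fast = group_convolve(Field(grid, w), Field(grid, phi)).values
            slow = direct_convolve(grid, w, phi)
            assert np.max(np.abs(fast - slow)) <= 1e-10 * max(1.0, np.max(np.abs(slow)))

    @given(st.integers(0, 2**31 - 1))
    def test_bilinear_and_commutative(self, seed):
        grid = PadicGrid(3, 2)
        rng = np.random.default_rng(seed)
        w, phi, psi = (Field(grid, rng.normal(size=9)) for _ in range(3))
        a = 1.7
        left = group_convolve(w, Field(grid, a * phi.values + psi.values)).values
        right = a * group_convolve(w, phi).values + group_convolve(w, psi).values
        assert left == pytest.approx(right)
        assert group_convolve(w, phi).values == pytest.approx(group_convolve(phi, w).values)

    def test_young_bound(self):
        grid = PadicGrid(2, 5)
        rng = np.random.default_rng(42)
        for _ in range(20):
            w = rng.normal(size=32)
            phi = rng.normal(size=32)
            out = group_convolve(Field(grid, w), Field(grid, phi)).values
            l1 = np.sum(np.abs(w)) * grid.haar_weight
            assert np.max(np.abs(out)) <= l1 * np.max(np.abs(phi)) + 1e-12

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            group_convolve(
                Field(PadicGrid(2, 2), np.ones(4)), Field(PadicGrid(2, 3), np.ones(8))
            )


class TestIntegralOperator:
    def test_all_ones(self, grid_2_3):
        phi = np.arange(8.0)
        out = integral_operator(np.ones((8, 8)), Field(grid_2_3, phi))
        assert out.values == pytest.approx(np.full(8, phi.sum() / 8.0))

    def test_scaled_identity(self, grid_2_3):
        phi = np.arange(8.0)
        out = integral_operator(8.0 * np.eye(8), Field(grid_2_3, phi))
        assert out.values == pytest.approx(phi)

    def test_circulant_equals_convolution(self, grid_3_2):
        rng = np.random.default_rng(3)
        w = rng.normal(size=9)
        phi = rng.normal(size=9)
        idx = np.arange(9)
        K = w[(idx[:, None] - idx[None, :]) % 9]
        via_matrix = integral_operator(K, Field(grid_3_2, phi)).values
        via_conv = group_convolve(Field(grid_3_2, w), Field(grid_3_2, phi)).values
        assert np.max(np.abs(via_matrix - via_conv)) < 1e-12

    def test_size_mismatch(self, grid_2_3):
        with pytest.raises(ValueError):
            integral_operator(np.ones((4, 4)), Field(grid_2_3, np.ones(8)))


class TestWCRhs:
    def test_rest_is_fixed_point(self, grid_3_2):
        model = WCModel(
            grid=grid_3_2,
            tau=10.0,
            r_e=1.0,
            r_i=1.0,
            w_ee=RadialExpKernel(1.5, 4.0),
            w_ei=RadialExpKernel(1.35, 6.0),
            w_ie=RadialExpKernel(1.35, 6.0),
            w_ii=RadialExpKernel(1.8, 3.0),
            s_e=Sigmoid(2.75, 9.0),
            s_i=Sigmoid(0.3, 17.0),
        )
        de, di = wc_rhs(Field.zeros(grid_3_2), Field.zeros(grid_3_2), 0.0, model)
        assert np.all(de.values == 0.0)
        assert np.all(di.values == 0.0)

    def test_pure_decay(self, grid_3_2):
        model = WCModel(
            grid=grid_3_2, tau=10.0, r_e=0.0, r_i=0.0,
            **_zero_couplings(grid_3_2), **ZERO_SIGMOIDS,
        )
        e0 = np.linspace(-1, 1, 9)
        de, di = wc_rhs(Field(grid_3_2, e0), Field.zeros(grid_3_2), 0.0, model)
        assert de.values == pytest.approx(-e0 / 10.0)
        assert np.all(di.values == 0.0)

    def test_two_site_brute_force(self):
        """Full right-hand side on a 2-site grid against independent arithmetic."""
        grid = PadicGrid(2, 1)
        w_ee, w_ei = np.array([2.0, 1.0]), np.array([0.5, 0.25])
        w_ie, w_ii = np.array([1.0, 0.0]), np.array([0.3, 0.1])
        s_e, s_i = Sigmoid(1.0, 0.5), Sigmoid(2.0, 1.0)
        tau, r_e, r_i = 10.0, 1.0, 0.5
        h_e = 0.7
        model = WCModel(
            grid=grid, tau=tau, r_e=r_e, r_i=r_i,
            w_ee=w_ee, w_ei=w_ei, w_ie=w_ie, w_ii=w_ii, s_e=s_e, s_i=s_i,
            stimulus_e=BallPulse(h_e, 0, 0),
        )
        e, i = np.array([0.2, 0.4]), np.array([0.1, 0.3])
        de, di = wc_rhs(Field(grid, e), Field(grid, i), 0.0, model)

        def sig(z, v, theta):
            return 1 / (1 + math.exp(-v * (z - theta))) - 1 / (1 + math.exp(v * theta))

        for k in range(2):
            conv = lambda w, f: 0.5 * (w[k] * f[0] + w[(k - 1) % 2] * f[1])
            z_e = conv(w_ee, e) - conv(w_ei, i) + h_e
            z_i = conv(w_ie, e) - conv(w_ii, i)
            expected_de = (-e[k] + (1 - r_e * e[k]) * sig(z_e, 1.0, 0.5)) / tau
            expected_di = (-i[k] + (1 - r_i * i[k]) * sig(z_i, 2.0, 1.0)) / tau
            assert de.values[k] == pytest.approx(expected_de, rel=1e-12)
            assert di.values[k] == pytest.approx(expected_di, rel=1e-12)

    def test_invalid_tau(self, grid_3_2):
        with pytest.raises(ValueError):
            WCModel(
                grid=grid_3_2, tau=0.0, r_e=0.0, r_i=0.0,
                **_zero_couplings(grid_3_2), **ZERO_SIGMOIDS,
            )


class TestIntegrate:
    def _decay_model(self, grid):
        return WCModel(
            grid=grid, tau=10.0, r_e=0.0, r_i=0.0,
            **_zero_couplings(grid), **ZERO_SIGMOIDS,
        )

    def test_decoupled_decay_closed_form(self, grid_3_2):
        model = self._decay_model(grid_3_2)
        traj = integrate(model, Field.constant(grid_3_2, 1.0), Field.zeros(grid_3_2), 10.0, 0.05)
        assert np.max(np.abs(traj.E[-1] - math.exp(-1.0))) < 1e-8

    def test_zero_state_stays_zero(self, grid_3_2):
        model = self._decay_model(grid_3_2)
        traj = integrate(model, Field.zeros(grid_3_2), Field.zeros(grid_3_2), 5.0, 0.05)
        assert np.all(traj.E == 0.0)
        assert np.all(traj.I == 0.0)

    def test_rk4_fourth_order(self, grid_3_2):
        """Halving dt shrinks the decay-test error by at least 8x."""
        model = self._decay_model(grid_3_2)
        errors = []
        for dt in (0.4, 0.2):
            traj = integrate(model, Field.constant(grid_3_2, 1.0), Field.zeros(grid_3_2), 10.0, dt)
            errors.append(abs(traj.E[-1, 0] - math.exp(-1.0)))
        assert errors[0] / errors[1] >= 8.0

    def test_euler_first_order(self, grid_3_2):
        model = self._decay_model(grid_3_2)
        errors = []
        for dt in (0.4, 0.2):
            traj = integrate(
                model, Field.constant(grid_3_2, 1.0), Field.zeros(grid_3_2), 10.0, dt,
                method="euler",
            )
            errors.append(abs(traj.E[-1, 0] - math.exp(-1.0)))
        assert 1.5 <= errors[0] / errors[1] <= 3.0

    def test_records_every_step(self, grid_3_2):
        model = self._decay_model(grid_3_2)
        traj = integrate(model, Field.zeros(grid_3_2), Field.zeros(grid_3_2), 1.0, 0.05)
        assert len(traj.times) == 21
        assert traj.times[0] == 0.0
        assert traj.times[-1] == pytest.approx(1.0)
        assert traj.dt == pytest.approx(0.05)

    def test_invalid_arguments(self, grid_3_2):
        model = self._decay_model(grid_3_2)
        e0 = Field.zeros(grid_3_2)
        with pytest.raises(ValueError):
            integrate(model, e0, e0, 1.0, -0.1)
        with pytest.raises(ValueError):
            integrate(model, e0, e0, 0.01, 0.05)
        with pytest.raises(ValueError):
            integrate(model, e0, e0, 1.0, 0.05, method="rk45")

    def test_blowup_reported_with_time(self, grid_3_2):
        # a coupling this large overflows the linear growth within a few steps
        model = WCModel(
            grid=grid_3_2, tau=1e-8, r_e=1e8, r_i=0.0,
            w_ee=np.full(9, 1e300), w_ei=np.zeros(9), w_ie=np.zeros(9), w_ii=np.zeros(9),
            **ZERO_SIGMOIDS,
        )
        with pytest.raises(IntegrationError):
            integrate(model, Field.constant(grid_3_2, 1e300), Field.zeros(grid_3_2), 1.0, 0.1)


class TestLevelChange:
    def test_coarse_project_samples_representatives(self):
        fine = PadicGrid(2, 2)
        f = Field(fine, [1.0, 2.0, 3.0, 4.0])
        out = coarse_project(f, 1)
        assert out.grid.l == 1
        assert list(out.values) == [1.0, 2.0]

    def test_refine_embed_repeats_pattern(self):
        coarse = PadicGrid(2, 1)
        out = refine_embed(Field(coarse, [5.0, 7.0]), 2)
        assert list(out.values) == [5.0, 7.0, 5.0, 7.0]

    @pytest.mark.parametrize("p,l,l_fine", [(2, 1, 3), (3, 2, 4)])
    def test_project_refine_roundtrip(self, p, l, l_fine):
        grid = PadicGrid(p, l)
        rng = np.random.default_rng(7)
        f = Field(grid, rng.normal(size=grid.size))
        back = coarse_project(refine_embed(f, l_fine), l)
        assert np.all(back.values == f.values)

    def test_constant_preserved(self):
        f = Field(PadicGrid(3, 1), np.full(3, 2.5))
        assert np.all(refine_embed(f, 3).values == 2.5)
        assert np.all(coarse_project(refine_embed(f, 3), 2).values == 2.5)

    def test_haar_integral_preserved_by_embedding(self):
        grid = PadicGrid(3, 2)
        rng = np.random.default_rng(11)
        f = Field(grid, rng.normal(size=9))
        fine = refine_embed(f, 4)
        assert fine.grid.haar_weight * fine.values.sum() == pytest.approx(
            grid.haar_weight * f.values.sum()
        )

    def test_sup_norm_nonincreasing_under_projection(self):
        grid = PadicGrid(2, 4)
        rng = np.random.default_rng(13)
        f = Field(grid, rng.normal(size=16))
        assert np.max(np.abs(coarse_project(f, 2).values)) <= np.max(np.abs(f.values))

    def test_level_errors(self):
        f = Field(PadicGrid(2, 2), np.zeros(4))
        with pytest.raises(ValueError):
            coarse_project(f, 2)
        with pytest.raises(ValueError):
            refine_embed(f, 2)
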