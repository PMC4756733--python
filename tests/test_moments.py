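"""Second-moment dynamics: closure, fields, RHS and steady-state solver."""

import math

import numpy as np
import pytest

from cellmove.core import ModelParams, step_length_density
from cellmove.moments import (
    MomentField,
    MomentParams,
    kirkwood_triplet,
    pair_bias_field,
    pair_motility_rate_field,
    radial_section,
    solve_to_steady_state,
    z2_rhs,
)


def make_params(**over):
    base = dict(m=10.0, alpha=0.0, sigma_w=0.5, beta=0.1, sigma_v=0.5,
                lambda_mu=5.0, sigma_mu=0.05, Lx=20.0, Ly=20.0, n=200)
    base.update(over)
    return ModelParams(**base)


def flat_field(params, delta, xi_max):
    Z1 = params.density
    M = int(round(xi_max / delta))
    N = 2 * M + 1
    return MomentField(Z1, np.full((N, N), Z1**2), delta, xi_max)


def bumpy_field(params, delta, xi_max, amp=0.4, scale=0.6):
    """Even, clustered-looking test fixture: Z2 = Z1^2 (1 + amp exp(-r^2/2 scale^2))."""
    f = flat_field(params, delta, xi_max)
    X, Y = f.grid()
    f.Z2 = f.Z1**2 * (1.0 + amp * np.exp(-(X**2 + Y**2) / (2 * scale**2)))
    return f


def test_kirkwood_closure_poisson_factorization():
    z1 = 0.37
    assert kirkwood_triplet(z1**2, z1**2, z1**2, z1) == pytest.approx(z1**3, rel=1e-14)
    assert kirkwood_triplet(2.0, 3.0, 4.0, 1.0) == pytest.approx(24.0)


class TestPairMotilityRate:
    def test_constant_when_alpha_zero(self):
        p = make_params(alpha=0.0)
        f = bumpy_field(p, 0.2, 3.0)
        assert np.allclose(pair_motility_rate_field(f, p), p.m)

    def test_flat_state_closed_form(self):
        # Z2 = Z1^2: M2 = m + Z1 * 2 pi sigma_w^2 alpha + w(xi)
        p = make_params(alpha=-1.5)
        f = flat_field(p, 0.1, 4.0)
        M2 = pair_motility_rate_field(f, p)
        X, Y = f.grid()
        w = p.alpha * np.exp(-(X**2 + Y**2) / (2 * p.sigma_w**2))
        expected = p.m + f.Z1 * 2 * math.pi * p.sigma_w**2 * p.alpha + w
        assert np.max(np.abs(M2 - expected)) < 1e-8

    def test_even_in_displacement(self):
        p = make_params(alpha=2.0)
        f = bumpy_field(p, 0.2, 3.0)
        M2 = pair_motility_rate_field(f, p)
        assert np.max(np.abs(M2 - M2[::-1, ::-1])) < 1e-10

    def test_fft_agrees_with_direct_summation(self):
        p = make_params(alpha=-1.0)
        f = bumpy_field(p, 0.4, 1.6)  # 9x9 grid: direct O(N^4) is affordable
        fft = pair_motility_rate_field(f, p, method="fft")
        direct = pair_motility_rate_field(f, p, method="direct")
        assert np.max(np.abs(fft - direct)) < 1e-8


class TestPairBias:
    def test_zero_when_beta_zero(self):
        p = make_params(beta=0.0)
        f = bumpy_field(p, 0.2, 3.0)
        assert np.all(pair_bias_field(f, p) == 0.0)

    def test_flat_state_reduces_to_kernel_gradient(self):
        p = make_params(beta=0.7)
        f = flat_field(p, 0.1, 4.0)
        b2 = pair_bias_field(f, p)
        X, Y = f.grid()
        v = p.beta * np.exp(-(X**2 + Y**2) / (2 * p.sigma_v**2))
        expected = np.stack([-X / p.sigma_v**2 * v, -Y / p.sigma_v**2 * v], axis=-1)
        assert np.max(np.abs(b2 - expected)) < 1e-10

    def test_fft_agrees_with_direct_summation(self):
        p = make_params(beta=0.5)
        f = bumpy_field(p, 0.4, 1.6)
        fft = pair_bias_field(f, p, method="fft")
        direct = pair_bias_field(f, p, method="direct")
        assert np.max(np.abs(fft - direct)) < 1e-8

    def test_antisymmetric_for_even_field(self):
        p = make_params(beta=0.5)
        f = bumpy_field(p, 0.2, 3.0)
        b2 = pair_bias_field(f, p)
        assert np.max(np.abs(b2 + b2[::-1, ::-1, :])) < 1e-10


class TestRhs:
    def test_poisson_state_is_stationary_without_interactions(self):
        p = make_params(alpha=0.0, beta=0.0)
        f = flat_field(p, 0.1, 4.0)
        rhs = z2_rhs(f, p, MomentParams(delta=0.1, xi_max=4.0))
        assert np.max(np.abs(rhs)) < 1e-12 * f.Z1**2

    def test_even_symmetry_preserved(self):
        p = make_params(beta=0.3)
        f = bumpy_field(p, 0.2, 3.0)
        rhs = z2_rhs(f, p, MomentParams(delta=0.2, xi_max=3.0))
        assert np.max(np.abs(rhs - rhs[::-1, ::-1])) < 1e-10 * f.Z1**2

    def test_interaction_free_rhs_matches_monte_carlo_smoothing(self, rng):
        """alpha=beta=0: rhs = -2 m Z2 + 2 m E_s[Z2(xi+s)], s the isotropic step."""
        p = make_params(alpha=0.0, beta=0.0)
        num = MomentParams(delta=0.2, xi_max=3.0)
        f = bumpy_field(p, 0.2, 3.0)
        rhs = z2_rhs(f, p, num)
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator((f.axis, f.axis), f.Z2,
                                         bounds_error=False, fill_value=f.Z1**2)
        n_mc = 400_000
        from cellmove.core import sample_step_length

        lengths = sample_step_length(p, rng, size=n_mc)
        angles = rng.uniform(0, 2 * math.pi, n_mc)
        steps = np.column_stack([lengths * np.cos(angles), lengths * np.sin(angles)])
        for idx in [(15, 15), (10, 12), (15, 8)]:
            xi = np.array([f.axis[idx[0]], f.axis[idx[1]]])
            vals = interp(xi + steps)
            in_term = 2 * p.m * vals.mean()
            mc = -2 * p.m * f.Z2[idx] + in_term
            se = 2 * p.m * vals.std() / math.sqrt(n_mc)
            # the MC integrates the bilinear field exactly over angle, the
            # quadrature only to its angular resolution: allow that floor
            assert rhs[idx] == pytest.approx(mc, abs=4 * se + 2e-4 * abs(in_term))

    def test_mass_balance_of_in_and_out_terms(self):
        # isotropic step smoothing moves pair mass around without creating it
        p = make_params(alpha=0.0, beta=0.0)
        f = bumpy_field(p, 0.1, 4.0, amp=0.4, scale=0.6)
        rhs = z2_rhs(f, p, MomentParams(delta=0.1, xi_max=4.0))
        net = abs(np.sum(rhs)) * 0.1**2
        gross = np.sum(np.abs(2 * p.m * f.Z2)) * 0.1**2
        assert net < 1e-4 * gross


class TestSteadyState:
    def test_no_interactions_converges_to_constant(self):
        p = make_params(alpha=0.0, beta=0.0)
        num = MomentParams(delta=0.2, xi_max=3.0, tol=1e-8)
        field = solve_to_steady_state(p, num)
        assert np.max(np.abs(field.correlation() - 1.0)) < 1e-8

    def test_repulsive_bias_regular_attractive_bias_clustered(self):
        num = MomentParams(delta=0.2, xi_max=3.0, tol=1e-4)
        reg = radial_section(solve_to_steady_state(make_params(beta=0.1), num))
        clu = radial_section(solve_to_steady_state(make_params(beta=-0.03), num))
        assert np.all(reg.values[:4] < 1.0)
        assert np.all(clu.values[:4] > 1.0)

    def test_tail_stays_uncorrelated(self):
        num = MomentParams(delta=0.2, xi_max=3.0, tol=1e-5)
        sec = radial_section(solve_to_steady_state(make_params(beta=0.1), num))
        assert abs(sec.values[-1] - 1.0) < 1e-2

    def test_grid_refinement_stability(self):
        # halving the production grid spacing moves the converged C field by < 2%
        coarse = MomentParams(delta=0.1, xi_max=4.0, tol=1e-5)
        fine = MomentParams(delta=0.05, xi_max=4.0, tol=1e-5)
        p = make_params(beta=0.1)
        c = solve_to_steady_state(p, coarse).correlation()
        f = solve_to_steady_state(p, fine).correlation()
        assert np.max(np.abs(c - f[::2, ::2])) < 0.02

    def test_unconverged_solve_raises(self):
        from cellmove.errors import ConvergenceError

        p = make_params(beta=1.0)
        num = MomentParams(delta=0.2, xi_max=3.0, tol=1e-10, max_hours=0.05,
                           newton_polish=False)
        with pytest.raises(ConvergenceError):
            solve_to_steady_state(p, num)


class TestRadialSection:
    def test_flat_field_gives_unity(self):
        p = make_params()
        sec = radial_section(flat_field(p, 0.2, 3.0))
        assert np.allclose(sec.values, 1.0)

    def test_scaling(self):
        p = make_params()
        f = flat_field(p, 0.2, 3.0)
        f.Z2 = 2.0 * f.Z2
        assert np.allclose(radial_section(f).values, 2.0)

    def test_axis_section_agrees_with_annular_average(self):
        p = make_params(beta=0.1)
        num = MomentParams(delta=0.1, xi_max=4.0, tol=1e-5)
        field = solve_to_steady_state(p, num)
        sec = radial_section(field)
        M = field.half_points
        axis = field.correlation()[M, M + 1:]  # positive x-axis slice
        axis_r = field.axis[M + 1:]
        sel = sec.bin_centers < 3.5
        interp_axis = np.interp(sec.bin_centers[sel], axis_r, axis)
        assert np.max(np.abs(interp_axis - sec.values[sel])) < 0.01


def test_step_quadrature_integrates_step_law_exactly():
    from cellmove.moments import _radial_rule

    p = make_params(lambda_mu=0.1, sigma_mu=2.5)
    nodes, weights = _radial_rule(p, 20)
    assert weights.sum() == pytest.approx(1.0, abs=1e-14)
    mean = np.sum(weights * nodes)
    # matches the analytic mean of the truncated normal
    from scipy import stats

    ref = stats.truncnorm(-4.0, np.inf, loc=10.0, scale=2.5).mean()
    assert mean == pytest.approx(ref, rel=1e-4)
    dens = step_length_density(nodes, p)
    assert np.all(dens > 0)
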