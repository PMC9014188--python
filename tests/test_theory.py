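"""Analytic-layer tests: closed forms, WF-matrix oracle, diffusion machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyport import (TheoryConfig, GAUSSIAN_01, HEAVY_TAIL,
                      ancestral_variance_remaining, closed_form_retention,
                      deterministic_trajectory, diffusion_retention,
                      equilibrium_variance_density, scaled_selection,
                      wf_matrix_retention)
from polyport.theory import (sojourn_density, wf_stationary_counts,
                             _freq_grid, _interior_weights)


class TestScaledSelection:
    def test_values(self):
        assert scaled_selection(0.0, 1000, 5.0) == 0.0
        assert scaled_selection(0.1, 10_000, 5.0) == pytest.approx(8.0)

    @given(a=st.floats(-2, 2, allow_nan=False))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_sign_symmetry(self, a):
        assert scaled_selection(a, 500, 5.0) == scaled_selection(-a, 500, 5.0)


class TestClosedForm:
    def test_pure_drift_product(self):
        r = closed_form_retention(0.0, 1500, 10_000, 5.0)
        assert r.product == pytest.approx(0.9277, abs=5e-4)
        assert r.exponential == pytest.approx(np.exp(-1500 / 20_000), rel=1e-6)

    def test_selected_exponential_form(self):
        # S = 8 at a=0.1, N=1e4, w=5: exp(-0.075 * 3)
        r = closed_form_retention(0.1, 1500, 10_000, 5.0)
        assert r.exponential == pytest.approx(0.7985, abs=5e-4)

    def test_t_zero_is_one(self):
        r = closed_form_retention(0.3, 0, 1000, 5.0)
        assert r.product == 1.0 and r.exponential == 1.0

    def test_rejects_outside_domain(self):
        with pytest.raises(ValueError):
            closed_form_retention(11.0, 10, 1000, 5.0)  # a^2/(4w^2) > 1


class TestWfMatrix:
    def test_neutral_matches_closed_form_exactly(self):
        N, t = 120, 60
        ret = wf_matrix_retention(0.0, t, N, None)
        assert ret == pytest.approx((1 - 1 / (2 * N)) ** t, rel=1e-10)

    def test_scaling_invariance(self):
        """Same S and t/2N at different N give the same retention."""
        S, tau, w = 8.0, 0.08, 5.0
        vals = []
        for N in (150, 300):
            a = np.sqrt(S * w * w / (2 * N))
            vals.append(wf_matrix_retention(a, int(tau * 2 * N), N, w))
        assert vals[0] == pytest.approx(vals[1], rel=0.01)

    def test_selection_accelerates_decay(self):
        N, w, tau = 200, 5.0, 0.1
        a = np.sqrt(8.0 * w * w / (2 * N))
        neutral = wf_matrix_retention(0.0, int(tau * 2 * N), N, None)
        sel = wf_matrix_retention(a, int(tau * 2 * N), N, w)
        assert sel < neutral

    def test_size_guard(self):
        with pytest.raises(ValueError):
            wf_matrix_retention(0.0, 1, 501, None)


class TestDiffusion:
    def test_neutral_limit(self):
        r = diffusion_retention(1e-9, 1000.0, 5000, 5.0)
        assert r == pytest.approx(np.exp(-0.1), rel=2e-3)

    def test_monotone_in_time_and_effect(self):
        taus = np.array([0.0, 250.0, 500.0, 1000.0])
        r_small = diffusion_retention(0.05, taus, 5000, 5.0)
        r_big = diffusion_retention(0.2, taus, 5000, 5.0)
        assert r_small[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(r_small) < 0)
        assert np.all(r_big[1:] < r_small[1:])

    def test_sign_symmetry(self):
        assert diffusion_retention(0.1, 500.0, 5000, 5.0) == pytest.approx(
            diffusion_retention(-0.1, 500.0, 5000, 5.0), rel=1e-12)


def test_sojourn_matches_wf_stationary_counts():
    """Diffusion sojourn density ~ finite-N stationary density under influx."""
    N, S, w = 150, 6.0, 5.0
    a = np.sqrt(S * w * w / (2 * N))
    counts = wf_stationary_counts(N, a, w)          # per unit influx, by count
    p = np.arange(1, 2 * N) / (2.0 * N)
    h_matrix = float(np.sum(counts * 2 * p * (1 - p)))
    x = _freq_grid(400)
    wq = _interior_weights(x)
    xi = x[1:-1]
    dens = sojourn_density(S, N, xi)
    h_diff = float(np.sum(wq * dens * 2 * xi * (1 - xi)))
    # matrix counts are per-mutation lifetimes too: same H integral
    assert h_matrix == pytest.approx(h_diff, rel=0.05)


class TestDeterministicTrajectory:
    def test_half_is_unstable_fixed_point(self):
        path = deterministic_trajectory(0.5, 0.3, 5.0, 50)
        assert np.allclose(path, 0.5)

    def test_mirror_symmetry(self):
        up = deterministic_trajectory(0.7, 0.3, 5.0, 200)
        down = deterministic_trajectory(0.3, 0.3, 5.0, 200)
        assert np.allclose(up, 1.0 - down, atol=1e-12)

    def test_larger_effect_reaches_boundary_faster(self):
        slow = deterministic_trajectory(0.3, 0.2, 5.0, 300)[-1]
        fast = deterministic_trajectory(0.3, 0.6, 5.0, 300)[-1]
        assert fast < slow
        assert np.all(np.diff(deterministic_trajectory(0.3, 0.4, 5.0, 100)) <= 0)

    def test_rejects_boundary_start(self):
        with pytest.raises(ValueError):
            deterministic_trajectory(0.0, 0.1, 5.0, 10)


class TestVarianceDensity:
    def test_neutral_limit_proportional_to_mutation_density(self):
        """With selection off, v(a) ~ mu(a) a^2 (all effects drift alike)."""
        cfg = TheoryConfig(N=2000, w=None, U=0.02, effect_dist=GAUSSIAN_01,
                           n_effect=64)
        vd = equilibrium_variance_density(cfg)
        expected = 2 * cfg.effect_dist.pdf(vd.effects) * vd.effects**2
        ratio = vd.density / expected
        inner = vd.density > 1e-3 * vd.density.max()
        assert np.ptp(ratio[inner]) / ratio[inner].mean() < 0.02
        # total matches 2 N U E[a^2] less the small boundary truncation
        assert vd.total == pytest.approx(
            2 * cfg.N * cfg.U * cfg.effect_dist.variance(), rel=0.02)

    def test_weaker_selection_shifts_mass_to_larger_effects(self):
        dens = {}
        for w in (4.0, 8.0):
            cfg = TheoryConfig(N=2000, w=w, U=0.02, effect_dist=GAUSSIAN_01)
            vd = equilibrium_variance_density(cfg)
            dens[w] = vd
        med = {}
        for w, vd in dens.items():
            c = np.cumsum(vd.density * np.gradient(vd.effects))
            med[w] = vd.effects[np.searchsorted(c, c[-1] / 2)]
        assert med[8.0] > med[4.0]


class TestAncestralVarianceRemaining:
    def test_t_zero_and_neutral_limit(self):
        cfg = TheoryConfig(N=2000, w=None, U=0.02)
        taus = np.array([0.0, 200.0, 400.0])
        r = ancestral_variance_remaining(cfg, taus)
        assert r[0] == pytest.approx(1.0)
        assert np.allclose(r, np.exp(-taus / (2 * cfg.N)), rtol=1e-6)

    def test_heavy_tail_decays_faster_early(self):
        common = dict(N=1000, w=5.0, U=0.02, scale_effects=True, n_effect=48)
        t = 100.0
        r_gauss = ancestral_variance_remaining(
            TheoryConfig(effect_dist=GAUSSIAN_01, **common), t)
        r_heavy = ancestral_variance_remaining(
            TheoryConfig(effect_dist=HEAVY_TAIL, **common), t)
        assert r_heavy < r_gauss

    def test_monotone_non_increasing(self):
        cfg = TheoryConfig(N=1000, w=5.0, U=0.02, scale_effects=True,
                           n_effect=32)
        r = ancestral_variance_remaining(cfg, np.array([0.0, 50.0, 100.0, 200.0]))
        assert np.all(np.diff(r) < 0) and r[0] == pytest.approx(1.0)
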