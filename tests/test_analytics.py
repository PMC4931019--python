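"""Random-matrix predictions: effective moments, supports, outliers, Gamma."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blockstab import (
    BlockSpec,
    InteractionSpec,
    UnsupportedCaseError,
    bipartite_support,
    bulk_support,
    correct_outliers,
    effective_parameters,
    full_spectrum,
    leading_eigenvalue,
    outliers_of_A,
    predict_gamma,
    predict_rightmost,
    sample_community_matrix,
    sqrt_ellipse_rightmost,
)


def _mc_effective_moments(mu, sigma2, rho, C, n_pairs, seed):
    """Monte-Carlo oracle: moments of the diluted pair distribution."""
    rng = np.random.default_rng(seed)
    sd = np.sqrt(sigma2)
    z1 = rng.normal(size=n_pairs)
    z2 = rng.normal(size=n_pairs)
    a = mu + sd * z1
    b = mu + sd * (rho * z1 + np.sqrt(1 - rho**2) * z2)
    keep = rng.random(n_pairs) < C
    a, b = a * keep, b * keep
    x = np.concatenate([a, b])
    cov = np.mean(a * b) - a.mean() * b.mean()
    return x.mean(), x.var(), cov / np.sqrt(a.var() * b.var())


class TestEffectiveParameters:
    def test_no_dilution_is_identity(self):
        eff = effective_parameters(InteractionSpec(mu=-1.0, sigma2=2.0, rho=0.3), 1.0, 1.0)
        assert (eff.mu_w, eff.sigma2_w, eff.rho_w) == pytest.approx((-1.0, 2.0, 0.3))

    def test_zero_mean_closed_form(self):
        eff = effective_parameters(InteractionSpec(mu=0.0, sigma2=1.0, rho=-0.6), 0.3, 0.3)
        assert eff.mu_w == 0.0
        assert eff.sigma2_w == pytest.approx(0.3)
        assert eff.rho_w == pytest.approx(-0.6)

    def test_dilution_example(self):
        eff = effective_parameters(InteractionSpec(mu=-1.0, sigma2=1.0, rho=0.0), 0.2, 0.2)
        assert eff.mu_w == pytest.approx(-0.2)
        assert eff.sigma2_w == pytest.approx(0.36)
        assert eff.rho_w == pytest.approx(0.16 / 0.36)

    @pytest.mark.parametrize("mu,rho,C", [(-1.0, 0.0, 0.2), (0.5, -0.75, 0.4), (1.0, 0.5, 0.1)])
    def test_against_monte_carlo(self, mu, rho, C):
        n = 10**6
        m_hat, v_hat, r_hat = _mc_effective_moments(mu, 1.0, rho, C, n, seed=17)
        eff = effective_parameters(InteractionSpec(mu=mu, sigma2=1.0, rho=rho), C, C)
        se_scale = 3 / np.sqrt(n)
        assert abs(eff.mu_w - m_hat) < se_scale * 3 * np.sqrt(eff.sigma2_w)
        assert abs(eff.sigma2_w - v_hat) < se_scale * 5 * eff.sigma2_w
        assert abs(eff.rho_w - r_hat) < se_scale * 5

    @given(mu=st.floats(-2, 2), rho=st.floats(-0.9, 0.9), C=st.floats(0.05, 0.95))
    @settings(max_examples=80, derandomize=True)
    def test_second_moments_even_in_mu(self, mu, rho, C):
        inter_p = InteractionSpec(mu=mu, sigma2=1.0, rho=rho)
        inter_m = InteractionSpec(mu=-mu, sigma2=1.0, rho=rho)
        ep = effective_parameters(inter_p, C, C)
        em = effective_parameters(inter_m, C, C)
        assert ep.sigma2_w == pytest.approx(em.sigma2_w, rel=1e-12)
        assert ep.rho_w == pytest.approx(em.rho_w, rel=1e-12, abs=1e-12)
        assert ep.mu_w == pytest.approx(-em.mu_w)


def _block_constant(S, alpha, mu_w, mu_b):
    m = int(round(alpha * S))
    g = np.r_[np.zeros(m, dtype=int), np.ones(S - m, dtype=int)]
    return np.where(g[:, None] == g[None, :], mu_w, mu_b)


class TestOutliersOfA:
    @pytest.mark.parametrize(
        "alpha, mu_w, mu_b",
        [(0.5, -0.3, -0.1), (0.25, 0.4, 0.2), (0.5, 0.0, -0.5), (0.3, -0.2, 0.0)],
    )
    def test_against_direct_eigensolve(self, alpha, mu_w, mu_b):
        S = 100
        ev = np.linalg.eigvals(_block_constant(S, alpha, mu_w, mu_b))
        nonzero = np.sort(ev.real[np.abs(ev) > 1e-8])
        assert outliers_of_A(S, alpha, mu_w, mu_b) == pytest.approx(nonzero, abs=1e-8)

    def test_unstructured_single_outlier(self):
        out = outliers_of_A(500, 0.5, -0.2, -0.2)
        assert out == pytest.approx([-100.0])

    def test_equal_blocks_closed_form(self):
        out = outliers_of_A(200, 0.5, -0.3, -0.1)
        assert sorted(out) == pytest.approx(sorted([200 * (-0.4) / 2, 200 * (-0.2) / 2]))

    def test_bipartite_closed_form(self):
        S, alpha, mu_b = 200, 0.25, -0.5
        expect = S * abs(mu_b) * np.sqrt(alpha * (1 - alpha))
        assert outliers_of_A(S, alpha, 0.0, mu_b) == pytest.approx([-expect, expect])

    def test_all_zero_means_no_outliers(self):
        assert outliers_of_A(100, 0.5, 0.0, 0.0) == []


class TestBulkSupport:
    def test_uniform_circle_edge_matches_simulation(self):
        block = BlockSpec(S=1000, alpha=0.5, C=0.2, Q=0.0)
        inter = InteractionSpec(mu=0.0, sigma2=1.0, rho=0.0)
        eff = effective_parameters(inter, block.C_w, block.C_b)
        sup = bulk_support(block.S, block.alpha, eff)
        assert sup.case_label == "uniform"
        assert sup.rightmost_bulk == pytest.approx(np.sqrt(200), abs=1e-9)
        lam = leading_eigenvalue(sample_community_matrix(block, inter, seed=21))
        assert lam == pytest.approx(sup.rightmost_bulk, rel=0.05)

    def test_zero_mean_support_independent_of_q(self):
        inter = InteractionSpec(mu=0.0, sigma2=1.0, rho=-0.5)
        edges = []
        for q in (-0.3, 0.0, 0.3):
            block = BlockSpec(S=1000, alpha=0.5, C=0.2, Q=q)
            eff = effective_parameters(inter, block.C_w, block.C_b)
            edges.append(bulk_support(block.S, block.alpha, eff).rightmost_bulk)
        assert edges[0] == pytest.approx(edges[1], rel=1e-12)
        assert edges[2] == pytest.approx(edges[1], rel=1e-12)

    def test_equal_blocks_even_in_q(self):
        inter = InteractionSpec(mu=-1.0, sigma2=1.0, rho=-0.5)
        for q in (0.1, 0.25, 0.4):
            sups = []
            for sq in (q, -q):
                block = BlockSpec(S=1000, alpha=0.5, C=0.2, Q=sq)
                eff = effective_parameters(inter, block.C_w, block.C_b)
                sups.append(bulk_support(block.S, block.alpha, eff))
            # same within/between variances swap roles; supports coincide
            a, b = sups
            assert a.ellipses[0][1] == pytest.approx(b.ellipses[0][1], rel=1e-12)
            assert a.ellipses[0][2] == pytest.approx(b.ellipses[0][2], rel=1e-12)

    def test_zero_correlation_circle_consistent_at_alpha_half(self):
        eff = effective_parameters(InteractionSpec(mu=0.0, sigma2=1.0, rho=0.0), 0.3, 0.1)
        sup = bulk_support(800, 0.5, eff)
        assert sup.case_label == "zero_correlation"
        sigma2_bar = 0.5 * (eff.sigma2_w + eff.sigma2_b)
        assert sup.rightmost_bulk == pytest.approx(np.sqrt(800 * sigma2_bar), rel=1e-12)

    def test_zero_correlation_circle_matches_simulation(self):
        block = BlockSpec(S=1000, alpha=0.25, C=0.2, Q=0.2)
        inter = InteractionSpec(mu=0.0, sigma2=1.0, rho=0.0)
        eff = effective_parameters(inter, block.C_w, block.C_b)
        sup = bulk_support(block.S, block.alpha, eff)
        lam = leading_eigenvalue(sample_community_matrix(block, inter, seed=23))
        assert lam == pytest.approx(sup.rightmost_bulk, rel=0.05)

    def test_untractable_case_raises(self):
        eff = effective_parameters(InteractionSpec(mu=-1.0, sigma2=1.0, rho=-0.5), 0.3, 0.1)
        with pytest.raises(UnsupportedCaseError, match="simulation"):
            bulk_support(500, 0.25, eff)


class TestBipartiteSupport:
    def test_zero_correlation_centers_at_origin(self):
        eff = effective_parameters(InteractionSpec(mu=0.0, sigma2=1.0, rho=0.0), 0.0, 0.4)
        sup = bipartite_support(600, 0.25, eff)
        assert sup.ellipses[0][0] == 0.0
        assert sup.spectral_mean == 0.0

    def test_trace_identity_for_spectral_mean(self):
        """Mean eigenvalue of XY equals (1-alpha) S rho_b sigma_b^2."""
        S, alpha, sigma2_b, rho_b = 800, 0.25, 0.3, -0.4
        eff = effective_parameters(InteractionSpec(mu=0.0, sigma2=1.0, rho=0.0), 0.0, 0.0)
        eff.sigma2_b, eff.rho_b = sigma2_b, rho_b
        eff.__post_init__()
        sup = bipartite_support(S, alpha, eff)
        assert sup.spectral_mean == pytest.approx((1 - alpha) * S * rho_b * sigma2_b)
        m = int(alpha * S)
        means = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            z1 = rng.normal(size=(m, S - m))
            z2 = rng.normal(size=(m, S - m))
            X = np.sqrt(sigma2_b) * z1
            Y = (np.sqrt(sigma2_b) * (rho_b * z1 + np.sqrt(1 - rho_b**2) * z2)).T
            means.append(np.linalg.eigvals(X @ Y).real.mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - sup.spectral_mean) < max(3 * se, 1e-6)

    def test_rightmost_matches_simulated_bipartite_bulk(self):
        block = BlockSpec(S=1000, alpha=0.25, C=0.2, Q=-0.625)  # C_w = 0
        inter = InteractionSpec(mu=0.0, sigma2=1.0, rho=-0.4)
        eff = effective_parameters(inter, block.C_w, block.C_b)
        sup = bipartite_support(block.S, block.alpha, eff)
        assert sup.sqrt_transformed
        lam = leading_eigenvalue(sample_community_matrix(block, inter, seed=29))
        assert lam == pytest.approx(sup.rightmost_bulk, rel=0.05)

    def test_requires_zero_within_variance(self):
        eff = effective_parameters(InteractionSpec(mu=0.0, sigma2=1.0), 0.2, 0.2)
        with pytest.raises(ValueError):
            bipartite_support(100, 0.5, eff)

    def test_consistent_with_equal_blocks_at_alpha_half(self):
        """At alpha = 1/2 the sqrt-transformed edge equals the equal-blocks
        ellipse edge."""
        inter = InteractionSpec(mu=0.0, sigma2=1.0, rho=-0.5)
        block = BlockSpec(S=1000, alpha=0.5, C=0.2, Q=-0.5)  # C_w = 0
        eff = effective_parameters(inter, block.C_w, block.C_b)
        sup = bipartite_support(block.S, block.alpha, eff)
        h = np.sqrt(block.S * eff.sigma2_bar) * (1 + eff.rho_bar)
        assert sup.rightmost_bulk == pytest.approx(h, rel=1e-6)


class TestSqrtEllipseRightmost:
    def test_degenerate_segment(self):
        assert sqrt_ellipse_rightmost(4.0, 5.0, 0.0) == pytest.approx(3.0)
        assert sqrt_ellipse_rightmost(-10.0, 3.0, 0.0) == 0.0

    def test_circle_at_origin(self):
        for r in (0.5, 2.0, 7.0):
            assert sqrt_ellipse_rightmost(0.0, r, r) == pytest.approx(np.sqrt(r), rel=1e-9)

    @given(
        x_c=st.floats(-50, 50),
        r_x=st.floats(0.01, 50),
        r_y=st.floats(0.01, 50),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_closed_form_matches_grid(self, x_c, r_x, r_y):
        grid = sqrt_ellipse_rightmost(x_c, r_x, r_y, method="grid")
        closed = sqrt_ellipse_rightmost(x_c, r_x, r_y, method="closed_form")
        assert closed == pytest.approx(grid, rel=1e-9, abs=1e-9)
        # the right vertex is always a candidate
        assert grid >= np.sqrt(max(x_c + r_x, 0.0)) - 1e-9


class TestCorrectOutliers:
    def _eff(self, mu, rho, C):
        return effective_parameters(InteractionSpec(mu=mu, sigma2=1.0, rho=rho), C, C)

    def test_identity_when_uncorrelated_and_centered(self):
        eff = self._eff(0.0, 0.0, 0.2)
        assert correct_outliers([5.0, -3.0], 100, eff, "uniform") == pytest.approx([5.0, -3.0])

    def test_unstructured_large_mean(self):
        S, C, mu = 1000, 0.2, -4.0
        eff = self._eff(mu, 0.0, C)
        [lam] = correct_outliers([S * C * mu], S, eff, "uniform")
        assert lam == pytest.approx(S * C * mu, rel=0.01)

    def test_bipartite_has_no_correction(self):
        eff = effective_parameters(InteractionSpec(mu=-1.0, sigma2=1.0), 0.0, 0.4)
        with pytest.raises(UnsupportedCaseError):
            correct_outliers([10.0], 100, eff, "bipartite")

    def test_corrected_outliers_match_simulation(self):
        """alpha=1/2, C=0.2, mu=-1, rho=0, Q=0.3: both corrected outliers
        within 2% of the empirically isolated ones (mean over 20 seeds)."""
        block = BlockSpec(S=1000, alpha=0.5, C=0.2, Q=0.3)
        inter = InteractionSpec(mu=-1.0, sigma2=1.0, rho=0.0)
        sup = predict_rightmost(block, inter)
        predicted = sorted(sup.outliers)
        assert len(predicted) == 2
        emp = []
        for seed in range(20):
            ev = full_spectrum(sample_community_matrix(block, inter, seed=1000 + seed))
            emp.append(np.sort(ev.real)[:2])
        emp = np.mean(emp, axis=0)
        assert predicted == pytest.approx(emp, rel=0.02)


class TestPredict:
    def test_zero_mean_no_outliers(self):
        sup = predict_rightmost(
            BlockSpec(S=500, alpha=0.5, C=0.2, Q=0.3), InteractionSpec(mu=0.0)
        )
        assert sup.outliers == []
        assert sup.rightmost == sup.rightmost_bulk

    def test_positive_mean_outlier_determines_stability(self):
        sup = predict_rightmost(
            BlockSpec(S=500, alpha=0.5, C=0.2, Q=0.0), InteractionSpec(mu=1.0)
        )
        assert len(sup.outliers) == 1
        assert sup.rightmost == max(sup.outliers) > sup.rightmost_bulk

    def test_bipartite_negative_mean_outliers_flank_bulk(self):
        sup = predict_rightmost(
            BlockSpec(S=500, alpha=0.5, C=0.2, Q=-0.5), InteractionSpec(mu=-1.0)
        )
        assert len(sup.outliers) == 2
        assert min(sup.outliers) < -sup.rightmost_bulk
        assert max(sup.outliers) > sup.rightmost_bulk
        assert sup.rightmost == max(sup.outliers)

    def test_gamma_is_one_for_unstructured_and_zero_mean(self):
        assert predict_gamma(
            BlockSpec(S=500, alpha=0.5, C=0.2, Q=0.0), InteractionSpec(mu=-1.0)
        ) == 1.0
        assert predict_gamma(
            BlockSpec(S=500, alpha=0.5, C=0.2, Q=0.35), InteractionSpec(mu=0.0, rho=-0.5)
        ) == pytest.approx(1.0, rel=1e-12)

    def test_gamma_matches_simulation_for_modular_case(self):
        """Analytic Gamma ~ 0.94 for alpha=1/2, C=0.2, mu=-1, rho=0, Q=0.4."""
        block = BlockSpec(S=1000, alpha=0.5, C=0.2, Q=0.4)
        inter = InteractionSpec(mu=-1.0, sigma2=1.0, rho=0.0)
        g = predict_gamma(block, inter)
        assert g == pytest.approx(0.94, abs=0.01)
        from blockstab import stability_ratio

        res = stability_ratio(block, inter, n_reps=10, seed=31)
        assert g == pytest.approx(res.gamma, abs=max(3 * res.se_gamma, 0.01))
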