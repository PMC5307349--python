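import numpy as np
import pytest

from hurstlab import (
    DecompositionConfig,
    ParameterSpace,
    approx_cov,
    build_sigma_inc,
    exact_cov,
    increment_autocov,
    term_cov,
)
from hurstlab.decomposition import inc_cov_long, inc_cov_short


class TestConfig:
    def test_space_inferred(self):
        assert DecompositionConfig(H=0.3).space is ParameterSpace.SHORT
        assert DecompositionConfig(H=0.7).space is ParameterSpace.LONG
        assert DecompositionConfig(H=0.5).space is ParameterSpace.SHORT

    def test_full_space_rejected(self):
        with pytest.raises(ValueError):
            DecompositionConfig(H=0.3, space=ParameterSpace.FULL)

    def test_mismatched_space_rejected(self):
        with pytest.raises(ValueError):
            DecompositionConfig(H=0.3, space=ParameterSpace.LONG)
        with pytest.raises(ValueError):
            DecompositionConfig(H=0.7, space=ParameterSpace.SHORT)

    def test_boundary_h_half_allowed_in_long(self):
        # the persistent representation is continuous down to a = 1
        cfg = DecompositionConfig(H=0.5, space=ParameterSpace.LONG)
        assert cfg.space is ParameterSpace.LONG

    def test_invalid_H_and_N(self):
        with pytest.raises(ValueError):
            DecompositionConfig(H=0.0)
        with pytest.raises(ValueError):
            DecompositionConfig(H=1.0)
        with pytest.raises(ValueError):
            DecompositionConfig(H=0.3, N=0)

    def test_ladder_shapes(self):
        cfg = DecompositionConfig(H=0.3, N=50)
        assert len(cfg.cuts) == 51
        assert len(cfg.rates) == 50
        assert len(cfg.weights) == 50
        assert np.all(np.diff(cfg.cuts) > 0)
        # each mean rate lies inside its ladder interval
        assert np.all(cfg.rates >= cfg.cuts[:-1])
        assert np.all(cfg.rates <= cfg.cuts[1:])

    def test_weights_nonnegative(self):
        for H in (0.1, 0.3, 0.49, 0.55, 0.7, 0.9):
            cfg = DecompositionConfig(H=H)
            assert np.all(cfg.weights >= 0)
            assert cfg.bm_weight >= 0
            assert cfg.slope_weight >= 0
            assert cfg.noise_weight >= 0


class TestBrownianCollapse:
    """At H = 1/2 all OU weights vanish and the series is exactly BM."""

    def test_short_regime_is_exact_min(self):
        cfg = DecompositionConfig(H=0.5, N=20)
        assert np.max(np.abs(cfg.weights)) == 0.0
        for t, s in [(0.2, 0.9), (0.5, 0.5), (1.0, 0.1)]:
            assert approx_cov(t, s, cfg) == pytest.approx(min(t, s), abs=1e-12)

    def test_long_regime_is_exact_min(self):
        cfg = DecompositionConfig(H=0.5, N=20, space=ParameterSpace.LONG)
        for t, s in [(0.2, 0.9), (0.5, 0.5)]:
            assert approx_cov(t, s, cfg) == pytest.approx(min(t, s), abs=1e-12)

    def test_increments_iid_at_half(self):
        m = 4
        cfg = DecompositionConfig(H=0.5, N=20)
        cov = build_sigma_inc(np.arange(1, m + 1) / m, cfg)
        np.testing.assert_allclose(cov.values, np.eye(m - 1) / m, atol=1e-12)


class TestTermCov:
    def test_vanishes_at_zero_time(self):
        cs = DecompositionConfig(H=0.3, N=10)
        cl = DecompositionConfig(H=0.7, N=10)
        for n in (1, 5, 10):
            assert term_cov(1, n, 0.0, 0.7, cs) == pytest.approx(0.0)
            assert term_cov(2, n, 0.0, 0.7, cl) == pytest.approx(0.0)
            assert term_cov(3, n, 0.0, 0.7, cl) == pytest.approx(0.0, abs=1e-15)

    def test_symmetry(self):
        cs = DecompositionConfig(H=0.3, N=10)
        cl = DecompositionConfig(H=0.7, N=10)
        for i, cfg in [(1, cs), (2, cl), (3, cl)]:
            assert term_cov(i, 3, 0.2, 0.8, cfg) == pytest.approx(term_cov(i, 3, 0.8, 0.2, cfg))

    def test_type_checks(self):
        cs = DecompositionConfig(H=0.3, N=10)
        cl = DecompositionConfig(H=0.7, N=10)
        with pytest.raises(ValueError):
            term_cov(1, 1, 0.1, 0.2, cl)
        with pytest.raises(ValueError):
            term_cov(2, 1, 0.1, 0.2, cs)
        with pytest.raises(ValueError):
            term_cov(4, 1, 0.1, 0.2, cs)
        with pytest.raises(ValueError):
            term_cov(1, 0, 0.1, 0.2, cs)
        with pytest.raises(ValueError):
            term_cov(1, 11, 0.1, 0.2, cs)

    def test_short_term_against_ou_monte_carlo(self):
        """Oracle: exact AR(1) simulation of the stationary OU difference."""
        cfg = DecompositionConfig(H=0.3, N=8)
        n = 5
        b = cfg.rates[n - 1]
        w = cfg.weights[n - 1]
        rng = np.random.default_rng(314)
        R = 200_000
        t1, t2 = 0.3, 0.8
        # exact Gaussian bridge of a stationary OU at times 0, t1, t2
        u0 = rng.normal(0, np.sqrt(w / 2), R)
        phi1 = np.exp(-b * t1)
        u1 = phi1 * u0 + rng.normal(0, np.sqrt((w / 2) * (1 - phi1**2)), R)
        phi2 = np.exp(-b * (t2 - t1))
        u2 = phi2 * u1 + rng.normal(0, np.sqrt((w / 2) * (1 - phi2**2)), R)
        d1, d2 = u1 - u0, u2 - u0
        got = float(np.mean(d1 * d2))
        want = term_cov(1, n, t1, t2, cfg)
        se = float(np.std(d1 * d2)) / np.sqrt(R)
        assert abs(got - want) < 4 * se + 1e-12

    def test_long_terms_against_integrated_ou_monte_carlo(self):
        """Oracle: fine-grid integration of a stationary OU path."""
        cfg = DecompositionConfig(H=0.75, N=6)
        n = 3
        b = cfg.rates[n - 1]
        w = cfg.weights[n - 1]
        sigma2 = w * b * b / 2.0  # stationary OU variance giving Var(int) = g
        rng = np.random.default_rng(2718)
        R, steps = 40_000, 400
        dt = 1.0 / steps
        phi = np.exp(-b * dt)
        innov_sd = np.sqrt(sigma2 * (1 - phi**2))
        u = rng.normal(0, np.sqrt(sigma2), R)
        u0 = u.copy()
        integ = np.zeros(R)
        i1 = i2 = None
        t1, t2 = 0.4, 0.9
        for k in range(1, steps + 1):
            u_new = phi * u + innov_sd * rng.normal(size=R)
            integ = integ + 0.5 * dt * (u + u_new)  # trapezoid
            u = u_new
            if abs(k * dt - t1) < dt / 2:
                i1 = integ.copy()
            if abs(k * dt - t2) < dt / 2:
                i2 = integ.copy()
        # initial-condition component and its complement
        x2_1 = u0 * (1 - np.exp(-b * t1)) / b
        x2_2 = u0 * (1 - np.exp(-b * t2)) / b
        got_full = float(np.mean(i1 * i2))
        want_full = term_cov(2, n, t1, t2, cfg) + term_cov(3, n, t1, t2, cfg)
        se_full = float(np.std(i1 * i2)) / np.sqrt(R)
        assert abs(got_full - want_full) < 4 * se_full + 0.01 * abs(want_full)
        got_2 = float(np.mean(x2_1 * x2_2))
        want_2 = term_cov(2, n, t1, t2, cfg)
        se_2 = float(np.std(x2_1 * x2_2)) / np.sqrt(R)
        assert abs(got_2 - want_2) < 4 * se_2 + 1e-12


class TestApproxCov:
    def test_sum_of_terms_identity_short(self):
        """approx_cov decomposes exactly into BM band + OU terms (+ noise)."""
        cfg = DecompositionConfig(H=0.3, N=12)
        for t, s in [(0.3, 0.8), (0.5, 0.5), (1.0, 0.1)]:
            total = cfg.bm_weight * min(t, s)
            total += sum(term_cov(1, n, t, s, cfg) for n in range(1, cfg.N + 1))
            # high-frequency band: shared offset + white noise
            total += 0.5 * cfg.noise_weight * (1 + (t == s))
            assert approx_cov(t, s, cfg) == pytest.approx(total, rel=1e-12)

    def test_sum_of_terms_identity_long(self):
        cfg = DecompositionConfig(H=0.7, N=12)
        for t, s in [(0.3, 0.8), (0.5, 0.5)]:
            total = cfg.slope_weight * t * s + cfg.bm_weight * min(t, s)
            total += sum(
                term_cov(2, n, t, s, cfg) + term_cov(3, n, t, s, cfg)
                for n in range(1, cfg.N + 1)
            )
            assert approx_cov(t, s, cfg) == pytest.approx(total, rel=1e-12)

    def test_vanishes_at_zero(self):
        for H in (0.3, 0.7):
            cfg = DecompositionConfig(H=H, N=20)
            assert approx_cov(0.0, 0.6, cfg) == pytest.approx(0.0, abs=1e-14)

    def test_broadcasting_and_scalar(self):
        cfg = DecompositionConfig(H=0.3, N=10)
        t = np.array([0.2, 0.5, 1.0])
        K = approx_cov(t[:, None], t[None, :], cfg)
        assert K.shape == (3, 3)
        assert isinstance(approx_cov(0.2, 0.5, cfg), float)
        assert K[0, 1] == pytest.approx(approx_cov(0.2, 0.5, cfg))

    @pytest.mark.parametrize("H", [0.2, 0.4, 0.6, 0.8])
    def test_converges_to_exact(self, H):
        t = np.linspace(0.05, 1.0, 15)
        tt, ss = t[:, None], t[None, :]
        exact = exact_cov(tt, ss, H)

        def err(N):
            cfg = DecompositionConfig(H=H, N=N)
            return float(np.max(np.abs(approx_cov(tt, ss, cfg) - exact)))

        e10, e100 = err(10), err(100)
        assert e100 < e10
        assert e100 < 5e-3

    def test_psd_on_grid(self):
        t = np.linspace(0.05, 1.0, 25)
        for H in (0.15, 0.45, 0.65, 0.9):
            cfg = DecompositionConfig(H=H, N=40)
            K = approx_cov(t[:, None], t[None, :], cfg)
            assert np.linalg.eigvalsh(K).min() >= -1e-10


class TestIncrementAutocov:
    def test_matches_second_differences_of_cov(self):
        """Toeplitz increment matrix = second differences of the path cov.

        This holds exactly, including the first increment, because the
        high-band shared offset cancels in every difference.
        """
        m = 16
        for H in (0.1, 0.3, 0.7):
            cfg = DecompositionConfig(H=H, N=30)
            t = np.arange(0, m + 1) / m
            K = approx_cov(t[:, None], t[None, :], cfg)
            D = np.diff(np.diff(K, axis=0), axis=1)
            gamma = increment_autocov(cfg, m, np.arange(m - 1))
            for lag in range(m - 1):
                np.testing.assert_allclose(
                    np.diag(D, k=lag), gamma[lag], rtol=0, atol=1e-12
                )

    def test_inc_cov_wrappers(self):
        m = 32
        cs = DecompositionConfig(H=0.3, N=20)
        cl = DecompositionConfig(H=0.7, N=20)
        g_s = increment_autocov(cs, m, [2])[0]
        assert inc_cov_short(3 / m, 5 / m, cs, 1 / m) == pytest.approx(g_s)
        g_l = increment_autocov(cl, m, [2])[0]
        assert inc_cov_long(3 / m, 5 / m, cl, 1 / m) == pytest.approx(g_l)
        with pytest.raises(ValueError):
            inc_cov_short(0.1, 0.2, cl, 1 / m)
        with pytest.raises(ValueError):
            inc_cov_long(0.1, 0.2, cs, 1 / m)

    def test_approximates_exact_fgn_autocov(self):
        from hurstlab import exact_increment_autocov

        m = 256
        for H in (0.1, 0.3, 0.7, 0.9):
            cfg = DecompositionConfig(H=H, N=100)
            g = increment_autocov(cfg, m, [0, 1, 2, 3])
            for k in range(4):
                want = exact_increment_autocov(k, m, H)
                assert g[k] == pytest.approx(want, abs=0.03 * m ** (-2 * H))


class TestBuildSigmaInc:
    def test_requires_regular_grid(self):
        cfg = DecompositionConfig(H=0.3, N=10)
        with pytest.raises(ValueError):
            build_sigma_inc(np.array([0.1, 0.5, 1.0]), cfg)

    def test_deterministic(self):
        cfg = DecompositionConfig(H=0.3, N=30)
        t = np.arange(1, 65) / 64
        a = build_sigma_inc(t, cfg)
        b = build_sigma_inc(t, cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_shape_metadata_and_factorizable(self):
        from scipy.linalg import cho_factor

        cfg = DecompositionConfig(H=0.7, N=30)
        t = np.arange(1, 129) / 128
        cov = build_sigma_inc(t, cfg)
        assert cov.values.shape == (127, 127)
        assert cov.H == 0.7 and cov.N == 30
        assert cov.jitter <= 1e-6 * np.mean(np.diag(cov.values)) + 1e-30
        cho_factor(cov.values, lower=True)  # must not raise

    def test_toeplitz_structure(self):
        cfg = DecompositionConfig(H=0.2, N=20)
        t = np.arange(1, 33) / 32
        S = build_sigma_inc(t, cfg).values
        first = S[0]
        for i in range(1, len(S)):
            np.testing.assert_allclose(S[i, i:], first[: len(S) - i], atol=1e-15)
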