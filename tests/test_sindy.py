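import numpy as np
import pytest

from dyndisc import sindy
from dyndisc.stability import lorenz_coeff_matrix


class TestLibrary:
    @pytest.mark.parametrize("d,expected", [(1, 4), (2, 10), (3, 20)])
    def test_term_counts(self, d, expected):
        assert sindy.build_library(d).n_terms == expected

    def test_constant_first_graded_order(self):
        lib = sindy.build_library(2)
        assert lib.terms[0] == (0, 0)
        degrees = [sum(t) for t in lib.terms]
        assert degrees == sorted(degrees)

    def test_one_dimensional_terms(self):
        lib = sindy.build_library(1)
        assert lib.terms == ((0,), (1,), (2,), (3,))

    def test_evaluate_matches_monomials(self):
        lib = sindy.build_library(2)
        V = np.array([[2.0, 3.0]])
        theta = sindy.evaluate_library(lib, V)[0]
        expected = [2.0**a * 3.0**b for a, b in lib.terms]
        assert np.allclose(theta, expected)


class TestDerivatives:
    def test_linear_ramp_exact(self):
        t = np.arange(50.0)
        V = np.column_stack([3 * t, -0.5 * t])
        _, dV = sindy.estimate_derivatives(V)
        assert np.allclose(dV[:, 0], 3.0) and np.allclose(dV[:, 1], -0.5)

    def test_cubic_exact_at_interior(self):
        t = np.arange(60.0)
        V = (t**3)[:, None]
        Vt, dV = sindy.estimate_derivatives(V)
        # the stencil is exact for cubics; the 3-point average of 3t^2 over
        # {t-1, t, t+1} adds exactly 2
        expected = 3 * t[2:-2] ** 2 + 2.0
        assert np.allclose(dV[2:-2, 0], expected[2:-2], rtol=1e-10)

    def test_sine_derivative_accuracy(self):
        t = np.arange(0, 1000)
        f = 5.0  # Hz at 1 kHz sampling
        V = np.sin(2 * np.pi * f * t / 1000)[:, None]
        _, dV = sindy.estimate_derivatives(V)
        true = (2 * np.pi * f / 1000) * np.cos(2 * np.pi * f * t / 1000)
        # interior points (the truncated smoothing at the two ends is coarser)
        err = np.abs(dV[1:-1, 0] - true[3:-3]).max()
        assert err < 1e-3 * (2 * np.pi * f / 1000)

    def test_alignment_and_length(self):
        V = np.random.default_rng(0).normal(size=(30, 2))
        Vt, dV = sindy.estimate_derivatives(V)
        assert Vt.shape == dV.shape == (26, 2)
        assert np.array_equal(Vt, V[2:-2])

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            sindy.estimate_derivatives(np.zeros((6, 2)))


class TestNormalization:
    def test_zscore_definition(self):
        rng = np.random.default_rng(0)
        lib = sindy.build_library(2)
        theta = sindy.evaluate_library(lib, rng.normal(size=(200, 2)))
        tz, norm = sindy.normalize_library(theta, lib)
        assert np.allclose(tz[:, 0], 1.0)  # constant column untouched
        assert np.abs(tz[:, 1:].mean(axis=0)).max() < 1e-12
        assert np.abs(tz[:, 1:].std(axis=0) - 1).max() < 1e-12

    def test_denormalization_round_trip(self):
        rng = np.random.default_rng(1)
        lib = sindy.build_library(3)
        theta = sindy.evaluate_library(lib, rng.normal(size=(100, 3)))
        tz, norm = sindy.normalize_library(theta, lib)
        assert np.allclose(tz * norm.sigma + norm.mu, theta, atol=1e-12)

    def test_zero_variance_column_named(self):
        lib = sindy.build_library(1)
        theta = np.ones((50, 4))  # x column constant
        with pytest.raises(ValueError, match="zero-variance"):
            sindy.normalize_library(theta, lib)


class TestFitting:
    def test_exact_linear_recovery(self):
        # dv = 2x with mask selecting only x
        lib = sindy.build_library(1)
        x = np.linspace(-1, 1, 200)[:, None]
        theta = sindy.evaluate_library(lib, x)
        tz, norm = sindy.normalize_library(theta, lib)
        dv = 2.0 * x
        mask = np.zeros((4, 1), dtype=np.uint8)
        mask[0] = mask[1] = 1
        cm = sindy.fit_coefficients(tz, dv, mask, norm, lib)
        raw = cm.denormalized()
        assert raw[1, 0] == pytest.approx(2.0, rel=1e-9)
        assert np.allclose(raw[2:], 0.0)

    def test_lorenz_parameter_recovery_under_true_support(
        self, clean_lorenz_states
    ):
        V, dt = clean_lorenz_states
        ref = lorenz_coeff_matrix(rho=28.0)
        cm = sindy.fit_trajectory(V, ref.mask, ref.library)
        raw = cm.denormalized() / dt  # per-sample -> per-time-unit
        nz = ref.xi != 0
        rel_err = np.abs(raw[nz] - ref.xi[nz]) / np.abs(ref.xi[nz])
        assert rel_err.max() < 0.01

    def test_all_zero_mask_column_rejected(self):
        lib = sindy.build_library(2)
        mask = np.ones((10, 2), dtype=np.uint8)
        mask[:, 1] = 0
        with pytest.raises(ValueError):
            sindy.fit_coefficients(np.ones((5, 10)), np.ones((5, 2)), mask,
                                   None, lib)

    def test_residual_orthogonality(self):
        rng = np.random.default_rng(2)
        lib = sindy.build_library(2)
        V = rng.normal(size=(300, 2))
        theta = sindy.evaluate_library(lib, V)
        tz, norm = sindy.normalize_library(theta, lib)
        dv = rng.normal(size=(300, 2))
        mask = np.zeros((10, 2), dtype=np.uint8)
        mask[[0, 1, 2, 4], 0] = 1
        mask[[0, 3, 5], 1] = 1
        cm = sindy.fit_coefficients(tz, dv, mask, norm, lib)
        for k in range(2):
            sel = mask[:, k].astype(bool)
            resid = dv[:, k] - tz[:, sel] @ cm.xi[sel, k]
            assert np.abs(tz[:, sel].T @ resid).max() < 1e-8 * len(dv)


class TestIntegration:
    def _decay_system(self):
        # 1-D dv = -0.1 v fitted from data, then integrated
        lib = sindy.build_library(1)
        t = np.arange(300.0)
        v = np.exp(-0.01 * t)[:, None]
        mask = np.zeros((4, 1), dtype=np.uint8)
        mask[0] = mask[1] = 1
        return sindy.fit_trajectory(v, mask, lib), v

    def test_one_step_euler_arithmetic(self):
        cm, _ = self._decay_system()
        ic = np.array([1.0])
        out, blew = sindy.integrate_model(cm, ic, 1)
        expected = ic + sindy.rhs(cm, ic)
        assert not blew
        assert np.allclose(out[1], expected)

    def test_constant_only_model_drifts_linearly(self):
        lib = sindy.build_library(1)
        cm = sindy.CoeffMatrix(
            xi=np.array([[0.3], [0.0], [0.0], [0.0]]),
            mask=np.array([[1], [0], [0], [0]], dtype=np.uint8),
            norm=sindy.NormStats(mu=np.zeros(4), sigma=np.ones(4)),
            library=lib,
        )
        out, blew = sindy.integrate_model(cm, np.array([0.0]), 10)
        assert not blew
        assert np.allclose(out[:, 0], 0.3 * np.arange(11))

    def test_linear_system_matches_exponential_to_first_order(self):
        cm, v = self._decay_system()
        out, _ = sindy.integrate_model(cm, np.array([1.0]), 100)
        # Euler on dv = -a v vs exp(-a t), a ~ 0.01 per step
        true = np.exp(-0.01 * np.arange(101))
        assert np.abs(out[:, 0] - true).max() < 0.01

    def test_lorenz_fit_integration_stays_bounded(self, clean_lorenz_states):
        V, dt = clean_lorenz_states
        ref = lorenz_coeff_matrix(rho=28.0)
        cm = sindy.fit_trajectory(V, ref.mask, ref.library)
        out, blew = sindy.integrate_model(
            cm, V[0], 1000, data_scale=np.abs(V).max()
        )
        assert not blew
        box = 5 * np.abs(V).max(axis=0)
        assert (np.abs(out) <= box).all()

    def test_blow_up_flagged_not_raised(self):
        lib = sindy.build_library(1)
        cm = sindy.CoeffMatrix(
            xi=np.array([[0.0], [2.0], [0.0], [0.0]]),  # dv = 2v, explosive
            mask=np.array([[1], [1], [0], [0]], dtype=np.uint8),
            norm=sindy.NormStats(mu=np.zeros(4), sigma=np.ones(4)),
            library=lib,
        )
        out, blew = sindy.integrate_model(cm, np.array([1.0]), 500,
                                          data_scale=1.0)
        assert blew and len(out) < 501


class TestScreening:
    def test_screening_bounds(self, clean_lorenz_states):
        V, dt = clean_lorenz_states
        ref = lorenz_coeff_matrix(rho=28.0)
        cm = sindy.fit_trajectory(V, ref.mask, ref.library)
        src = V[: 2000]
        cands = src[[0, 500, 1000]]
        accepted = sindy.screen_initial_conditions(cm, src, cands)
        assert len(accepted) >= 1  # self-consistent fit keeps some ICs

    def test_explosive_and_collapsing_candidates_rejected(self):
        lib = sindy.build_library(1)
        explosive = sindy.CoeffMatrix(
            xi=np.array([[0.0], [2.0], [0.0], [0.0]]),
            mask=np.array([[1], [1], [0], [0]], dtype=np.uint8),
            norm=sindy.NormStats(mu=np.zeros(4), sigma=np.ones(4)),
            library=lib,
        )
        src = np.sin(np.arange(3000.0) / 10)[:, None]
        assert sindy.screen_initial_conditions(explosive, src,
                                               np.array([[1.0]])) == []
        collapsing = sindy.CoeffMatrix(
            xi=np.array([[0.0], [-1.0], [0.0], [0.0]]),  # extinguishes at once
            mask=np.array([[1], [1], [0], [0]], dtype=np.uint8),
            norm=sindy.NormStats(mu=np.zeros(4), sigma=np.ones(4)),
            library=lib,
        )
        assert sindy.screen_initial_conditions(collapsing, src,
                                               np.array([[1.0]])) == []
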