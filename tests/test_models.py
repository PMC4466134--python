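import numpy as np
import pytest
from sklearn.base import clone

from einscan.constants import K_B, M2_TO_A2, PLANCK_H
from einscan.models import (
    BimodalElasticModel,
    EinsteinOscillatorModel,
    GaussianElasticModel,
    PiecewiseLinearModel,
    oscillator_msd,
)


def wls_normal_equations(q2, ln_s, w):
    """Independent oracle: weighted normal equations solved directly."""
    A = np.column_stack([np.ones_like(q2), q2])
    W = np.diag(w)
    beta = np.linalg.solve(A.T @ W @ A, A.T @ W @ ln_s)
    return beta  # [intercept, slope]


class TestGaussianElasticModel:
    def test_exact_log_linear_data(self):
        q2 = np.linspace(0.1, 4.0, 10)
        s = 1.0 * np.exp(-0.3 * q2 / 6.0)
        m = GaussianElasticModel().fit(q2[:, None], s)
        assert m.msd_ == pytest.approx(0.3, rel=1e-12)
        assert m.i0_ == pytest.approx(1.0, rel=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            q2 = np.sort(rng.uniform(0.05, 4.0, 5))
            s = rng.uniform(0.8, 1.2) * np.exp(-rng.uniform(0.0, 0.5) * q2 / 6.0)
            s *= np.exp(rng.normal(0, 0.02, 5))
            w = rng.uniform(0.5, 2.0, 5)
            m = GaussianElasticModel().fit(q2[:, None], s, sample_weight=w)
            intercept, slope = wls_normal_equations(q2, np.log(s), w)
            assert m.slope_ == pytest.approx(slope, abs=1e-10)
            assert m.intercept_ == pytest.approx(intercept, abs=1e-10)

    def test_matches_brute_force_grid_search(self):
        # coarse grid + local refinement over (i0, u2), minimising weighted SSE
        q2 = np.array([0.2, 0.8, 1.6, 2.7, 3.9])
        s = 1.05 * np.exp(-0.42 * q2 / 6.0) * np.exp([0.01, -0.02, 0.015, 0.0, -0.01])
        m = GaussianElasticModel().fit(q2[:, None], s)
        ln_s = np.log(s)
        best = None
        for i0 in np.linspace(0.9, 1.2, 301):
            for u in np.linspace(0.2, 0.7, 501):
                sse = np.sum((ln_s - (np.log(i0) - u * q2 / 6.0)) ** 2)
                if best is None or sse < best[0]:
                    best = (sse, i0, u)
        assert m.i0_ == pytest.approx(best[1], abs=1e-3)
        assert m.msd_ == pytest.approx(best[2], abs=1e-3)

    def test_rejects_nonpositive_intensity(self):
        with pytest.raises(ValueError):
            GaussianElasticModel().fit(np.array([[0.1], [0.2], [0.3]]),
                                       np.array([1.0, -0.1, 0.5]))

    def test_predict_round_trip(self):
        q2 = np.linspace(0.1, 3.0, 8)
        s = 0.95 * np.exp(-0.25 * q2 / 6.0)
        m = GaussianElasticModel().fit(q2[:, None], s)
        np.testing.assert_allclose(m.predict(q2[:, None]), s, rtol=1e-12)


class TestOscillatorMsd:
    def test_zero_temperature_is_zero(self):
        assert oscillator_msd(3.7, 2.5, 0.0) == 0.0

    def test_table_parameters_at_room_temperature(self):
        # published harmonic level: <u2>/6 ~ 0.05 AA^2 at 300 K
        u2 = oscillator_msd(3.7, 2.5, 300.0)
        assert u2 == pytest.approx(0.273, abs=0.001)
        assert round(u2 / 6.0, 2) == 0.05

    def test_strictly_increasing_in_temperature(self):
        t = np.linspace(1.0, 400.0, 200)
        u2 = oscillator_msd(1.5, 2.0, t)
        assert np.all(np.diff(u2) > 0)

    def test_decreasing_in_force_constant(self):
        ks = [0.5, 1.0, 5.0, 20.0]
        vals = [oscillator_msd(k, 2.5, 200.0) for k in ks]
        assert np.all(np.diff(vals) < 0)

    def test_classical_high_temperature_slope(self):
        k, nu = 2.0, 1.0
        t_high = 10 * PLANCK_H * nu * 1e12 / K_B
        eps = 1.0
        slope = (
            oscillator_msd(k, nu, t_high + eps) - oscillator_msd(k, nu, t_high - eps)
        ) / (2 * eps)
        classical = 3 * K_B / k * M2_TO_A2
        assert slope == pytest.approx(classical, rel=0.01)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            oscillator_msd(-1.0, 2.5, 100.0)
        with pytest.raises(ValueError):
            oscillator_msd(1.0, 2.5, -5.0)


class TestBimodalElasticModel:
    @staticmethod
    def forward(q2, i0, a1, u1, u2):
        return i0 * (a1 * np.exp(-u1 * q2 / 6.0) + (1 - a1) * np.exp(-u2 * q2 / 6.0))

    def test_noise_free_round_trip_on_in13_grid(self, in13):
        q = np.linspace(in13.q_min, in13.q_max, 16)
        q2 = q**2
        s = self.forward(q2, 1.0, 0.26, 2.0, 0.2)
        m = BimodalElasticModel(a1=0.26).fit(q2[:, None], s)
        assert m.i0_ == pytest.approx(1.0, rel=1e-6)
        assert m.msd1_ == pytest.approx(2.0, rel=1e-6)
        assert m.msd2_ == pytest.approx(0.2, rel=1e-6)
        assert m.converged_ and m.separated_

    def test_equal_populations_collapse_to_single_gaussian(self, in13):
        q2 = np.linspace(in13.q_min, in13.q_max, 16) ** 2
        s = self.forward(q2, 1.0, 0.26, 0.5, 0.5)
        m = BimodalElasticModel(a1=0.26).fit(q2[:, None], s)
        # residual identical to the single-Gaussian solution
        np.testing.assert_allclose(m.predict(q2[:, None]), s, atol=1e-10)
        assert not m.separated_
        assert m.msd1_ == pytest.approx(0.5, abs=1e-6)
        assert m.msd2_ == pytest.approx(0.5, abs=1e-6)

    def test_zero_methyl_fraction_reduces_to_gaussian(self, in13):
        q2 = np.linspace(in13.q_min, in13.q_max, 16) ** 2
        s = np.exp(-0.35 * q2 / 6.0)
        m = BimodalElasticModel(a1=0.0).fit(q2[:, None], s)
        assert m.msd2_ == pytest.approx(0.35, rel=1e-6)

    def test_free_fractions_recovers_a1(self, in13):
        q2 = np.linspace(in13.q_min, in13.q_max, 24) ** 2
        s = self.forward(q2, 1.0, 0.3, 2.5, 0.1)
        m = BimodalElasticModel(a1=0.26, free_fractions=True).fit(q2[:, None], s)
        assert m.a1_ == pytest.approx(0.3, abs=1e-4)

    def test_ordering_constraint_enforced(self, in13):
        q2 = np.linspace(in13.q_min, in13.q_max, 16) ** 2
        rng = np.random.default_rng(5)
        s = self.forward(q2, 1.0, 0.26, 1.2, 0.3) * np.exp(rng.normal(0, 0.01, 16))
        m = BimodalElasticModel(a1=0.26).fit(q2[:, None], s)
        assert m.msd1_ >= m.msd2_ >= 0.0


class TestEinsteinOscillatorModel:
    def test_noise_free_recovery(self):
        t = np.arange(20.0, 150.1, 5.0)
        y = oscillator_msd(3.7, 2.5, t) - oscillator_msd(3.7, 2.5, 20.0)
        m = EinsteinOscillatorModel().fit(t[:, None], y)
        assert m.force_constant_k_ == pytest.approx(3.7, rel=1e-4)
        assert m.frequency_nu_ == pytest.approx(2.5, rel=1e-4)

    def test_all_zero_series_rejected(self):
        t = np.arange(20.0, 150.1, 5.0)
        with pytest.raises(ValueError, match="all-zero"):
            EinsteinOscillatorModel().fit(t[:, None], np.zeros_like(t))

    def test_multiplicative_noise_median_recovery(self):
        # per-point 3% multiplicative noise on the series, many seeds
        t = np.arange(20.0, 150.1, 5.0)
        truth = oscillator_msd(3.7, 2.5, t) - oscillator_msd(3.7, 2.5, 20.0)
        rng = np.random.default_rng(0)
        rel_err = []
        for _ in range(100):
            y = truth * (1 + rng.normal(0, 0.03, t.size))
            m = EinsteinOscillatorModel().fit(t[:, None], y)
            rel_err.append(abs(m.force_constant_k_ - 3.7) / 3.7)
        assert np.median(rel_err) <= 0.15

    def test_sklearn_protocol(self):
        m = EinsteinOscillatorModel(n_starts=3)
        params = m.get_params()
        assert params["n_starts"] == 3
        m2 = clone(m).set_params(n_starts=4)
        assert m2.get_params()["n_starts"] == 4


class TestPiecewiseLinearModel:
    def test_exact_line_selects_zero_breaks(self):
        x = np.arange(0.0, 50.0)
        y = 2.0 - 0.1 * x
        m = PiecewiseLinearModel(max_breakpoints=2).fit(x[:, None], y)
        assert m.n_breakpoints_ == 0
        assert m.segment_slopes_[0] == pytest.approx(-0.1)

    def test_two_breaks_recovered(self):
        x = np.arange(0.0, 60.0)
        y = (
            1.0
            - 0.02 * x
            - 0.05 * np.maximum(0.0, x - 20.0)
            - 0.08 * np.maximum(0.0, x - 40.0)
        )
        m = PiecewiseLinearModel(max_breakpoints=2).fit(x[:, None], y)
        assert m.breakpoints_ == [20.0, 40.0]
        slopes = m.segment_slopes_
        assert slopes == pytest.approx([-0.02, -0.07, -0.15])

    def test_predict_interpolates_fit(self):
        x = np.arange(0.0, 30.0)
        y = 1.0 - 0.1 * np.maximum(0.0, x - 10.0)
        m = PiecewiseLinearModel(max_breakpoints=1).fit(x[:, None], y)
        np.testing.assert_allclose(m.predict(x[:, None]), y, atol=1e-10)
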