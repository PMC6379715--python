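"""Two-state melting simulation/fitting and CD signature classification."""
import numpy as np
import pytest

from quadfold.melting import (
    MeltingCurve,
    MeltingFitError,
    TwoStateMeltModel,
    classify_cd,
    fit_two_state,
    folded_fraction,
    hysteresis,
    simulate_melt,
    synthetic_cd_spectrum,
)


class TestModelAnalytics:
    def test_theta_is_half_at_tm(self):
        assert folded_fraction(60.0, 60.0, 45.0) == pytest.approx(0.5)

    def test_large_enthalpy_approaches_step(self):
        th = folded_fraction(np.array([59.0, 61.0]), 60.0, 2000.0)
        assert th[0] > 0.999 and th[1] < 0.001

    def test_theta_monotone_decreasing(self):
        T = np.arange(15, 95, 0.5)
        th = folded_fraction(T, 60.0, 45.0)
        assert np.all(np.diff(th) < 0)

    def test_simulation_deterministic(self):
        a = simulate_melt(60.0, 45.0, noise_sd=0.002, seed=5)
        b = simulate_melt(60.0, 45.0, noise_sd=0.002, seed=5)
        assert np.array_equal(a.signal, b.signal)


class TestFitting:
    def test_noiseless_self_consistency(self):
        c = simulate_melt(60.0, 45.0)
        f = fit_two_state(c)
        assert f.tm_celsius == pytest.approx(60.0, abs=0.1)
        assert f.dh_kcal == pytest.approx(45.0, rel=0.01)
        sig_range = c.signal.max() - c.signal.min()
        assert f.residual_rms < 1e-6 * sig_range
        assert np.all((f.theta >= 0) & (f.theta <= 1))

    def test_flat_curve_raises(self, rng):
        curve = MeltingCurve(
            np.arange(15, 95, 0.5),
            np.full(160, 1.0) + rng.normal(0, 0.002, 160),
        )
        with pytest.raises(MeltingFitError):
            fit_two_state(curve)

    def test_results_summary_and_bse(self):
        c = simulate_melt(60.2, 45.0, noise_sd=0.002, seed=1)
        res = TwoStateMeltModel(c).fit()
        s = res.summary()
        assert "Tm" in s and "van't Hoff" in s
        assert res.fit.bse["tm_celsius"] < 0.5

    @pytest.mark.parametrize("tm", [50.0, 55.0, 60.0, 65.0])
    @pytest.mark.parametrize("dh", [30.0, 45.0, 60.0])
    def test_parameter_recovery_grid(self, tm, dh):
        """Bias < 0.3 C and RMSE < 1.0 C over noisy replicates."""
        recovered = []
        for rep in range(100):
            c = simulate_melt(tm, dh, noise_sd=0.002, seed=rep + int(tm * 13 + dh))
            recovered.append(fit_two_state(c).tm_celsius)
        recovered = np.array(recovered)
        assert abs(recovered.mean() - tm) < 0.3
        assert np.sqrt(np.mean((recovered - tm) ** 2)) < 1.0


class TestHysteresis:
    def test_equilibrium_curves_are_consistent(self):
        heat = simulate_melt(60.0, 45.0)
        cool = simulate_melt(60.0, 45.0, direction="cooling")
        d, ok = hysteresis(heat, cool)
        assert d < 0.2
        assert ok
        # noisy equilibrium curves stay inside the 2 C criterion
        heat = simulate_melt(60.0, 45.0, noise_sd=0.002, seed=7)
        cool = simulate_melt(60.0, 45.0, noise_sd=0.002, seed=8, direction="cooling")
        d, ok = hysteresis(heat, cool)
        assert ok and d < 2.0

    def test_shifted_tm_flagged(self):
        heat = simulate_melt(60.0, 45.0)
        cool = simulate_melt(63.0, 45.0, direction="cooling")
        d, ok = hysteresis(heat, cool)
        assert d == pytest.approx(3.0, abs=0.1)
        assert not ok


class TestCsv:
    def test_roundtrip(self):
        c = simulate_melt(60.0, 45.0, noise_sd=0.001, seed=3)
        again = MeltingCurve.from_csv(c.to_csv())
        assert again.direction == c.direction
        assert np.allclose(again.signal, c.signal, atol=1e-6)


class TestCd:
    @pytest.mark.parametrize(
        "peaks,expected",
        [
            ([(265, 1.0), (290, 0.8), (240, -0.9)], "hybrid"),
            ([(265, 1.0), (240, -0.9)], "parallel"),
            ([(295, 1.0), (265, -0.9)], "antiparallel"),
        ],
    )
    def test_signatures(self, peaks, expected):
        wl, y = synthetic_cd_spectrum(peaks)
        assert classify_cd(wl, y) == expected

    def test_flat_unclassified(self):
        wl = np.arange(220, 321.0)
        assert classify_cd(wl, np.zeros_like(wl)) == "unclassified"

    def test_short_range_unclassified(self):
        wl = np.arange(250, 301.0)
        assert classify_cd(wl, np.sin(wl / 10)) == "unclassified"
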