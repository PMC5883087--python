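import numpy as np
import pytest

from bproline import (
    EnergyTable,
    ExchangeModel,
    PopulationTable,
    boltzmann_dg,
    coalescence_dg,
    coalescence_rate,
    eyring_rate,
    fit_exchange,
    make_exchange_profiles,
    populations_from_dg,
    simulate_lineshape,
)
from bproline.thermo import R_KCAL, eyring_dg


class TestBoltzmann:
    def test_tetramer_energy_from_printed_populations(self):
        e = boltzmann_dg(PopulationTable({"ZZZ": 42.0, "ZZE": 23.0}, 298.0))
        assert round(e.energies["ZZE"], 2) == 0.36
        assert e.energies["ZZZ"] == pytest.approx(0.0, abs=1e-12)

    def test_pentamer_energy_from_printed_populations(self):
        e = boltzmann_dg(PopulationTable({"ZZEZ": 55.0, "ZEZZ": 21.0}, 298.0))
        assert round(e.energies["ZEZZ"], 2) == 0.57

    def test_equal_populations_all_zero(self):
        e = boltzmann_dg(PopulationTable({"A": 30.0, "B": 30.0, "C": 30.0}, 298.0))
        assert all(abs(v) < 1e-12 for v in e.energies.values())

    def test_mutually_inverse_with_populations(self):
        e = EnergyTable({"ZZZ": 0.0, "ZZE": 0.36, "ZEZ": 0.57, "EZZ": 1.39}, 298.0)
        p = populations_from_dg(e)
        back = boltzmann_dg(p)
        for label in e.energies:
            assert back.energies[label] == pytest.approx(e.energies[label], abs=1e-9)

    def test_closed_form_two_state_populations(self):
        dg = R_KCAL * 298.0 * np.log(2.0)
        p = populations_from_dg(EnergyTable({"A": 0.0, "B": dg}, 298.0))
        assert p.populations["A"] == pytest.approx(200.0 / 3.0, abs=1e-9)
        assert p.populations["B"] == pytest.approx(100.0 / 3.0, abs=1e-9)

    def test_invalid_populations_rejected(self):
        with pytest.raises(ValueError):
            PopulationTable({"A": -1.0}, 298.0)
        with pytest.raises(ValueError):
            PopulationTable({"A": 60.0, "B": 60.0}, 298.0)


class TestRates:
    def test_zero_barrier_gives_prefactor(self):
        # independent evaluation of k_B*T/h at 298 K
        assert eyring_rate(0.0, 298.0) == pytest.approx(
            1.380649e-23 * 298.0 / 6.62607015e-34, rel=1e-12
        )
        assert eyring_rate(0.0, 298.0) == pytest.approx(6.21e12, rel=1e-3)

    def test_barrier_rate_magnitude(self):
        k = eyring_rate(20.6, 298.0)
        oracle = (1.380649e-23 * 298.0 / 6.62607015e-34) * np.exp(
            -20.6 / (1.98720425e-3 * 298.0)
        )
        assert k == pytest.approx(oracle, rel=1e-12)
        assert 1e-3 < k < 1e-2  # ~5×10⁻³ s⁻¹

    def test_rate_monotone_in_temperature(self):
        ks = [eyring_rate(20.6, t) for t in (298.0, 348.0, 398.0, 408.0)]
        assert all(a < b for a, b in zip(ks, ks[1:]))

    def test_coalescence_rate(self):
        assert coalescence_rate(100.0) == pytest.approx(np.pi * 100.0 / np.sqrt(2.0))
        assert coalescence_rate(100.0) == pytest.approx(222.14, abs=0.01)
        assert coalescence_rate(1e-6) < 1e-5

    def test_coalescence_eyring_inverse_consistency(self):
        dg = coalescence_dg(100.0, 350.0)
        assert eyring_rate(dg, 350.0) == pytest.approx(
            coalescence_rate(100.0), rel=1e-6
        )


class TestLineshape:
    grid = np.linspace(-120.0, 120.0, 8001)

    def test_no_exchange_limit_two_lorentzians(self):
        m = ExchangeModel(-20.0, 20.0, 0.3, 0.0, 0.5)
        y = simulate_lineshape(m, self.grid)
        # peaks at the site frequencies
        peaks = self.grid[np.argsort(y)[-2:]]
        assert sorted(np.round(np.abs(peaks), 1)) == [20.0, 20.0]
        # area ratio ~ population ratio
        area_a = np.trapezoid(y[self.grid < 0], self.grid[self.grid < 0])
        area_b = np.trapezoid(y[self.grid > 0], self.grid[self.grid > 0])
        assert area_a / area_b == pytest.approx(0.3 / 0.7, rel=0.02)

    def test_fast_exchange_limit_single_weighted_peak(self):
        m = ExchangeModel(-20.0, 20.0, 0.3, 1e7, 0.5)
        y = simulate_lineshape(m, self.grid)
        nu_max = self.grid[np.argmax(y)]
        assert nu_max == pytest.approx(0.3 * -20.0 + 0.7 * 20.0, abs=0.1)

    @pytest.mark.parametrize("k", [0.0, 1e2, 1e6])
    def test_area_independent_of_rate(self, k):
        m0 = ExchangeModel(-20.0, 20.0, 0.4, 0.0, 0.5)
        ref = np.trapezoid(simulate_lineshape(m0, self.grid), self.grid)
        mk = ExchangeModel(-20.0, 20.0, 0.4, k, 0.5)
        area = np.trapezoid(simulate_lineshape(mk, self.grid), self.grid)
        assert area == pytest.approx(ref, rel=0.01)

    def test_profile_non_negative_and_grid_must_span_sites(self):
        m = ExchangeModel(-20.0, 20.0, 0.5, 10.0, 1.0)
        assert (simulate_lineshape(m, self.grid) >= 0).all()
        with pytest.raises(ValueError):
            simulate_lineshape(m, np.linspace(0.0, 10.0, 100))


class TestFitExchange:
    def test_noiseless_rates_recovered_exactly(self):
        profiles, _ = make_exchange_profiles(
            dg_act=20.6, delta_nu=20.0, temperatures=(368.0, 388.0, 408.0), noise=0.0
        )
        fit = fit_exchange(profiles, 20.0)
        for temp, k_fit in fit.rates.items():
            true_k = eyring_rate(20.6, temp)
            assert k_fit == pytest.approx(true_k, rel=1e-3)
        assert fit.dg_act == pytest.approx(20.6, abs=1e-3)

    def test_noisy_barrier_recovery_over_full_temperature_range(self):
        profiles, _ = make_exchange_profiles(
            dg_act=20.6, delta_nu=20.0, noise=0.01, seed=11
        )
        fit = fit_exchange(profiles, 20.0)
        assert abs(fit.dg_act - 20.6) < 0.3
        assert np.isfinite(fit.dg_uncertainty)

    def test_single_temperature_rejected(self):
        profiles, _ = make_exchange_profiles(temperatures=(398.0,), noise=0.0)
        with pytest.raises(ValueError):
            fit_exchange(profiles, 20.0)

    def test_fitted_rate_monotone_in_temperature(self):
        profiles, _ = make_exchange_profiles(
            dg_act=20.6, delta_nu=20.0, temperatures=(358.0, 378.0, 398.0), noise=0.0
        )
        fit = fit_exchange(profiles, 20.0)
        ks = [fit.rates[t] for t in sorted(fit.rates)]
        assert ks[0] < ks[1] < ks[2]


class TestEyringInverse:
    def test_round_trip(self):
        for dg in (15.0, 19.0, 20.6):
            k = eyring_rate(dg, 370.0)
            assert eyring_dg(k, 370.0) == pytest.approx(dg, abs=1e-12)
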