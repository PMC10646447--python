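"""Energy-balance model: allometry, radiation, conductances, annual costs."""

import numpy as np
import pytest

from islandtone.heatflux import (
    HeatFluxConfig,
    Microclimate,
    _boundary_conductance,
    _plumage_conductance,
    absorbed_solar,
    allometric_morph,
    annual_simulation,
    effective_conductance,
    nir_counterfactual,
    operative_temperature,
    solve_energy_balance,
)
from islandtone.spectra import WavelengthGrid
from islandtone.synthetic import CohortSpec, gen_climate, gen_population_spectra, gen_solar_spectrum


def hour(t_air=10.0, wind=2.0, direct=0.0, diffuse=0.0, albedo=0.2, zenith=120.0):
    return Microclimate(
        air_temperature_c=[t_air],
        wind_m_s=[wind],
        direct_w_m2=[direct],
        diffuse_w_m2=[diffuse],
        albedo=[albedo],
        zenith_deg=[zenith],
    )


@pytest.fixture
def morph():
    return allometric_morph(25.0, reflectance_dorsal=0.3)


class TestAllometry:
    def test_power_law_scaling(self):
        cfg = HeatFluxConfig()
        m1 = allometric_morph(20.0, 0.3, config=cfg)
        m2 = allometric_morph(40.0, 0.3, config=cfg)
        assert m2.plumage_depth_m / m1.plumage_depth_m == pytest.approx(2**cfg.plumage_depth_exp)
        assert m2.bmr_w / m1.bmr_w == pytest.approx(2**cfg.bmr_exp)
        assert m2.diameter_m / m1.diameter_m == pytest.approx(2 ** (1 / 3))

    def test_worked_mass_value(self):
        cfg = HeatFluxConfig()
        m = allometric_morph(20.0, 0.25, config=cfg)
        # hand-evaluated: D = (6*0.02/(pi*1000))^(1/3); BMR = 0.04*20^0.669
        assert m.diameter_m == pytest.approx((6 * 0.02 / (np.pi * 1000)) ** (1 / 3), rel=1e-12)
        assert m.bmr_w == pytest.approx(0.04 * 20**0.669, rel=1e-12)
        assert m.alpha_dorsal == pytest.approx(0.75)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            allometric_morph(0.0, 0.3)


class TestAbsorbedSolar:
    def test_zero_absorptance_absorbs_nothing(self):
        m = allometric_morph(25.0, reflectance_dorsal=1.0, reflectance_ventral=1.0)
        m.transmittance = 0.0
        surf, _ = absorbed_solar(m, hour(direct=800.0, diffuse=150.0, zenith=30.0))
        assert surf[0] == 0.0

    def test_night_absorbs_nothing(self, morph):
        surf, skin = absorbed_solar(morph, hour(direct=0.0, diffuse=0.0))
        assert surf[0] == 0.0 and skin[0] == 0.0

    def test_black_body_matches_area_weighted_sum(self):
        m = allometric_morph(25.0, reflectance_dorsal=0.0, reflectance_ventral=0.0)
        m.transmittance = 0.0
        clim = hour(direct=700.0, diffuse=120.0, albedo=0.25, zenith=40.0)
        surf, _ = absorbed_solar(m, clim)
        ap = m.projected_area_m2
        oracle = 700.0 * ap + 120.0 * ap + 0.25 * (700.0 + 120.0) * ap
        assert surf[0] == pytest.approx(oracle, rel=1e-12)

    def test_negative_radiation_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            hour(direct=-5.0)


class TestOperativeTemperature:
    def test_no_radiation_equals_air_temperature(self, morph):
        t_e = operative_temperature(morph, hour(t_air=12.3))
        assert t_e[0] == pytest.approx(12.3, abs=1e-12)

    def test_radiation_raises_operative_temperature(self, morph):
        sunny = operative_temperature(morph, hour(direct=800.0, zenith=30.0))
        assert sunny[0] > 10.0

    def test_lower_wind_raises_operative_temperature(self, morph):
        fast = operative_temperature(morph, hour(wind=4.0, direct=800.0, zenith=30.0))
        slow = operative_temperature(morph, hour(wind=2.0, direct=800.0, zenith=30.0))
        assert slow[0] > fast[0]


class TestConductance:
    def test_infinite_plumage_depth_limit(self, morph):
        morph.plumage_depth_m = 100.0
        assert effective_conductance(morph, hour())[0] < 1e-4

    def test_series_combination(self, morph):
        cfg = HeatFluxConfig()
        clim = hour()
        k_p = _plumage_conductance(morph, cfg)
        k_b = _boundary_conductance(morph, clim, cfg)[0]
        k_e = effective_conductance(morph, clim, cfg)[0]
        assert k_e == pytest.approx(1.0 / (1.0 / k_p + 1.0 / k_b), rel=1e-12)
        assert k_e < min(k_p, k_b)

    def test_slab_formula_hand_evaluated(self, morph):
        cfg = HeatFluxConfig()
        hand = cfg.plumage_conductivity * np.pi * morph.diameter_m**2 / morph.plumage_depth_m
        assert _plumage_conductance(morph, cfg) == pytest.approx(hand, rel=1e-12)

    def test_deeper_plumage_insulates_more(self, morph):
        k1 = effective_conductance(morph, hour())[0]
        morph.plumage_depth_m *= 2.0
        assert effective_conductance(morph, hour())[0] < k1


class TestEnergyBalance:
    def test_body_equals_operative_no_cost(self, morph):
        st = solve_energy_balance(morph, hour(t_air=morph.body_temperature_c))
        assert st.Q[0] == pytest.approx(0.0, abs=1e-12)
        assert st.heating_cost_pct_bmr[0] == 0.0
        assert st.water_loss_pct_mass_hr[0] == 0.0

    def test_linear_law_ten_degrees(self, morph):
        clim = hour(t_air=morph.body_temperature_c - 10.0)
        st = solve_energy_balance(morph, clim)
        assert st.Q[0] == pytest.approx(10.0 * st.K_e[0], rel=1e-12)

    def test_conservation_residual_machine_precision(self):
        clim = gen_climate(seed=3, n_hours=720)
        st = solve_energy_balance(allometric_morph(25.0, 0.3), clim)
        residual = np.abs(st.M - st.E - st.K_e * (st.T_b - st.T_e))
        assert residual.max() < 1e-9

    def test_heating_cost_monotone_in_dorsal_absorptance(self):
        clim = hour(t_air=5.0, direct=900.0, diffuse=100.0, zenith=20.0)
        costs = []
        for refl in np.linspace(0.9, 0.1, 9):
            st = solve_energy_balance(allometric_morph(25.0, refl), clim)
            costs.append(st.heating_cost_pct_bmr[0])
        assert all(a >= b - 1e-12 for a, b in zip(costs, costs[1:]))


class TestAnnual:
    def test_identical_morphs_zero_differential(self):
        clim = gen_climate(seed=1, n_hours=480)
        m = allometric_morph(25.0, 0.3)
        res = annual_simulation(m, allometric_morph(25.0, 0.3), clim)
        np.testing.assert_allclose(res["differential_pct_bmr"], 0.0, atol=1e-12)

    def test_night_differential_zero_with_equal_conductance(self):
        clim = hour(direct=0.0, diffuse=0.0, zenith=150.0)
        dark = allometric_morph(25.0, 0.2)
        light = allometric_morph(25.0, 0.5)
        res = annual_simulation(dark, light, clim)
        assert res["differential_pct_bmr"][0] == pytest.approx(0.0, abs=1e-12)

    def test_darker_island_saves_energy_in_daylight(self):
        clim = gen_climate(seed=2, n_hours=2160)
        res = annual_simulation(allometric_morph(25.0, 0.25), allometric_morph(25.0, 0.40), clim)
        day = clim.daylight & ((clim.direct_w_m2 + clim.diffuse_w_m2) > 50.0)
        assert res["differential_pct_bmr"][day].min() > 0.0
        assert res["differential_pct_bmr"][~clim.daylight].max() == pytest.approx(0.0, abs=1e-12)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            annual_simulation(
                allometric_morph(25.0, 0.3),
                allometric_morph(25.0, 0.3),
                Microclimate([], [], [], [], [], []),
            )


class TestNirCounterfactual:
    @pytest.fixture
    def cohorts(self):
        spec = CohortSpec("jay", 4, 4, vis_multiplier=0.6, nir_multiplier=1.2, noise_lognormal_sigma=0.0, noise_local_sigma=0.0)
        return gen_population_spectra(spec, seed=0)

    def test_identical_spectra_identity(self, sun):
        spec = CohortSpec("t", 3, 3, vis_multiplier=1.0, nir_multiplier=1.0, noise_lognormal_sigma=0.0, noise_local_sigma=0.0)
        c = gen_population_spectra(spec, seed=0)
        chim, _ = nir_counterfactual(c["island"][0], c["mainland"][0], sun)
        np.testing.assert_array_equal(chim.values, c["island"][0].values)

    def test_chimera_band_construction(self, cohorts, sun):
        from islandtone.spectra import solar_weighted_reflectance

        isl, mai = cohorts["island"][0], cohorts["mainland"][0]
        chim, summary = nir_counterfactual(isl, mai, sun)
        wl = isl.wavelengths
        np.testing.assert_array_equal(chim.values[wl < 700], isl.values[wl < 700])
        np.testing.assert_array_equal(chim.values[wl >= 700], mai.values[wl >= 700])
        # agreement up to the shared 700 nm integration endpoint
        assert summary["VIS"]["chimera"] == pytest.approx(
            solar_weighted_reflectance(isl, sun, "VIS"), rel=5e-3
        )

    def test_high_island_nir_means_chimera_absorbs_more(self, cohorts, sun):
        """Swapping in the mainland's lower NIR reflectance raises full-spectrum
        absorptance relative to the island bird."""
        isl, mai = cohorts["island"][0], cohorts["mainland"][0]
        _, summary = nir_counterfactual(isl, mai, sun)
        assert summary["FULL"]["chimera"] < summary["FULL"]["island"]

    def test_grid_mismatch_rejected(self, cohorts, sun):
        from dataclasses import replace

        small = WavelengthGrid(400, 700, 10)
        other = replace(
            cohorts["mainland"][0],
            grid=small,
            values=np.full(len(small), 0.4),
        )
        with pytest.raises(ValueError, match="grid"):
            nir_counterfactual(cohorts["island"][0], other, sun)
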