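"""Solar weighting, patch averaging and binned mainland-island comparisons."""

import numpy as np
import pytest
from scipy import stats

from islandtone.spectra import (
    BANDS,
    IrradianceSpectrum,
    ReflectanceSpectrum,
    WavelengthGrid,
    average_patches,
    binned_band_tests,
    binned_weighted_means,
    divergence_percent,
    holm_adjust,
    make_bins,
    solar_correct_spectrum,
    solar_weighted_reflectance,
)

from conftest import make_spectrum


def trapz_oracle(y, x):
    """Independent trapezoid integration by explicit summation."""
    total = 0.0
    for i in range(len(x) - 1):
        total += 0.5 * (y[i] + y[i + 1]) * (x[i + 1] - x[i])
    return total


class TestAveragePatches:
    def test_single_patch_is_identity(self, small_grid, rng):
        s = make_spectrum(small_grid, rng.uniform(0, 1, len(small_grid)))
        out = average_patches([s])
        np.testing.assert_array_equal(out.values, s.values)
        assert out.patch == "mean"

    def test_two_flat_patches(self, small_grid):
        a = make_spectrum(small_grid, np.full(len(small_grid), 0.2), patch="crown")
        b = make_spectrum(small_grid, np.full(len(small_grid), 0.4), patch="mantle")
        np.testing.assert_allclose(average_patches([a, b]).values, 0.3)

    def test_five_patches_match_bruteforce_mean(self, small_grid, rng):
        patches = [make_spectrum(small_grid, rng.uniform(0, 1, len(small_grid))) for _ in range(5)]
        expected = []
        for j in range(len(small_grid)):
            acc = 0.0
            for p in patches:
                acc += p.values[j]
            expected.append(acc / 5.0)
        np.testing.assert_allclose(average_patches(patches).values, expected, atol=1e-14)

    def test_mixed_specimens_rejected(self, small_grid):
        a = make_spectrum(small_grid, np.full(len(small_grid), 0.2), specimen_id="s1")
        b = make_spectrum(small_grid, np.full(len(small_grid), 0.4), specimen_id="s2")
        with pytest.raises(ValueError, match="mix specimens"):
            average_patches([a, b])

    def test_grid_mismatch_rejected(self, small_grid):
        other = WavelengthGrid(400, 700, 20)
        a = make_spectrum(small_grid, np.full(len(small_grid), 0.2))
        b = make_spectrum(other, np.full(len(other), 0.2))
        with pytest.raises(ValueError, match="grids"):
            average_patches([a, b])


class TestSolarWeighted:
    def test_flat_reflectance_factors_out(self, small_grid, rng):
        s = make_spectrum(small_grid, np.full(len(small_grid), 0.5))
        sun = IrradianceSpectrum(grid=small_grid, intensity=rng.uniform(0.1, 2, len(small_grid)))
        assert solar_weighted_reflectance(s, sun, "VIS") == pytest.approx(0.5, abs=1e-12)

    def test_point_mass_irradiance_picks_reflectance(self, small_grid, rng):
        vals = rng.uniform(0, 1, len(small_grid))
        s = make_spectrum(small_grid, vals)
        intensity = np.zeros(len(small_grid))
        intensity[10] = 3.0
        sun = IrradianceSpectrum(grid=small_grid, intensity=intensity)
        assert solar_weighted_reflectance(s, sun, "VIS") == pytest.approx(vals[10], abs=1e-12)

    def test_ramp_matches_independent_integrator(self, full_grid, sun):
        wl = full_grid.wavelengths
        ramp = (wl - 350.0) / (2500.0 - 350.0)
        s = make_spectrum(full_grid, ramp)
        intensity = sun.on_grid(full_grid)
        expected = trapz_oracle(ramp * intensity, wl) / trapz_oracle(intensity, wl)
        assert solar_weighted_reflectance(s, sun, "FULL") == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_irradiance_rescaling(self, full_grid, sun, rng):
        s = make_spectrum(full_grid, rng.uniform(0, 1, len(full_grid)))
        ref = solar_weighted_reflectance(s, sun, "VIS")
        for scale in rng.uniform(0.01, 100.0, 5):
            scaled = IrradianceSpectrum(grid=sun.grid, intensity=sun.intensity * scale)
            assert solar_weighted_reflectance(s, scaled, "VIS") == pytest.approx(ref, rel=1e-12)

    def test_band_decomposition(self, full_grid, sun, rng):
        """FULL equals the irradiance-weighted combination of UV, VIS and NIR."""
        s = make_spectrum(full_grid, rng.uniform(0, 1, len(full_grid)))
        wl = full_grid.wavelengths
        intensity = sun.on_grid(full_grid)
        total = 0.0
        weight = 0.0
        for name in ("UV", "VIS", "NIR"):
            m = BANDS[name].mask(wl)
            w = np.trapezoid(intensity[m], wl[m])
            total += solar_weighted_reflectance(s, sun, name) * w
            weight += w
        assert solar_weighted_reflectance(s, sun, "FULL") == pytest.approx(total / weight, abs=1e-9)

    def test_zero_band_irradiance_rejected(self, small_grid):
        s = make_spectrum(small_grid, np.full(len(small_grid), 0.5))
        sun = IrradianceSpectrum(grid=small_grid, intensity=np.zeros(len(small_grid)))
        with pytest.raises(ValueError, match="zero total irradiance"):
            solar_weighted_reflectance(s, sun, "VIS")


class TestSolarCorrect:
    def test_flat_irradiance_is_identity(self, small_grid, rng):
        s = make_spectrum(small_grid, rng.uniform(0, 1, len(small_grid)))
        sun = IrradianceSpectrum(grid=small_grid, intensity=np.full(len(small_grid), 7.0))
        np.testing.assert_allclose(solar_correct_spectrum(s, sun).values, s.values, atol=1e-14)

    def test_invariant_to_doubling_irradiance(self, small_grid, rng):
        s = make_spectrum(small_grid, rng.uniform(0, 1, len(small_grid)))
        sun = IrradianceSpectrum(grid=small_grid, intensity=rng.uniform(0.5, 2, len(small_grid)))
        doubled = IrradianceSpectrum(grid=small_grid, intensity=2 * sun.intensity)
        np.testing.assert_allclose(
            solar_correct_spectrum(s, doubled).values,
            solar_correct_spectrum(s, sun).values,
            atol=1e-14,
        )

    def test_structured_irradiance_hand_computation(self):
        grid = WavelengthGrid(400, 440, 10)  # 5 wavelengths
        r = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        i = np.array([2.0, 1.0, 4.0, 1.0, 2.0])  # mean 2.0
        s = make_spectrum(grid, r)
        sun = IrradianceSpectrum(grid=grid, intensity=i)
        expected = [0.1 * 2 / 2, 0.2 * 1 / 2, 0.3 * 4 / 2, 0.4 * 1 / 2, 0.5 * 2 / 2]
        np.testing.assert_allclose(solar_correct_spectrum(s, sun).values, expected, atol=1e-14)

    def test_raw_mode_passthrough(self, small_grid, flat_sun, rng):
        s = make_spectrum(small_grid, rng.uniform(0, 1, len(small_grid)))
        np.testing.assert_array_equal(solar_correct_spectrum(s, flat_sun, mode="raw").values, s.values)


class TestDivergence:
    @pytest.mark.parametrize(
        "island, mainland, expected",
        [(0.2, 0.1, 50.0), (0.3, 0.3, 0.0), (0.1, 0.2, -100.0)],
    )
    def test_formula(self, island, mainland, expected):
        assert divergence_percent(island, mainland) == pytest.approx(expected)

    def test_zero_island_mean_rejected(self):
        with pytest.raises(ValueError):
            divergence_percent(0.0, 0.1)


class TestHolm:
    def test_worked_example(self):
        np.testing.assert_allclose(holm_adjust([0.001, 0.02, 0.04]), [0.003, 0.04, 0.04])

    def test_adjusted_ge_raw_and_monotone(self, rng):
        p = rng.uniform(0, 1, 25)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestBinnedTests:
    def test_identical_cohorts_no_signal(self, full_grid, sun, rng):
        vals = rng.uniform(0.1, 0.6, (3, len(full_grid)))
        cohort = [make_spectrum(full_grid, v, population="island") for v in vals]
        cohort2 = [make_spectrum(full_grid, v, population="mainland") for v in vals]
        table = binned_band_tests(cohort, cohort2, sun)
        np.testing.assert_allclose(table["divergence_pct"], 0.0, atol=1e-12)
        assert (table["significant_for"] == "none").all()

    def test_last_partial_bin_flagged(self, full_grid):
        bins = make_bins(full_grid.start_nm, full_grid.stop_nm, 100)
        assert bins[-1] == (2450, 2500)
        assert len(bins) == 22

    def test_single_shifted_bin_detected(self, full_grid, sun, rng):
        """An island cohort 10 s.d. darker inside one bin flags only that bin."""
        n, sd = 30, 0.01
        base = 0.5 + rng.normal(0, sd, (2 * n, len(full_grid)))
        wl = full_grid.wavelengths
        shift_zone = (wl >= 460) & (wl <= 540)  # interior of the [450, 550) bin
        island_vals = base[:n].copy()
        island_vals[:, shift_zone] -= 10 * sd
        island = [make_spectrum(full_grid, v, population="island") for v in island_vals]
        mainland = [make_spectrum(full_grid, v, population="mainland") for v in base[n:]]
        table = binned_band_tests(island, mainland, sun)
        hits = table[table["significant_for"] != "none"]
        assert list(hits["bin_lo_nm"]) == [450]
        assert hits["significant_for"].iloc[0] == "mainland"

    def test_too_small_cohorts_rejected(self, full_grid, sun):
        s = make_spectrum(full_grid, np.full(len(full_grid), 0.5))
        with pytest.raises(ValueError, match="2 specimens"):
            binned_band_tests([s], [s, s], sun)

    def test_type_one_error_controlled_under_null(self):
        """With both cohorts from one distribution, Holm keeps the rate of
        falsely significant bins at or below the nominal 5%."""
        rng = np.random.default_rng(7)
        grid = WavelengthGrid(350, 2500, 10)
        wl = grid.wavelengths
        intensity = np.ones(len(wl))
        bins = make_bins(350, 2500, 100)
        n_sig = 0
        n_total = 0
        for _ in range(500):
            vals = 0.4 + rng.normal(0, 0.05, (20, len(wl)))
            means = binned_weighted_means(vals, wl, intensity, bins)
            _, p = stats.ttest_ind(means[:10], means[10:], axis=0, equal_var=False)
            n_sig += int((holm_adjust(p) < 0.05).sum())
            n_total += len(bins)
        assert n_sig / n_total <= 0.05


class TestValidation:
    def test_values_above_clip_threshold_rejected(self, small_grid):
        with pytest.raises(ValueError, match="calibration"):
            make_spectrum(small_grid, np.full(len(small_grid), 1.2))

    def test_slightly_high_values_clipped_with_warning(self, small_grid):
        with pytest.warns(UserWarning, match="clipped"):
            s = make_spectrum(small_grid, np.full(len(small_grid), 1.03))
        assert s.values.max() == 1.0

    def test_negative_values_rejected(self, small_grid):
        with pytest.raises(ValueError, match=">= 0"):
            make_spectrum(small_grid, np.full(len(small_grid), -0.1))
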