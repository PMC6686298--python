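"""Spectrum aggregation, orange ratio, midpoint and OR-depth profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pundavision import light_env as le
from pundavision import synthetic_data as sd
from pundavision.io_formats import FishRecord

from conftest import spectra_frame


class TestAggregation:
    def test_identical_replicates_idempotent(self):
        table = pd.concat([spectra_frame(replicate=1), spectra_frame(replicate=2)])
        agg = le.aggregate_spectra(table)
        assert np.allclose(agg["irradiance"], 1.0)

    def test_replicate_mean(self):
        table = pd.concat([
            spectra_frame(replicate=1, irradiance=np.full(301, 2.0)),
            spectra_frame(replicate=2, irradiance=np.full(301, 4.0)),
        ])
        agg = le.aggregate_spectra(table)
        assert np.allclose(agg["irradiance"], 3.0)

    def test_date_mean_after_replicate_mean(self):
        table = pd.concat([
            spectra_frame(date="2010-05-01", irradiance=np.full(301, 1.0)),
            spectra_frame(date="2010-05-09", irradiance=np.full(301, 3.0)),
        ])
        agg = le.aggregate_spectra(table)
        assert np.allclose(agg["irradiance"], 2.0)

    def test_permutation_invariance(self, rng):
        table = pd.concat([
            spectra_frame(date=d, replicate=r,
                          irradiance=rng.uniform(0.5, 2.0, 301))
            for d in ("2010-05-01", "2010-05-09") for r in (1, 2)
        ])
        agg1 = le.aggregate_spectra(table)
        agg2 = le.aggregate_spectra(
            table.sample(frac=1, random_state=0).reset_index(drop=True)
        )
        assert np.allclose(agg1["irradiance"], agg2["irradiance"])

    def test_mismatched_grids_rejected(self):
        table = pd.concat([
            spectra_frame(replicate=1),
            spectra_frame(replicate=2, wavelengths=np.arange(400.0, 700.0, 2.0),
                          irradiance=np.ones(150)),
        ])
        with pytest.raises(le.LightEnvError, match="grids"):
            le.aggregate_spectra(table)


class TestOrangeRatio:
    def test_flat_spectrum_band_width_ratio(self, flat_spectrum):
        # numerator spans 150 nm, denominator 149 nm under inclusive edges
        assert le.orange_ratio(*flat_spectrum) == pytest.approx(150 / 149, abs=1e-12)

    def test_no_long_wavelength_light_gives_zero(self, flat_spectrum):
        wl, ir = flat_spectrum
        ir = np.where(wl >= 550, 0.0, ir)
        assert le.orange_ratio(wl, ir) == 0.0

    def test_no_short_wavelength_light_gives_inf(self, flat_spectrum):
        wl, ir = flat_spectrum
        ir = np.where(wl < 550, 0.0, ir)
        assert le.orange_ratio(wl, ir) == np.inf

    @given(k=st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, k):
        wl = np.arange(400.0, 701.0)
        ir = 1.0 + np.sin(wl / 40.0) ** 2
        assert le.orange_ratio(wl, k * ir) == pytest.approx(
            le.orange_ratio(wl, ir), rel=1e-12
        )


class TestSpectralMidpoint:
    def test_flat_spectrum_splits_at_550(self, flat_spectrum):
        assert le.spectral_midpoint(*flat_spectrum) == pytest.approx(550.0, abs=0.5)

    def test_block_spectrum_splits_at_block_centre(self):
        wl = np.arange(400.0, 701.0)
        ir = np.where((wl >= 600) & (wl <= 610), 1.0, 0.0)
        assert le.spectral_midpoint(wl, ir) == pytest.approx(605.0, abs=1.0)

    def test_intensity_scale_invariance(self, flat_spectrum):
        wl, ir = flat_spectrum
        assert le.spectral_midpoint(wl, 2 * ir) == le.spectral_midpoint(wl, ir)

    def test_all_zero_spectrum_rejected(self, flat_spectrum):
        wl, _ = flat_spectrum
        with pytest.raises(le.LightEnvError):
            le.spectral_midpoint(wl, np.zeros_like(wl))


def _profile(points, island="Luanso"):
    depths = np.array([p[0] for p in points], dtype=float)
    ors = np.array([p[1] for p in points], dtype=float)
    slope, intercept = np.polyfit(depths, ors, 1)
    return le.OrProfile(island, depths, ors, slope, intercept, "measured")


class TestOrProfiles:
    def test_linear_profile_extrapolates_exactly(self):
        prof = _profile([(1, 2.0), (2, 3.0), (3, 4.0)])
        fish = FishRecord("f", "Luanso", "red", 5.0)
        value, provenance = le.assign_or(fish, prof)
        assert value == pytest.approx(6.0, abs=1e-9)
        assert provenance == "regression-extrapolated"

    def test_anchor_median_of_two_islands(self):
        wl = np.arange(400.0, 701.0)
        frames = []
        for island, scale in (("Makobe", 1.2), ("Python", 1.8)):
            for depth in (1.0, 2.0):
                ir = np.where(wl >= 550, scale * depth, 1.0)
                frames.append(pd.DataFrame({
                    "island": island, "depth_m": depth,
                    "wavelength_nm": wl, "irradiance": ir,
                }))
        agg = pd.concat(frames, ignore_index=True)
        makobe = le.build_or_profile("Makobe", agg)
        python = le.build_or_profile("Python", agg)
        anchor = le.anchor_or_profile(makobe, python)
        assert anchor.provenance == "median-estimated"
        expected = np.median([makobe.or_values, python.or_values], axis=0)
        assert np.allclose(anchor.or_values, expected)

    def test_single_depth_island_rejected(self):
        agg = pd.DataFrame({
            "island": "Luanso", "depth_m": 1.0,
            "wavelength_nm": np.arange(400.0, 701.0),
            "irradiance": 1.0,
        })
        with pytest.raises(le.LightEnvError, match="2 depths"):
            le.build_or_profile("Luanso", agg)

    def test_fish_at_measured_depth_gets_that_or(self):
        prof = _profile([(1, 2.0), (2, 3.0), (3, 4.0)])
        value, _ = le.assign_or(FishRecord("f", "Luanso", "red", 2.0), prof)
        assert value == 3.0

    def test_between_depths_linear_interpolation(self):
        prof = _profile([(1.5, 2.0), (2.0, 3.0)])
        value, _ = le.assign_or(FishRecord("f", "Luanso", "red", 1.75), prof)
        assert value == pytest.approx(2.5)

    def test_above_shallowest_clamps_with_shallowest_value(self):
        prof = _profile([(1.0, 2.0), (2.0, 3.0)])
        value, _ = le.assign_or(FishRecord("f", "Luanso", "blue", 0.4), prof)
        assert value == 2.0


class TestSyntheticLight:
    def test_or_strictly_increases_with_depth_everywhere(self):
        table = sd.generate_irradiance(
            islands=sd.DEFAULT_LIGHT_PARAMS,
            dates={k: 2 for k in sd.DEFAULT_LIGHT_PARAMS},
            seed=0,
        )
        agg = le.aggregate_spectra(table)
        for island in sd.DEFAULT_LIGHT_PARAMS:
            prof = le.build_or_profile(island, agg)
            assert np.all(np.diff(prof.or_values) > 0), island

    def test_turbid_island_has_higher_or_at_one_metre(self):
        wl = np.arange(400.0, 701.0)
        luanso = sd.model_spectrum(sd.DEFAULT_LIGHT_PARAMS["Luanso"], 1.0, wl)
        makobe = sd.model_spectrum(sd.DEFAULT_LIGHT_PARAMS["Makobe"], 1.0, wl)
        assert le.orange_ratio(wl, luanso) > le.orange_ratio(wl, makobe)
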