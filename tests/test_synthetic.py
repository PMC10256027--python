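"""Generator contracts: trajectories, Beer-Lambert composition, counts."""
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from mustspec.io import ANALYTES
from mustspec.spectra import SpectraError
from mustspec.synthetic import (
    ACID_WINDOW,
    SUGAR_WINDOW,
    TABLE1_N_SAMPLES,
    TABLE1_RANGES,
    AnalyteBandSet,
    Band,
    SimulationConfig,
    VarietyProfile,
    default_band_sets,
    default_config,
    generate_dataset,
    pure_component_absorbance,
    ripening_trajectory,
    simulate_transmission,
)

RIESLING = VarietyProfile("Riesling", TABLE1_RANGES["Riesling"], 22)


class TestRipeningTrajectory:
    def test_values_stay_in_published_ranges(self):
        traj = ripening_trajectory(RIESLING, seed=7)
        for analyte, (lo, hi) in TABLE1_RANGES["Riesling"].items():
            assert traj[analyte].between(lo, hi).all()

    def test_zero_jitter_sugar_endpoints_exact(self):
        traj = ripening_trajectory(RIESLING, seed=0, jitter_frac=0.0)
        for sugar in ("fructose", "glucose"):
            lo, hi = TABLE1_RANGES["Riesling"][sugar]
            assert traj[sugar].iloc[0] == pytest.approx(lo, abs=1e-12)
            assert traj[sugar].iloc[-1] == pytest.approx(hi, abs=1e-12)

    def test_direction_of_change(self):
        traj = ripening_trajectory(RIESLING, seed=0, jitter_frac=0.0)
        means = traj.groupby("time_point").mean()
        for sugar in ("fructose", "glucose"):
            assert means[sugar].is_monotonic_increasing
        assert means["malic_acid"].is_monotonic_decreasing
        assert means["tartaric_acid"].is_monotonic_decreasing

    def test_tartaric_relative_span_smaller_than_malic(self):
        traj = ripening_trajectory(RIESLING, seed=0, jitter_frac=0.0)
        rel = lambda c: (c.max() - c.min()) / c.max()
        assert rel(traj["tartaric_acid"]) < rel(traj["malic_acid"])

    def test_invalid_range_rejected(self):
        with pytest.raises(SpectraError, match="min >= max"):
            VarietyProfile("bad", {"fructose": (50.0, 50.0)}, 5)

    def test_row_count_is_sample_count(self):
        traj = ripening_trajectory(RIESLING, seed=1)
        assert len(traj) == RIESLING.n_samples
        assert set(traj["time_point"]) == set(range(RIESLING.n_time_points))


class TestPureComponentAbsorbance:
    def test_single_band_peaks_at_center(self):
        bs = AnalyteBandSet("fructose", (Band(1130.0, 15.0, 2.0),))
        grid = np.arange(1100.0, 1350.1, 2.0)
        eps = pure_component_absorbance(bs, grid)
        assert grid[np.argmax(eps)] == 1130.0
        assert np.all(eps >= 0)

    def test_empty_grid_rejected(self):
        bs = AnalyteBandSet("fructose", (Band(1130.0, 15.0, 2.0),))
        with pytest.raises(SpectraError):
            pure_component_absorbance(bs, np.array([]))

    def test_two_identical_bands_double_one(self):
        grid = np.arange(1100.0, 1350.1, 2.0)
        one = pure_component_absorbance(
            AnalyteBandSet("x", (Band(1200.0, 20.0, 1.5),)), grid)
        two = pure_component_absorbance(
            AnalyteBandSet("x", (Band(1200.0, 20.0, 1.5),) * 2), grid)
        np.testing.assert_allclose(two, 2 * one, rtol=1e-14)

    def test_default_bands_concentrated_in_attribution_windows(self):
        sets = default_band_sets()
        for sugar in ("fructose", "glucose"):
            assert sets[sugar].window_mass_fraction(SUGAR_WINDOW) >= 0.8
        for acid in ("malic_acid", "tartaric_acid"):
            assert sets[acid].window_mass_fraction(ACID_WINDOW) >= 0.8


class TestSimulateTransmission:
    def test_blank_equals_reference(self):
        cfg = default_config(seed=0).noise_free()
        s = simulate_transmission(
            {a: 0.0 for a in ANALYTES}, cfg.reference_temperature_c, cfg, seed=0)
        assert s.state == "absorbance"
        np.testing.assert_allclose(s.values, 0.0, atol=1e-15)

    def test_beer_lambert_doubling(self):
        cfg = default_config(seed=0).noise_free()
        ref = cfg.reference_temperature_c
        base = {a: 0.0 for a in ANALYTES}
        one = simulate_transmission({**base, "glucose": 40.0}, ref, cfg, seed=0)
        two = simulate_transmission({**base, "glucose": 80.0}, ref, cfg, seed=0)
        np.testing.assert_allclose(two.values, 2 * one.values, rtol=1e-12)

    def test_mixture_additivity_at_zero_noise(self):
        """Beer-Lambert additivity: mixture == sum of single-analyte runs."""
        cfg = default_config(seed=0).noise_free()
        ref = cfg.reference_temperature_c
        conc = {"fructose": 60.0, "glucose": 55.0,
                "malic_acid": 12.0, "tartaric_acid": 7.0}
        mixture = simulate_transmission(conc, ref, cfg, seed=0).values
        singles = sum(
            simulate_transmission(
                {**{a: 0.0 for a in ANALYTES}, a: c}, ref, cfg, seed=0).values
            for a, c in conc.items()
        )
        np.testing.assert_allclose(mixture, singles, atol=1e-14)

    def test_seeded_determinism(self):
        cfg = default_config(seed=0)
        conc = {a: 10.0 for a in ANALYTES}
        a = simulate_transmission(conc, 14.0, cfg, seed=42)
        b = simulate_transmission(conc, 14.0, cfg, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_negative_concentration_rejected(self):
        cfg = default_config(seed=0)
        with pytest.raises(SpectraError, match="negative"):
            simulate_transmission({"glucose": -1.0}, 14.0, cfg, seed=0)


class TestGenerateDataset:
    def test_published_count_pattern(self):
        """Every sample yields one spectrum per temperature (n/3n pattern)."""
        ds = generate_dataset(default_config(seed=5))
        counts = pd.Series([s.variety for s in ds.spectra]).value_counts()
        for variety, n in TABLE1_N_SAMPLES.items():
            assert counts[variety] == 3 * n
        assert counts["Riesling"] == 66

    def test_single_temperature_collapses_counts(self):
        cfg = replace(default_config(seed=5), temperatures_c=(14.0,))
        ds = generate_dataset(cfg)
        assert len(ds.spectra) == len(ds.primary_reference)

    def test_full_determinism(self):
        a = generate_dataset(default_config(seed=3))
        b = generate_dataset(default_config(seed=3))
        assert a.spectra == b.spectra
        pd.testing.assert_frame_equal(a.primary_reference, b.primary_reference)
        pd.testing.assert_frame_equal(a.secondary_reference, b.secondary_reference)

    def test_different_seeds_same_shape_different_noise(self):
        a = generate_dataset(default_config(seed=1))
        b = generate_dataset(default_config(seed=2))
        assert [s.sample_id for s in a.spectra] == [s.sample_id for s in b.spectra]
        assert not np.array_equal(a.spectra[0].values, b.spectra[0].values)

    def test_concentrations_within_configured_ranges(self):
        ds = generate_dataset(default_config(seed=8))
        ref = ds.primary_reference
        for profile in ds.config.varieties:
            tag = profile.variety.replace(" ", "")
            rows = ref[ref["sample_id"].str.startswith(tag + "-")]
            for analyte, (lo, hi) in profile.ranges.items():
                assert rows[f"{analyte}_g_l"].between(lo, hi).all()

    def test_secondary_disagreement_scale(self):
        """Method disagreement lands near its configured sd (3x tolerance)."""
        ds = generate_dataset(default_config(seed=21))
        diff = ds.secondary_reference.set_index("sample_id") \
            .drop(columns="method_role") \
            - ds.primary_reference.set_index("sample_id").drop(columns="method_role")
        for a, sd in ds.config.secondary_disagreement_sd.items():
            rms = float(np.sqrt((diff[f"{a}_g_l"] ** 2).mean()))
            assert sd / 3 < rms < sd * 3

    def test_yaml_config_round_trip_regenerates_identically(self, tmp_path):
        cfg = default_config(seed=4)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = SimulationConfig.from_yaml(tmp_path / "cfg.yaml")
        assert generate_dataset(cfg).spectra == generate_dataset(back).spectra

    def test_grid_too_coarse_rejected(self):
        with pytest.raises(SpectraError, match="25"):
            SimulationConfig(wavelength_step_nm=20.0)
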