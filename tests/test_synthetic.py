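"""Synthetic attribute tables and hyperspectral scenes."""

import numpy as np
import pandas as pd
import pytest

import grassspec as gs
from grassspec import envi, roi
from grassspec.synthetic import _beta_params


class TestAttributeTable:
    def test_nitrogen_population_mean_recovered(self):
        """Large-sample blade nitrogen mean matches the 3.2 +/- SE target."""
        spec = gs.AttributeSpec("Nitrogen", "%", 3.2, 0.7, 0.4, 4.65)
        table = gs.generate_attribute_table([spec], 10_000, seed=5)
        bl = table[table.tissue == "BL"].Nitrogen
        se = 0.7 / np.sqrt(10_000)
        assert abs(bl.mean() - 3.2) < 3 * se

    def test_degenerate_sd_gives_constant_values(self):
        spec = gs.AttributeSpec("X", "u", 5.0, 1e-9, 0.0, 10.0)
        table = gs.generate_attribute_table([spec], 50, seed=0)
        assert np.allclose(table.X, 5.0, atol=1e-6)

    def test_ps_bl_shift_recovered(self):
        """BL - PS nitrogen difference lands within 3 SE of the planted 1.1."""
        spec = gs.AttributeSpec(
            "Nitrogen", "%", 3.2, 0.7, 0.4, 4.65, ps_bl_shift=-1.1, ps_bl_r2=0.83
        )
        table = gs.generate_attribute_table([spec], 1000, seed=7)
        bl = table[table.tissue == "BL"].Nitrogen.to_numpy()
        ps = table[table.tissue == "PS"].Nitrogen.to_numpy()
        se_diff = np.std(bl - ps, ddof=1) / np.sqrt(1000)
        assert abs((bl.mean() - ps.mean()) - 1.1) < 3 * se_diff

    def test_statistical_fidelity_all_attributes(self):
        """Every default attribute's BL mean and SD within 3 SE of spec at n = 2000."""
        specs = gs.default_attribute_specs()
        table = gs.generate_attribute_table(specs, 2000, seed=3)
        bl = table[table.tissue == "BL"]
        for s in specs:
            vals = bl[s.name]
            assert abs(vals.mean() - s.mean) < 3 * s.sd / np.sqrt(2000), s.name
            assert abs(vals.std(ddof=1) - s.sd) < 3 * s.sd / np.sqrt(2 * 2000), s.name
            assert vals.min() >= s.min and vals.max() <= s.max, s.name

    def test_ps_bl_coupling_strength(self):
        """Realized PS-BL r^2 reaches the target (up to the comonotone cap)."""
        specs = gs.default_attribute_specs()
        table = gs.generate_attribute_table(specs, 4000, seed=2)
        bl = table[table.tissue == "BL"]
        ps = table[table.tissue == "PS"]
        for s in specs:
            if s.ps_bl_shift == 0:
                continue
            r2 = np.corrcoef(bl[s.name], ps[s.name])[0, 1] ** 2
            assert r2 >= s.ps_bl_r2 - 0.1, (s.name, r2)

    def test_whole_is_tissue_weighted_mean(self):
        specs = gs.default_attribute_specs()
        table = gs.generate_attribute_table(specs, 20, seed=1, ps_fraction=0.3)
        piv = table.pivot(index="plant_id", columns="tissue", values="Sugars")
        assert np.allclose(piv["whole"], 0.3 * piv["PS"] + 0.7 * piv["BL"])

    def test_determinism_and_errors(self):
        specs = gs.default_attribute_specs()
        a = gs.generate_attribute_table(specs, 64, seed=9)
        b = gs.generate_attribute_table(specs, 64, seed=9)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError, match="n_plants"):
            gs.generate_attribute_table(specs, 1, seed=0)
        with pytest.raises(ValueError, match="Bogus.*sd|sd.*Bogus"):
            gs.AttributeSpec("Bogus", "u", 1.0, -1.0, 0.0, 2.0)

    def test_beta_moment_match_is_exact(self):
        """Oracle: analytic Beta moments reproduce requested mean/sd exactly."""
        for mean, sd, lo, hi in [(3.2, 0.7, 0.4, 4.65), (36.2, 35.1, 2.4, 167.5)]:
            a, b = _beta_params(mean, sd, lo, hi)
            m = lo + (hi - lo) * a / (a + b)
            v = (hi - lo) ** 2 * a * b / ((a + b) ** 2 * (a + b + 1))
            assert abs(m - mean) < 1e-9 and abs(np.sqrt(v) - sd) < 1e-9


class TestScene:
    def test_determinism(self, library, small_scene, attribute_names):
        table = gs.generate_attribute_table(gs.default_attribute_specs(), 5, seed=4)
        row = table[table.tissue == "BL"].iloc[0][attribute_names].to_dict()
        a = gs.generate_cube(row, library, small_scene)
        b = gs.generate_cube(row, library, small_scene)
        assert np.array_equal(a.raw.irradiance, b.raw.irradiance)
        assert np.array_equal(a.refs.dark, b.refs.dark)
        assert np.array_equal(a.truth_mask, b.truth_mask)

    def test_calibration_inverts_forward_model(self, library, clean_scene, attribute_names):
        table = gs.generate_attribute_table(gs.default_attribute_specs(), 5, seed=4)
        row = table[table.tissue == "BL"].iloc[0][attribute_names].to_dict()
        sim = gs.generate_cube(row, library, clean_scene)
        cube = envi.calibrate(sim.raw, sim.refs)
        assert np.abs(cube.reflectance - sim.reflectance).max() <= 1e-10

    def test_mask_consistency_with_segmentation(self, library, clean_scene, attribute_names):
        """Ground-truth foreground equals ROI segmentation on the noise-free cube."""
        table = gs.generate_attribute_table(gs.default_attribute_specs(), 5, seed=4)
        row = table[table.tissue == "BL"].iloc[0][attribute_names].to_dict()
        sim = gs.generate_cube(row, library, clean_scene)
        cube = envi.calibrate(sim.raw, sim.refs)
        mask = roi.segment(cube)
        assert np.array_equal(mask.mask, sim.truth_mask)

    def test_background_below_threshold_at_1080(self, library, small_scene, attribute_names):
        table = gs.generate_attribute_table(gs.default_attribute_specs(), 5, seed=4)
        row = table[table.tissue == "BL"].iloc[0][attribute_names].to_dict()
        sim = gs.generate_cube(row, library, small_scene)
        cube = envi.calibrate(sim.raw, sim.refs)
        band = envi.band_index(cube.wavelengths, 1080.0)
        assert cube.reflectance[~sim.truth_mask, band].max() < 0.3

    def test_monotone_encoding_of_concentration(self, library, clean_scene):
        """Raising a concentration never raises reflectance at its feature centers."""
        concs = [1.0, 2.0, 3.0, 4.0]
        bands = library.feature_bands("Nitrogen")
        prev = None
        for c in concs:
            sim = gs.generate_cube({"Nitrogen": c}, library, clean_scene)
            vals = sim.reflectance[sim.truth_mask][:, bands].mean(axis=0)
            if prev is not None:
                assert np.all(vals <= prev + 1e-12)
            prev = vals

    def test_concentration_contrast_strongest_in_feature_bands(self, library, clean_scene):
        """Brute-force band-wise SNV comparison peaks inside nitrogen features."""
        from grassspec.preprocess import snv

        sims = [
            gs.generate_cube({"Nitrogen": c}, library, clean_scene) for c in (2.0, 4.0)
        ]
        means = [s.reflectance[s.truth_mask].mean(axis=0) for s in sims]
        delta = np.abs(snv(means[0]) - snv(means[1]))
        top = int(np.argmax(delta))
        feature_bands = set(library.feature_bands("Nitrogen"))
        # the biggest SNV difference lies within 3 bands of a feature center
        assert any(abs(top - b) <= 3 for b in feature_bands)

    def test_plant_fraction_bounds_rejected(self, library):
        with pytest.raises(ValueError, match="plant_fraction"):
            gs.SceneConfig(plant_fraction=0.0)
        with pytest.raises(ValueError, match="plant_fraction"):
            gs.SceneConfig(plant_fraction=1.0)

    def test_two_zone_cube_zones_differ(self, library, clean_scene):
        sim = gs.generate_two_zone_cube(
            {"Sugars": 60.0}, {"Sugars": 153.0}, library, clean_scene
        )
        bl = sim.reflectance[sim.truth_mask & (sim.zone_labels == "BL")].mean(axis=0)
        ps = sim.reflectance[sim.truth_mask & (sim.zone_labels == "PS")].mean(axis=0)
        band_1100 = envi.band_index(library.wavelengths, 1100.0)
        assert ps[band_1100] > bl[band_1100]  # pseudostem brighter at 800-1100 nm


class TestSimulateDataset:
    def test_writes_csv_and_cubes(self, tmp_path, library):
        scene = gs.SceneConfig(lines=16, samples=12, seed=2)
        out = gs.synthetic.simulate_dataset(
            tmp_path / "ds", n_plants=2, seed=1, scene=scene, n_images=1
        )
        table = pd.read_csv(out / "attributes.csv")
        assert list(table.columns[:2]) == ["plant_id", "tissue"]
        assert len(table) == 2 * 3  # whole/PS/BL per plant
        raw = envi.read_envi(out / "plant001_rep1.hdr")
        assert raw.shape == (16, 12, 235)
        white = envi.read_envi(out / "plant001_rep1_white.hdr")
        cube = envi.calibrate(
            raw, envi.ReferencePair(
                white.irradiance[0],
                envi.read_envi(out / "plant001_rep1_dark.hdr").irradiance[0],
            )
        )
        assert np.isfinite(cube.reflectance).all()
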