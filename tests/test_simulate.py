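import json

import numpy as np
import pytest

from cottonvit import (ConfigError, build_dataset, correct_reflectance,
                       extract_seed_spectra, read_fixture, simulate_dataset,
                       write_fixture)
from tests.conftest import small_sim_config


class TestGeneration:
    def test_noiseless_cube_equals_planted_reflectance(self):
        cfg = small_sim_config(noise_sd=0.0, scatter_sd=0.0, offset_sd=0.0,
                               texture_base_amp=0.0)
        sim = simulate_dataset(cfg)
        cube = correct_reflectance(sim.raw[0])
        spectra = extract_seed_spectra(cube, sim.truth.masks[0])
        np.testing.assert_allclose(spectra, sim.truth.clean_spectra[: len(spectra)],
                                   atol=2e-5)  # float32 storage of the raw cube
        # pixel-level identity inside each seed
        for k in range(1, 4):
            sel = sim.truth.masks[0] == k
            diff = cube.S[sel] - sim.truth.clean_spectra[k - 1][None, :]
            assert np.abs(diff).max() < 2e-5

    def test_fixed_seed_is_deterministic(self):
        a = simulate_dataset(small_sim_config(rng_seed=5))
        b = simulate_dataset(small_sim_config(rng_seed=5))
        for ra, rb in zip(a.raw, b.raw):
            np.testing.assert_array_equal(ra.O, rb.O)
        np.testing.assert_array_equal(a.truth.vitality, b.truth.vitality)
        for ma, mb in zip(a.truth.masks, b.truth.masks):
            np.testing.assert_array_equal(ma, mb)

    def test_default_layout_counts(self, default_dataset):
        sim, data = default_dataset
        assert len(sim.raw) == 8
        assert all(int(m.max()) == 25 for m in sim.truth.masks)
        assert len(sim.vitality_table) == 200
        assert data.spectra.shape == (200, 520)
        assert sim.wavelengths[0] == pytest.approx(391.0)
        assert sim.wavelengths[-1] == pytest.approx(1041.8, abs=0.1)

    def test_vitality_positive_and_masks_labelled(self, default_dataset):
        sim, _ = default_dataset
        assert (sim.truth.vitality > 0).all()
        for m in sim.truth.masks:
            assert set(np.unique(m)) == set(range(26))

    def test_planted_signal_recoverable_by_ols(self):
        """Low-noise oracle: vitality regressed on the planted bands'
        reflectance reaches R >= 0.99."""
        cfg = small_sim_config(noise_sd=1e-4, scatter_sd=1e-3, offset_sd=1e-4)
        sim = simulate_dataset(cfg)
        data = build_dataset(sim)
        ib = sim.truth.informative_band_indices
        A = np.column_stack([np.ones(cfg.n_seeds), data.spectra[:, ib]])
        beta = np.linalg.lstsq(A, sim.truth.vitality, rcond=None)[0]
        r = np.corrcoef(A @ beta, sim.truth.vitality)[0, 1]
        assert r >= 0.99

    def test_band_slope_increases_correlation(self):
        """A steeper vitality slope on an absorption feature strengthens
        the vitality-reflectance correlation at that band."""
        rs = []
        for slope in (0.004, 0.01, 0.02):
            cfg = small_sim_config(absorption_bands=[(700.0, 30.0, slope)],
                                   scatter_sd=0.01, offset_sd=0.002,
                                   noise_sd=5e-4, rng_seed=3)
            sim = simulate_dataset(cfg)
            data = build_dataset(sim)
            band = sim.truth.informative_band_indices[0]
            rs.append(abs(np.corrcoef(data.spectra[:, band],
                                      sim.truth.vitality)[0, 1]))
        assert rs[0] < rs[1] < rs[2]

    @pytest.mark.parametrize("bad", [dict(n_plates=0), dict(n_bands=1),
                                     dict(wavelength_step_nm=0.0),
                                     dict(texture_coupling=1.5),
                                     dict(vitality_sd_cm=-1.0)])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigError):
            simulate_dataset(small_sim_config(**bad))


class TestFixtureIO:
    def test_file_counts_and_round_trip(self, tmp_path):
        cfg = small_sim_config()
        sim = simulate_dataset(cfg)
        manifest = write_fixture(sim, tmp_path)
        assert len(list(tmp_path.glob("plate*.raw"))) == cfg.n_plates
        assert len(list(tmp_path.glob("plate*.raw.hdr"))) == cfg.n_plates
        assert len(list(tmp_path.glob("plate*_mask.png"))) == cfg.n_plates
        assert (tmp_path / "vitality.csv").exists()
        captures, masks, table = read_fixture(tmp_path)
        np.testing.assert_array_equal(captures[0].O, sim.raw[0].O)
        np.testing.assert_array_equal(masks[1], sim.truth.masks[1])
        assert len(table) == cfg.n_seeds
        listed = json.loads((tmp_path / "manifest.json").read_text())["files"]
        assert set(listed) == {p.name for p in tmp_path.iterdir()
                               if p.name != "manifest.json"}

    def test_manifest_changes_iff_config_changes(self, tmp_path):
        cfg = small_sim_config()
        m1 = write_fixture(simulate_dataset(cfg), tmp_path / "a")
        m2 = write_fixture(simulate_dataset(small_sim_config()), tmp_path / "b")
        assert m1 == m2  # same config -> byte-identical outputs
        m3 = write_fixture(simulate_dataset(small_sim_config(noise_sd=0.01)),
                           tmp_path / "c")
        assert m1 != m3
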