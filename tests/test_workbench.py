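import math
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

from uedindex.matching import ReducedData
from uedindex.profiles import MosaicityModel
from uedindex.workbench import (ModelParams, Project, Setting,
                                SyntheticTruth, default_truth_setting,
                                load_settings, load_truth,
                                make_synthetic_project, read_reduced_data,
                                save_settings, setting_from_dict,
                                setting_to_dict, simulate_image,
                                simulate_pattern, write_reduced_data,
                                predict_setting, DetectorMask)


class TestReducedDataIO:
    def test_round_trip(self, tmp_path):
        spots = ReducedData(("a", "b", "c"),
                            np.array([[1.0, 2.0], [3.5, 4.25], [10, 20]]),
                            np.array([5.0, 1.25, 9.0]))
        p = tmp_path / "rd.tsv"
        write_reduced_data(spots, p)
        back = read_reduced_data(p)
        assert back.spot_ids == spots.spot_ids
        assert np.allclose(back.xy, spots.xy)
        assert np.allclose(back.intensity, spots.intensity)

    def test_nonpositive_rows_rejected_with_report(self, tmp_path, caplog):
        p = tmp_path / "rd.tsv"
        p.write_text("id\tx\ty\tI\na\t1\t2\t5\nb\t3\t4\t-1\nc\t5\t6\t2\n")
        import logging
        with caplog.at_level(logging.WARNING, logger="uedindex.workbench"):
            spots = read_reduced_data(p)
        assert len(spots) == 2
        assert any("I <= 0" in r.message for r in caplog.records)

    def test_missing_column_error(self, tmp_path):
        p = tmp_path / "rd.tsv"
        p.write_text("id\tx\ty\na\t1\t2\n")
        with pytest.raises(ValueError, match="'I'"):
            read_reduced_data(p)

    def test_comments_and_extra_columns(self, tmp_path, caplog):
        p = tmp_path / "rd.tsv"
        p.write_text("# comment line\nid\tx\ty\tI\tsigI\na\t1\t2\t5\t0.2\n")
        import logging
        with caplog.at_level(logging.WARNING, logger="uedindex.workbench"):
            spots = read_reduced_data(p)
        assert len(spots) == 1
        assert any("ignored" in r.message for r in caplog.records)


class TestModelParamsConsistency:
    def test_magnification_follows_camera_length(self):
        m = ModelParams(detector_distance_mm=400.0, camera_length_mm=480.0)
        assert m.magnification == pytest.approx(1.2)
        m2 = m.update(camera_length_mm=600.0)
        assert m2.magnification == pytest.approx(1.5)

    def test_setting_magnification_updates_camera_length(self):
        m = ModelParams(detector_distance_mm=400.0, camera_length_mm=400.0)
        m2 = m.update(magnification=1.25)
        assert m2.camera_length_mm == pytest.approx(500.0)

    def test_wavelength_energy_coupled(self):
        m = ModelParams(energy_kev=90.0)
        lam = m.wavelength_A
        m2 = m.update(wavelength_A=lam / 2)
        assert m2.energy_kev > 90.0
        assert m2.wavelength_A == pytest.approx(lam / 2, rel=1e-12)


class TestSettingsIO:
    def test_round_trip(self, tmp_path):
        s = default_truth_setting()
        p = tmp_path / "settings.yaml"
        save_settings([s], p, run_history=[{"setting": "00001",
                                           "provenance": "manual"}])
        back, hist = load_settings(p)
        assert len(back) == 1
        assert back[0] == s
        assert hist[0]["provenance"] == "manual"

    def test_unknown_field_error(self):
        d = setting_to_dict(default_truth_setting())
        d["model"]["bogus_field"] = 1.0
        with pytest.raises(ValueError, match="bogus_field"):
            setting_from_dict(d)

    def test_schema_version_mismatch(self, tmp_path):
        p = tmp_path / "settings.yaml"
        p.write_text("schema_version: 99\nsettings: []\n")
        with pytest.raises(ValueError, match="schema version"):
            load_settings(p)


class TestSyntheticProject:
    def test_same_seed_identical_bytes(self, tmp_path):
        truth = SyntheticTruth(setting=default_truth_setting(), seed=3)
        a = make_synthetic_project(truth, tmp_path / "a", with_image=False)
        b = make_synthetic_project(truth, tmp_path / "b", with_image=False)
        for name in ("reduced_data.tsv", "structure.cif", "truth.yaml"):
            assert (Path(a.root) / name).read_bytes() == \
                (Path(b.root) / name).read_bytes()

    def test_noise_free_equals_merged_simulation(self, clean_project):
        # with zero noise/jitter the reduced data equal the ambit-merged
        # simulation of the generating setting (up to file precision)
        truth = load_truth(clean_project.root)
        spots = clean_project.reduced_data()
        st = clean_project.structure()
        merged = simulate_pattern(truth.setting, st, merge=True, spots=spots)
        assert merged.matched.all()
        assert np.allclose(merged.I_clc, spots.intensity, rtol=1e-9)
        assert np.allclose(merged.xy_clc, spots.xy, atol=1e-6)

    def test_intensity_noise_statistics(self, tmp_path):
        base = SyntheticTruth(setting=default_truth_setting(), seed=11,
                              intensity_noise=0.0, centroid_jitter=0.0)
        noisy = SyntheticTruth(setting=default_truth_setting(), seed=11,
                               intensity_noise=0.1, centroid_jitter=0.0)
        a = make_synthetic_project(base, tmp_path / "a", with_image=False)
        b = make_synthetic_project(noisy, tmp_path / "b", with_image=False)
        Ia = a.reduced_data().intensity
        Ib = b.reduced_data().intensity
        assert len(Ia) == len(Ib) >= 100
        s = np.std(np.log(Ib / Ia), ddof=1)
        se = 0.1 / math.sqrt(2 * (len(Ia) - 1))
        assert abs(s - 0.1) < 3 * se

    def test_project_round_trip(self, synth_project):
        loaded = Project.load(synth_project.root)
        assert loaded.n_images == 1
        assert len(loaded.reduced_data()) == len(synth_project.reduced_data())

    def test_truth_regenerates(self, synth_project):
        truth = load_truth(synth_project.root)
        assert truth.seed == 1
        assert truth.setting.model.mosaicity.sigma_iso_deg == 2.0


class TestSimulatePattern:
    def test_zero_F2_absent(self, clean_project):
        truth = load_truth(clean_project.root)
        preds = simulate_pattern(truth.setting, clean_project.structure())
        assert all(p.intensity > 0 for p in preds)

    def test_merge_composition(self, clean_project):
        truth = load_truth(clean_project.root)
        spots = clean_project.reduced_data()
        st = clean_project.structure()
        merged = simulate_pattern(truth.setting, st, merge=True, spots=spots)
        # external merge of the raw prediction list gives the same result
        from uedindex.matching import (assign_predictions, merge_assigned,
                                       default_ambit_radius)
        pred = predict_setting(truth.setting, st)
        xy = pred.detector_xy(truth.setting.model.geometry())
        a = assign_predictions(xy, spots, default_ambit_radius(spots))
        m2 = merge_assigned(a, xy, pred.intensity)
        assert np.allclose(merged.I_clc, m2.I_clc)

    def test_standard_vs_aniso_agreement(self, clean_project):
        # relrods parallel to the beam, isotropic mosaicity: the two
        # modelings give closely correlated matched intensities
        truth = load_truth(clean_project.root)
        spots = clean_project.reduced_data()
        st = clean_project.structure()
        s_an = replace(truth.setting,
                       control=replace(truth.setting.control, aniso=True))
        s_st = replace(truth.setting,
                       control=replace(truth.setting.control, aniso=False))
        m_an = simulate_pattern(s_an, st, merge=True, spots=spots)
        m_st = simulate_pattern(s_st, st, merge=True, spots=spots)
        both = m_an.matched & m_st.matched
        r = np.corrcoef(m_an.I_clc[both], m_st.I_clc[both])[0, 1]
        assert r > 0.95


class TestSimulateImage:
    def test_pixel_sum_close_to_total_intensity(self, clean_project):
        # whole-pattern sum; a few percent is lost to spots clipped at the
        # detector edge
        truth = load_truth(clean_project.root)
        st = clean_project.structure()
        img = simulate_image(truth.setting, st, (512, 512))
        pred = predict_setting(truth.setting, st)
        xy = pred.detector_xy(truth.setting.model.geometry())
        on = ((xy[:, 0] >= 0) & (xy[:, 0] < 512)
              & (xy[:, 1] >= 0) & (xy[:, 1] < 512))
        total = pred.intensity[on].sum()
        assert 0.93 * total < img.sum() < 1.05 * total
        assert np.all(img >= 0)

    def test_single_spot_normalization(self):
        # one rendered Gaussian well inside the frame: pixel sum = I
        # within the 0.5% truncation contract
        from uedindex.workbench import _render_gaussian
        img = np.zeros((256, 256))
        C = np.array([[2.5, 0.8], [0.8, 1.7]])
        _render_gaussian(img, 120.3, 140.7, C, I=7.0)
        assert img.sum() == pytest.approx(7.0, rel=5e-3)

    def test_zero_predictions_zero_image(self, cubic_carbon):
        s = default_truth_setting()
        s = replace(s, model=s.model.update(beam_center=(64.0, 64.0)),
                    control=replace(s.control, dmin=4.6, dmax=4.9))
        img = simulate_image(s, cubic_carbon, (128, 128))
        assert img.shape == (128, 128)
        assert img.sum() == 0.0

    def test_beam_center_outside_is_error(self, clean_project):
        truth = load_truth(clean_project.root)
        with pytest.raises(ValueError, match="beam center"):
            simulate_image(truth.setting, clean_project.structure(), (64, 64))

    def test_divergence_broadens_spots(self, clean_project):
        truth = load_truth(clean_project.root)
        st = clean_project.structure()
        from uedindex.profiles import BeamModel

        def second_moment(sigma_divg):
            s = replace(truth.setting, model=replace(
                truth.setting.model, beam=BeamModel(sigma_divg=sigma_divg)))
            img = simulate_image(s, st, (512, 512))
            yy, xx = np.mgrid[0:512, 0:512]
            w = img / img.sum()
            cx, cy = (w * xx).sum(), (w * yy).sum()
            return (w * ((xx - cx) ** 2 + (yy - cy) ** 2)).sum()

        assert second_moment(3e-3) > second_moment(1e-4)


class TestMask:
    def test_masked_spots_excluded(self, tmp_path):
        truth = SyntheticTruth(setting=default_truth_setting(), seed=5)
        proj = make_synthetic_project(truth, tmp_path / "m", with_mask=True,
                                      with_image=False)
        spots = proj.reduced_data()
        mask = proj.mask()
        assert mask is not None
        assert not mask.contains(spots.xy).any()

    def test_region_specs(self):
        m = DetectorMask(regions=[("circle", 10, 10, 5),
                                  ("rect", 50, 50, 60, 70)])
        got = m.contains(np.array([[10, 12], [10, 16], [55, 60], [55, 80]]))
        assert list(got) == [True, False, True, False]
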