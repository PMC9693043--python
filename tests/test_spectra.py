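"""Preprocessing tests: I/O round trips, FT, calibration, binning, normalization."""

import numpy as np
import pandas as pd
import pytest

from gestox import spectra, synth
from gestox.spectra import (
    AssignmentMap,
    BinSpec,
    FeatureMatrix,
    Fid,
    SampleMeta,
    Spectrum1D,
    SpectrumError,
)


def _spectrum(ppm, intensity, **meta):
    kw = dict(sample_id="s1", group="C", day="D8", fluid="plasma")
    kw.update(meta)
    return Spectrum1D(np.asarray(ppm, float), np.asarray(intensity, float),
                      SampleMeta(**kw))


class TestIO:
    def test_csv_three_point_parse(self, tmp_path):
        p = tmp_path / "tiny.csv"
        p.write_text("# sample_id: s1\n# group: C\n# day: D8\n# fluid: plasma\n"
                     "ppm,intensity\n1.0,5\n0.9,6\n0.8,7\n")
        sp = spectra.read_spectrum(p)
        assert len(sp) == 3
        assert sp.ppm[0] == 1.0 and sp.intensity[-1] == 7.0

    def test_csv_round_trip_preserves_values(self, tmp_path):
        rng = np.random.default_rng(0)
        sp = _spectrum(np.linspace(9.0, 0.5, 512), rng.normal(size=512))
        path = tmp_path / "sp.csv"
        spectra.write_spectrum(sp, path)
        back = spectra.read_spectrum(path)
        np.testing.assert_allclose(back.intensity, sp.intensity, rtol=1e-9)
        np.testing.assert_allclose(back.ppm, sp.ppm, rtol=1e-9)
        assert back.meta.sample_id == "s1"

    def test_jcampdx_round_trip_matches_csv_twin(self, tmp_path):
        rng = np.random.default_rng(1)
        sp = _spectrum(np.linspace(9.0, 0.5, 300), rng.normal(size=300))
        spectra.write_spectrum(sp, tmp_path / "sp.jdx", format="jcampdx")
        spectra.write_spectrum(sp, tmp_path / "sp.csv", format="csv")
        a = spectra.read_spectrum(tmp_path / "sp.jdx")
        b = spectra.read_spectrum(tmp_path / "sp.csv")
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-9)
        np.testing.assert_allclose(a.ppm, b.ppm, rtol=1e-9, atol=1e-12)
        assert a.meta.group == b.meta.group == "C"

    def test_missing_metadata_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("# sample_id: s1\nppm,intensity\n1.0,5\n0.9,6\n")
        with pytest.raises(SpectrumError, match="metadata"):
            spectra.read_spectrum(p)

    def test_malformed_line_reported_with_context(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("# sample_id: s1\n# group: C\n# day: D8\n# fluid: plasma\n"
                     "ppm,intensity\n1.0,5\nnot-a-row\n")
        with pytest.raises(SpectrumError, match="line 7"):
            spectra.read_spectrum(p)

    def test_axis_must_be_strictly_monotone(self):
        with pytest.raises(SpectrumError, match="monotone"):
            _spectrum([1.0, 1.0, 0.8], [1, 2, 3])


class TestApodizeTransform:
    @staticmethod
    def _fid(freq_hz, t2=0.5, n=65536, dwell=1e-4):
        t = np.arange(n) * dwell
        data = np.exp(2j * np.pi * freq_hz * t - t / t2)
        return Fid(data=data, dwell_s=dwell, sweep_hz=1.0 / dwell,
                   meta=SampleMeta("f", "C", "D8", "plasma"))

    @staticmethod
    def _fwhm(sp):
        y = sp.intensity
        half = y.max() / 2
        peak = int(np.argmax(y))
        hz = sp.ppm * spectra.PROTON_FREQ_MHZ
        # interpolate the half-max crossings on either side of the peak
        left = np.interp(half, y[:peak + 1], hz[:peak + 1])
        right = np.interp(half, y[peak:][::-1], hz[peak:][::-1])
        return abs(left - right)

    def test_peak_lands_at_fid_frequency(self):
        fid = self._fid(freq_hz=600.13)  # 1 ppm off carrier
        sp = spectra.apodize_transform(fid, 0.0)
        peak_ppm = sp.ppm[int(np.argmax(sp.intensity))]
        assert peak_ppm == pytest.approx(fid.carrier_ppm + 1.0, abs=0.01)

    def test_line_broadening_widens_fwhm_by_lb(self):
        fid = self._fid(freq_hz=0.0, t2=0.5)
        w0 = self._fwhm(spectra.apodize_transform(fid, 0.0))
        w1 = self._fwhm(spectra.apodize_transform(fid, 1.0))
        assert w1 - w0 == pytest.approx(1.0, abs=0.3)

    def test_fluid_default_line_broadening(self):
        assert spectra.LINE_BROADENING_HZ["plasma"] == 1.0
        assert spectra.LINE_BROADENING_HZ["urine"] == 0.3

    def test_negative_lb_rejected(self):
        with pytest.raises(SpectrumError):
            spectra.apodize_transform(self._fid(0.0), -1.0)


class TestCalibrate:
    @staticmethod
    def _doublet_spectrum(center, fluid="plasma"):
        design = synth.CohortDesign(fluid=fluid, points=16384, noise_sd=0.01,
                                    baseline_amplitude=0.0, shift_jitter_sd=0.0)
        lib = synth.MetabolitePeakLibrary((
            synth.MetaboliteEntry("Lactate", (synth.Peak(center, "d", 3.0),)),))
        return synth.render_spectrum({"Lactate": 5.0}, lib, design, seed=0,
                                     meta=SampleMeta("s", "C", "D8", fluid))

    def test_offset_doublet_is_pulled_back_to_nominal(self):
        sp = self._doublet_spectrum(1.345)
        cal = spectra.calibrate(sp)
        assert cal.meta.extra["calibration_shift_ppm"] == pytest.approx(-0.015, abs=0.002)
        det = spectra.detect_reference(cal, 1.33, (1.2, 1.45), "doublet")
        assert det == pytest.approx(1.33, abs=0.002)

    def test_reference_on_nominal_gives_zero_shift(self):
        design = synth.CohortDesign(fluid="urine", points=16384, noise_sd=0.01,
                                    baseline_amplitude=0.0, shift_jitter_sd=0.0)
        lib = synth.MetabolitePeakLibrary((
            synth.MetaboliteEntry("TSP", (synth.Peak(0.0, "s", 9.0),)),))
        sp = synth.render_spectrum({"TSP": 3.0}, lib, design, seed=0,
                                   meta=SampleMeta("u", "C", "D8", "urine"))
        cal = spectra.calibrate(sp)
        assert abs(cal.meta.extra["calibration_shift_ppm"]) < 1e-3

    def test_shift_recovery_round_trip(self):
        sp = self._doublet_spectrum(1.33)
        shifted = Spectrum1D(sp.ppm + 0.021, sp.intensity, sp.meta)
        cal = spectra.calibrate(shifted)
        step = abs(sp.ppm[1] - sp.ppm[0])
        np.testing.assert_allclose(cal.ppm, sp.ppm, atol=step + 1e-9)

    def test_calibration_is_idempotent(self):
        sp = self._doublet_spectrum(1.36)
        once = spectra.calibrate(sp)
        twice = spectra.calibrate(once)
        step = abs(sp.ppm[1] - sp.ppm[0])
        extra_shift = twice.meta.extra["calibration_shift_ppm"] - \
            once.meta.extra["calibration_shift_ppm"]
        assert abs(extra_shift) <= step

    def test_no_peak_in_window_rejected(self, flat_spectrum):
        with pytest.raises(SpectrumError, match="window"):
            spectra.calibrate(flat_spectrum,
                              {"nominal": 8.0, "window": (7.9, 8.1), "shape": "singlet"})


class TestBinning:
    def test_plasma_defaults_give_3655_bins(self, flat_spectrum):
        row = spectra.bin_spectrum(flat_spectrum, BinSpec.for_fluid("plasma"))
        # (9.0-0.5)/0.002 = 4250 bins minus 250 (urea) minus 345 (water)
        assert len(row.feature_ids) == 3655

    def test_urine_defaults_give_1590_bins(self, flat_spectrum):
        meta = SampleMeta("u", "C", "D8", "urine")
        sp = Spectrum1D(flat_spectrum.ppm, flat_spectrum.intensity, meta)
        row = spectra.bin_spectrum(sp, BinSpec.for_fluid("urine"))
        # (9.5-0.5)/0.005 = 1800 bins minus 90 (urea) minus 120 (water)
        assert len(row.feature_ids) == 1590

    def test_constant_intensity_bins_equal_value_times_spacing(self, flat_spectrum):
        spec = BinSpec.for_fluid("plasma")
        row = spectra.bin_spectrum(flat_spectrum, spec)
        np.testing.assert_allclose(row.values, 3.0 * spec.spacing, rtol=1e-9)

    def test_no_bin_center_inside_exclusions(self, flat_spectrum):
        row = spectra.bin_spectrum(flat_spectrum, BinSpec.for_fluid("plasma"))
        centers = np.array([float(c) for c in row.feature_ids])
        assert not np.any((centers > 4.54) & (centers < 5.23))
        assert not np.any((centers > 5.5) & (centers < 6.0))

    def test_binning_conserves_mass(self):
        rng = np.random.default_rng(3)
        ppm = np.linspace(9.5, -0.5, 16384)
        sp = _spectrum(ppm, rng.random(ppm.size) + 0.5)
        spec = BinSpec((0.5, 9.0), 0.002, ((5.5, 6.0), (4.54, 5.23)))
        row = spectra.bin_spectrum(sp, spec)
        from scipy.integrate import cumulative_trapezoid
        x, y = sp.ppm[::-1], sp.intensity[::-1]
        cum = np.concatenate([[0.0], cumulative_trapezoid(y, x)])

        def seg(a, b):
            return np.interp(b, x, cum) - np.interp(a, x, cum)

        expected = seg(0.5, 9.0) - seg(5.5, 6.0) - seg(4.54, 5.23)
        assert row.values.sum() == pytest.approx(expected, rel=1e-6)

    def test_region_outside_axis_rejected(self):
        sp = _spectrum(np.linspace(5.0, 1.0, 2048), np.ones(2048))
        with pytest.raises(SpectrumError, match="outside"):
            spectra.bin_spectrum(sp, BinSpec.for_fluid("plasma"))


class TestMatrixAssembly:
    @staticmethod
    def _rows(n=4):
        rows = []
        ids = ("2.000000", "1.000000")
        for i in range(n):
            meta = SampleMeta(f"s{i}", "C" if i % 2 == 0 else "H", "D8", "plasma")
            rows.append(spectra.FeatureRow(ids, np.array([float(i), float(i) + 1]), meta))
        return rows

    def test_single_row_matrix_equals_row(self):
        rows = self._rows(1)
        m = spectra.assemble_matrix(rows)
        assert m.values.shape == (1, 2)
        np.testing.assert_array_equal(m.values.iloc[0].to_numpy(), rows[0].values)

    def test_row_order_is_canonical(self):
        rows = self._rows(4)
        a = spectra.assemble_matrix(rows)
        b = spectra.assemble_matrix(list(reversed(rows)))
        assert a.values.equals(b.values)
        assert list(a.meta["group"]) == sorted(a.meta["group"])

    def test_ragged_rows_rejected_naming_feature(self):
        rows = self._rows(2)
        bad = spectra.FeatureRow(("2.000000", "0.500000"), np.array([1.0, 2.0]),
                                 SampleMeta("sx", "H", "D8", "plasma"))
        with pytest.raises(SpectrumError, match="0.500000"):
            spectra.assemble_matrix(rows + [bad])

    def test_cohort_matrix_shape(self, small_plasma_cohort):
        cohort, _ = small_plasma_cohort
        spec = BinSpec.for_fluid("plasma")
        m = spectra.assemble_matrix([spectra.bin_spectrum(sp, spec) for sp in cohort])
        assert m.values.shape == (len(cohort), 3655)


class TestNormalize:
    @staticmethod
    def _matrix(X, groups=None):
        n = X.shape[0]
        ids = [f"s{i}" for i in range(n)]
        groups = groups or ["C"] * n
        meta = pd.DataFrame({"group": groups, "day": "D8", "fluid": "plasma"}, index=ids)
        return FeatureMatrix(pd.DataFrame(X, index=ids,
                                          columns=[f"f{j}" for j in range(X.shape[1])]), meta)

    def test_pqn_leaves_identical_rows_unchanged(self):
        X = np.tile(np.array([1.0, 2.0, 3.0]), (4, 1))
        out = spectra.normalize(self._matrix(X), "pqn")
        np.testing.assert_allclose(out.values.to_numpy(), X, rtol=1e-12)

    def test_pqn_restores_single_scaled_row(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.vstack([base, base, base, 2.0 * base])
        out = spectra.normalize(self._matrix(X), "pqn")
        np.testing.assert_allclose(out.values.to_numpy()[3], base, rtol=1e-9)

    def test_pqn_recovers_known_dilution_factors(self):
        # pqn removes per-sample factors up to the cohort-median factor:
        # all diluted copies of one profile collapse onto a common profile
        rng = np.random.default_rng(7)
        base = rng.random(200) + 0.5
        factors = np.array([0.5, 0.8, 1.0, 1.25, 2.0, 1.1])
        X = np.outer(factors, base)
        out = spectra.normalize(self._matrix(X), "pqn").values.to_numpy()
        expected = np.tile(np.median(factors) * base, (6, 1))
        np.testing.assert_allclose(out, expected, rtol=1e-9)

    def test_total_area_equalizes_row_sums(self):
        rng = np.random.default_rng(1)
        X = rng.random((5, 30)) + 0.1
        out = spectra.normalize(self._matrix(X), "total_area")
        sums = out.values.to_numpy().sum(axis=1)
        np.testing.assert_allclose(sums, sums[0], rtol=1e-9)

    def test_nonpositive_row_sum_rejected_with_sample_id(self):
        X = np.array([[1.0, 2.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(SpectrumError, match="s1"):
            spectra.normalize(self._matrix(X), "total_area")


class TestQuantify:
    @staticmethod
    def _bin_matrix():
        centers = ["3.000000", "2.000000", "1.200000", "1.100000", "1.000000"]
        X = np.array([[5.0, 4.0, 1.0, 2.0, 3.0]])
        meta = pd.DataFrame({"group": ["C"], "day": ["D8"], "fluid": ["plasma"]},
                            index=["s0"])
        return FeatureMatrix(pd.DataFrame(X, index=["s0"], columns=centers), meta)

    def test_window_sums_covered_bins(self):
        m = self._bin_matrix()
        amap = AssignmentMap({"Met": [(0.95, 1.25)]})
        q = spectra.quantify_metabolites(m, amap)
        assert q.values.loc["s0", "Met"] == pytest.approx(6.0)

    def test_disjoint_windows_add_up(self):
        m = self._bin_matrix()
        amap = AssignmentMap({"Met": [(0.95, 1.05), (2.9, 3.1)]})
        q = spectra.quantify_metabolites(m, amap)
        assert q.values.loc["s0", "Met"] == pytest.approx(3.0 + 5.0)

    def test_empty_window_rejected_naming_metabolite(self):
        m = self._bin_matrix()
        amap = AssignmentMap({"Ghost": [(7.0, 7.1)]})
        with pytest.raises(SpectrumError, match="Ghost"):
            spectra.quantify_metabolites(m, amap)

    def test_quantification_is_linear_in_spectrum_scale(self, small_plasma_cohort,
                                                        plasma_library):
        cohort, _ = small_plasma_cohort
        sp = cohort[0]
        spec = BinSpec.for_fluid("plasma")
        amap = synth.default_assignment_map(plasma_library, fluid="plasma")
        row1 = spectra.bin_spectrum(sp, spec)
        sp2 = Spectrum1D(sp.ppm, 3.0 * sp.intensity, sp.meta)
        row2 = spectra.bin_spectrum(sp2, spec)
        m1 = spectra.assemble_matrix([row1])
        m2 = spectra.assemble_matrix([row2])
        q1 = spectra.quantify_metabolites(m1, amap).values.to_numpy()
        q2 = spectra.quantify_metabolites(m2, amap).values.to_numpy()
        np.testing.assert_allclose(q2, 3.0 * q1, rtol=1e-9)

    def test_planted_fold_change_recovered_through_spectra(self):
        # zero-noise end-to-end: render -> calibrate -> bin -> quantify
        design = synth.CohortDesign(fluid="plasma", n_per_cell=2, points=16384,
                                    noise_sd=0.0, baseline_amplitude=0.0,
                                    shift_jitter_sd=0.0)
        lib = synth.build_default_library("plasma")
        base = {name: 0.0 for name in lib.names}
        base["Citrate"] = 2.0
        base["Lactate"] = 1.0  # calibration reference must be present
        eff = synth.EffectSpec((synth.Effect("Citrate", "D20", 2.0),))
        cohort, _ = synth.simulate_cohort(design, eff, seed=0, base_levels=base,
                                          sigma_log=0.0)
        spec = BinSpec.for_fluid("plasma")
        rows = [spectra.bin_spectrum(spectra.calibrate(sp), spec) for sp in cohort]
        m = spectra.assemble_matrix(rows)
        amap = synth.default_assignment_map(lib, fluid="plasma")
        q = spectra.quantify_metabolites(m, amap)
        d20 = q.subset(day="D20")
        vals = d20.values["Citrate"]
        fc = vals[d20.meta["group"] == "H"].mean() / vals[d20.meta["group"] == "C"].mean()
        assert fc == pytest.approx(2.0, rel=0.01)
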