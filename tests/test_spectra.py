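"""Spectrum reduction: peak fitting, relative indicators, categorization."""

import numpy as np
import pytest

from solucover.spectra import (GAUSS_AREA_FACTOR, Evaluation, Spectrum,
                               categorize, fit_main_peak, fwhm_nm_to_ev,
                               indicator_table, relative_indicators)
from solucover.synthdata import SpectrumSpec, synth_spectrum


def make_eval(mol, solv, fwhm_r, area_r, found=True):
    return Evaluation(mol, solv, found, 420.0 if found else None,
                      1.0 if found else None, 12.0 if found else None,
                      12.0 if found else None, fwhm_r, area_r)


class TestFitMainPeak:
    def test_noiseless_single_gaussian_recovered_analytically(self):
        spec, _ = synth_spectrum(SpectrumSpec(components=((418.0, 1.0, 12.0),)))
        fit = fit_main_peak(spec)
        assert fit.peak_found
        assert fit.lambda_max == pytest.approx(418.0, abs=0.1)
        assert fit.intensity == pytest.approx(1.0, abs=0.01)
        assert fit.fwhm == pytest.approx(12.0, abs=0.1)
        assert fit.area == pytest.approx(1.0 * 12.0 * GAUSS_AREA_FACTOR, rel=0.01)

    def test_flat_spectrum_no_peak(self):
        wl = np.arange(350.0, 700.0)
        fit = fit_main_peak(Spectrum(wl, np.zeros_like(wl)))
        assert not fit.peak_found

    def test_noise_only_spectrum_no_peak(self):
        spec, truth = synth_spectrum(SpectrumSpec(components=(), noise_sd=0.002,
                                                  seed=5))
        assert not truth.peak_found
        assert not fit_main_peak(spec).peak_found

    def test_shoulder_widens_single_fit_but_area_recovers_main(self):
        spec, truth = synth_spectrum(SpectrumSpec(
            components=((418.0, 1.0, 12.0), (403.0, 0.3, 14.0))))
        fit = fit_main_peak(spec)
        assert fit.peak_found
        assert fit.fwhm > 12.0  # shoulder inflates the single-Gaussian width
        assert fit.area == pytest.approx(truth.area, rel=0.05)

    def test_window_outside_grid_rejected(self):
        wl = np.arange(400.0, 450.0)
        with pytest.raises(ValueError, match="window"):
            fit_main_peak(Spectrum(wl, np.ones_like(wl)), window=(380.0, 470.0))

    def test_fwhm_ev_helper(self):
        # a ~12 nm FWHM at ~418 nm is ~0.085 eV
        assert fwhm_nm_to_ev(418.0, 12.0) == pytest.approx(0.0851, abs=0.001)

    def test_random_spectra_parameter_recovery(self, rng):
        # 50 random single peaks at SNR 50: lambda_max within 0.5 nm,
        # fwhm and area within 5% of analytic truth
        for i in range(50):
            center = float(rng.uniform(400.0, 440.0))
            fwhm = float(rng.uniform(8.0, 40.0))
            height = float(rng.uniform(0.3, 1.2))
            spec, truth = synth_spectrum(SpectrumSpec(
                components=((center, height, fwhm),),
                noise_sd=height / 50.0, seed=1000 + i))
            fit = fit_main_peak(spec)
            assert fit.peak_found
            assert abs(fit.lambda_max - truth.lambda_max) < 0.5
            assert abs(fit.fwhm - truth.fwhm) / truth.fwhm < 0.05
            assert abs(fit.area - truth.area) / truth.area < 0.05


class TestRelativeIndicators:
    def test_extremes_and_ratio(self):
        fits = [fit_main_peak(synth_spectrum(SpectrumSpec(
            components=((418.0, 1.0, f),)))[0]) for f in (12.0, 24.0, 18.0)]
        rel = relative_indicators(fits)
        fwhm_rs = [r[0] for r in rel]
        assert fwhm_rs[0] == pytest.approx(1.0, abs=1e-3)   # attains FWHM_min
        assert fwhm_rs[1] == pytest.approx(0.5, abs=1e-3)   # 2x FWHM_min
        # widest peak also has the largest area here (same height)
        assert max(r[1] for r in rel) == pytest.approx(1.0)

    def test_no_peak_entries_zeroed(self):
        good = fit_main_peak(synth_spectrum(SpectrumSpec(
            components=((418.0, 1.0, 12.0),)))[0])
        flat = fit_main_peak(synth_spectrum(SpectrumSpec(components=()))[0])
        rel = relative_indicators([good, flat])
        assert rel[1] == (0.0, 0.0)
        assert rel[0] == (pytest.approx(1.0), pytest.approx(1.0))

    def test_insoluble_everywhere_warns_and_zeroes(self):
        flat = [fit_main_peak(synth_spectrum(SpectrumSpec(components=()))[0])
                for _ in range(3)]
        with pytest.warns(UserWarning, match="no peak"):
            rel = relative_indicators(flat)
        assert rel == [(0.0, 0.0)] * 3

    def test_scale_invariance(self):
        specs = [synth_spectrum(SpectrumSpec(components=((418.0, h, f),)))[0]
                 for h, f in [(1.0, 12.0), (0.5, 20.0), (0.8, 15.0)]]
        rel = relative_indicators([fit_main_peak(s) for s in specs])
        scaled = [Spectrum(s.wavelength, 3.7 * s.absorbance) for s in specs]
        rel_scaled = relative_indicators([fit_main_peak(s) for s in scaled])
        for (a, b), (c, d) in zip(rel, rel_scaled):
            assert a == pytest.approx(c, rel=1e-4)
            assert b == pytest.approx(d, rel=1e-4)


class TestCategorize:
    def _blob_evals(self, rng):
        centers = [(0.05, 0.05), (0.3, 0.9), (0.9, 0.3), (0.8, 0.8), (1.0, 1.0)]
        evals, truth = [], []
        for c, (fx, fy) in enumerate(centers):
            for i in range(12):
                x = float(np.clip(fx + rng.normal(0, 0.02), 0, 1.05))
                y = float(np.clip(fy + rng.normal(0, 0.02), 0, 1.05))
                evals.append(make_eval(f"M{c}_{i}", "S1", x, y))
                truth.append(c)
        return evals, truth

    def test_planted_blobs_recovered_with_centroid_ordering(self, rng):
        evals, truth = self._blob_evals(rng)
        out = categorize(evals, k=5, seed=0)
        # centroid-sum ordering: blob near the origin -> 0, blob at (1,1) -> 4
        by_blob = {}
        for e, t in zip(out, truth):
            by_blob.setdefault(t, set()).add(e.category)
        assert all(len(cats) == 1 for cats in by_blob.values())
        assert by_blob[0] == {0}
        assert by_blob[4] == {4}
        # (0.3,0.9) and (0.9,0.3) tie on centroid sum against each other but
        # both sit strictly between the origin blob and the (0.8,0.8) blob
        assert by_blob[3] | by_blob[1] | by_blob[2] == {1, 2, 3}

    def test_no_peak_forced_to_category_zero(self, rng):
        evals, _ = self._blob_evals(rng)
        evals.append(make_eval("MX", "S2", 0.0, 0.0, found=False))
        out = categorize(evals, k=5, seed=0)
        assert out[-1].category == 0
        assert not out[-1].label_good

    def test_duplicate_point_changes_nothing(self, rng):
        evals, _ = self._blob_evals(rng)
        base = categorize(evals, k=5, seed=0)
        dup = categorize(evals + [evals[7]], k=5, seed=0)
        assert [e.category for e in dup[:-1]] == [e.category for e in base]
        assert dup[-1].category == base[7].category

    def test_too_few_distinct_points_rejected(self):
        evals = [make_eval("M", f"S{i}", 0.5, 0.5) for i in range(10)]
        with pytest.raises(ValueError, match="smaller k"):
            categorize(evals, k=5)

    def test_label_good_is_category_3_or_4(self, rng):
        evals, _ = self._blob_evals(rng)
        out = categorize(evals, k=5, seed=0)
        for e in out:
            assert e.label_good == (e.category in (3, 4))


class TestIndicatorTable:
    def test_small_design_bookkeeping(self):
        # 2 molecules x 3 solvents, one flat spectrum -> 6 rows, 1 no-peak
        specs = []
        params = [(418, 1.0, 12.0), (420, 0.8, 30.0), (415, 0.2, 14.0),
                  (419, 1.1, 11.0), (417, 0.4, 25.0)]
        k = 0
        for m in range(2):
            for s in range(3):
                if (m, s) == (1, 2):
                    sp, _ = synth_spectrum(SpectrumSpec(
                        components=(), molecule_id=f"M{m}", solvent_id=f"S{s}"))
                else:
                    c, h, f = params[k]
                    sp, _ = synth_spectrum(SpectrumSpec(
                        components=((float(c), h, f),),
                        molecule_id=f"M{m}", solvent_id=f"S{s}"))
                    k += 1
                specs.append(sp)
        table = indicator_table(specs, k=3, seed=0)
        assert len(table) == 6
        assert int((~table["peak_found"]).sum()) == 1
        assert int((table["category"] == 0).sum()) >= 1
        no_peak = table[~table["peak_found"]].iloc[0]
        assert no_peak["category"] == 0
        assert np.isnan(no_peak["lambda_max"])

    def test_per_molecule_relative_maxima(self):
        specs = []
        for m, fwhms in enumerate([(12.0, 18.0, 24.0), (10.0, 15.0, 40.0)]):
            for s, f in enumerate(fwhms):
                sp, _ = synth_spectrum(SpectrumSpec(
                    components=((418.0, 1.0, f),),
                    molecule_id=f"M{m}", solvent_id=f"S{s}"))
                specs.append(sp)
        table = indicator_table(specs, k=3, seed=0)
        for _, grp in table.groupby("molecule_id"):
            assert grp["fwhm_r"].max() == pytest.approx(1.0, abs=1e-3)
            assert grp["area_r"].max() == pytest.approx(1.0, abs=1e-3)
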