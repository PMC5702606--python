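"""Peak picking, lineshape fitting and the normalized-intensity statistic."""

import math

import numpy as np
import pytest

from metnmr.exchange import SpectralAxis
from metnmr.peaks import (
    IntensityRecord,
    correct_snr,
    estimate_noise,
    fit_peaks,
    match_peaks_to_labels,
    normalize_series,
    pick_peaks,
    relative_intensity,
    water_viscosity,
    PeakFit,
)
from metnmr.peaks import _model_volume, _lorentzian_1d
from metnmr.nus import Spectrum2D
from metnmr.synthetic import (
    GroundTruthPeak,
    ReceptorStateSpec,
    SyntheticScene,
    make_scene,
    render_spectrum,
)


def long_axes():
    """Axes with long acquisition so rendered peaks are near-pure Lorentzians."""
    h = SpectralAxis("1H", 800.0, 10_000.0, 1024, carrier=1.8)
    c = SpectralAxis("13C", 201.0, 4_000.0, 512, carrier=17.0)
    return h, c


def scene_of(peaks, noise=0.0, seed=0, axes=None):
    st = ReceptorStateSpec(state_kind="apo")
    return SyntheticScene(state=st, peaks=tuple(peaks),
                          axes=axes or long_axes(), noise_sigma=noise, seed=seed)


def peak(dh, dc, h, fwhm_h=60.0, fwhm_c=40.0, label="P"):
    return GroundTruthPeak(label, "", dh, dc, h, fwhm_h, fwhm_c,
                           h * np.pi**2 / 4 * fwhm_h * fwhm_c)


class TestNoise:
    def test_gaussian_sigma_recovered(self, rng):
        z = rng.normal(0, 1.0, size=(80, 80))
        spec = _bare_spectrum(z)
        assert estimate_noise(spec, region=(slice(None), slice(None))) == pytest.approx(
            1.0, rel=0.05)

    def test_zero_spectrum(self):
        spec = _bare_spectrum(np.zeros((64, 64)))
        assert estimate_noise(spec) == 0.0

    def test_offset_invariance(self, rng):
        z = rng.normal(0, 2.0, size=(80, 80))
        a = estimate_noise(_bare_spectrum(z), region=(slice(None), slice(None)))
        b = estimate_noise(_bare_spectrum(z + 17.0), region=(slice(None), slice(None)))
        assert a == pytest.approx(b, rel=1e-12)

    def test_empty_region_rejected(self):
        spec = _bare_spectrum(np.zeros((16, 16)))
        with pytest.raises(ValueError):
            estimate_noise(spec, region=(slice(20, 25), slice(0, 4)))


def _bare_spectrum(z):
    h = SpectralAxis("1H", 800.0, 10_000.0, z.shape[0], carrier=1.8)
    c = SpectralAxis("13C", 201.0, 4_000.0, z.shape[1], carrier=17.0)
    return Spectrum2D(intensity=z, ppm_direct=h.ppm_grid(z.shape[0]),
                      ppm_indirect=c.ppm_grid(z.shape[1]), axes=(h, c))


class TestPicking:
    def test_zero_spectrum_empty(self):
        spec = _bare_spectrum(np.zeros((64, 64)))
        assert pick_peaks(spec, threshold_sigma=5, noise=1.0) == []

    def test_single_peak_at_ten_sigma(self):
        # threshold 6: on the zero-filled ~8M-point grid, isolated >5 sigma
        # noise excursions are expected; 6 sigma keeps only the real peak
        sc = scene_of([peak(2.2, 16.0, 10.0)], noise=1.0, seed=7)
        spec, _ = render_spectrum(sc)
        found = pick_peaks(spec, threshold_sigma=6)
        assert len(found) == 1
        assert abs(found[0].delta_h - 2.2) <= 2 * np.mean(np.diff(spec.ppm_direct))

    def test_broadened_out_peak_not_picked(self):
        # detectability round trip: a reporter attenuated below the noise
        # floor is absent from the picked set while its neighbor is found
        pks = [peak(2.0, 16.0, 20.0, label="strong"),
               peak(2.5, 18.0, 1.0, label="gone")]
        sc = scene_of(pks, noise=1.0, seed=11)
        spec, _ = render_spectrum(sc)
        found = pick_peaks(spec, threshold_sigma=3)
        assert any(abs(f.delta_h - 2.0) < 0.02 for f in found)
        assert not any(abs(f.delta_h - 2.5) < 0.03 and abs(f.delta_c - 18.0) < 0.3
                       for f in found)

    def test_full_scene_m90_reported_broadened_out(self, models):
        # with a full agonist the M90 reporter is flagged, not fabricated
        st = ReceptorStateSpec(state_kind="ligand", ligand="isoprenaline")
        sc = make_scene(models, st, noise_sigma=1.0, seed=3)
        spec, _ = render_spectrum(sc)
        picked = pick_peaks(spec, threshold_sigma=5)
        truth = {p.label: (p.delta_h, p.delta_c) for p in sc.peaks
                 if p.broadening_flag == "detectable"}
        match_peaks_to_labels(picked, truth)
        fits = fit_peaks(spec, [p for p in picked if p.label != "unassigned"])
        rec = relative_intensity(fits, "M90a")
        assert rec.broadened_out and rec.relative_intensity == 0.0

    def test_threshold_must_be_positive(self):
        spec = _bare_spectrum(np.zeros((16, 16)))
        with pytest.raises(ValueError):
            pick_peaks(spec, threshold_sigma=0.0)


class TestFitting:
    def test_exact_lorentzian_parameters_recovered(self):
        # fitter correctness on an analytically constructed 2D Lorentzian
        from metnmr.peaks import Peak

        h = SpectralAxis("1H", 800.0, 10_000.0, 512, carrier=1.8)
        c = SpectralAxis("13C", 201.0, 4_000.0, 256, carrier=17.0)
        gh = h.ppm_grid(512)[:, None]
        gc = c.ppm_grid(256)[None, :]
        z = 50.0 * _lorentzian_1d(gh, 2.2, 60.0 / 800.0) * _lorentzian_1d(
            gc, 16.0, 40.0 / 201.0)
        spec = Spectrum2D(intensity=z, ppm_direct=h.ppm_grid(512),
                          ppm_indirect=c.ppm_grid(256), axes=(h, c),
                          noise_estimate=0.01)
        f = fit_peaks(spec, [Peak(2.21, 16.07, 40.0)])[0]
        step_h = np.mean(np.diff(spec.ppm_direct))
        assert abs(f.delta_h - 2.2) < 0.1 * step_h
        assert f.fwhm_h == pytest.approx(60.0, rel=1e-3)
        assert f.fwhm_c == pytest.approx(40.0, rel=1e-3)
        assert f.amplitude == pytest.approx(50.0, rel=1e-3)
        assert f.snr == pytest.approx(5000.0, rel=1e-3)

    def test_rendered_lorentzian_parameters_recovered(self):
        # rendered FIDs carry discrete-sampling distortion of order r*dt,
        # so linewidth recovery is a few percent
        from metnmr.peaks import Peak

        sc = scene_of([peak(2.2, 16.0, 50.0)])
        spec, _ = render_spectrum(sc, window="none", zero_fill=False)
        f = fit_peaks(spec, [Peak(2.205, 16.05, 45.0)])[0]
        step_h = np.mean(np.diff(spec.ppm_direct))
        assert abs(f.delta_h - 2.2) < 0.5 * step_h
        assert f.fwhm_h == pytest.approx(60.0, rel=0.06)
        assert f.fwhm_c == pytest.approx(40.0, rel=0.06)
        assert f.amplitude == pytest.approx(50.0, rel=0.03)

    def test_two_overlapping_peaks_resolved(self):
        sep_ppm = 60.0 / 800.0  # one 1H fwhm apart
        pks = [peak(2.2, 16.0, 50.0, label="A"),
               peak(2.2 + sep_ppm, 16.0, 40.0, label="B")]
        sc = scene_of(pks, noise=0.5, seed=2)
        spec, _ = render_spectrum(sc, window="none", zero_fill=False)
        from metnmr.peaks import Peak

        initial = [Peak(2.195, 16.02, 45.0, label="A"),
                   Peak(2.2 + sep_ppm + 0.004, 15.98, 35.0, label="B")]
        fits = {f.label: f for f in fit_peaks(spec, initial)}
        assert abs(fits["A"].delta_h - 2.2) < 0.1 * sep_ppm
        assert abs(fits["B"].delta_h - (2.2 + sep_ppm)) < 0.1 * sep_ppm

    def test_volume_closed_form_matches_quadrature(self):
        # oracle: numerical integration of the separable 2D Lorentzian
        from scipy.integrate import quad

        amp, wh, wc = 1.0, 50.0, 20.0
        vol = _model_volume("lorentzian", amp, wh, wc)
        ih, _ = quad(_lorentzian_1d, -np.inf, np.inf, args=(0.0, wh))
        ic, _ = quad(_lorentzian_1d, -np.inf, np.inf, args=(0.0, wc))
        assert vol == pytest.approx(amp * ih * ic, rel=1e-8)
        assert vol == pytest.approx(np.pi**2 / 4 * amp * wh * wc, rel=1e-12)

    def test_unknown_model_rejected(self):
        spec = _bare_spectrum(np.zeros((16, 16)))
        with pytest.raises(ValueError):
            fit_peaks(spec, [], model="voigtish")


class TestIntensityStatistics:
    def _fits(self, heights):
        return [PeakFit(2.0, 16.0, 30, 20, h, 1.0, label=lab)
                for lab, h in heights.items()]

    def test_relative_intensity_examples(self):
        fits = self._fits({"M223": 0.3, "M153": 0.6})
        rec = relative_intensity(fits, "M223")
        assert rec.relative_intensity == pytest.approx(0.5)
        rec2 = relative_intensity(fits, "M153")
        assert rec2.relative_intensity == pytest.approx(1.0)

    def test_missing_target_flags_zero(self):
        fits = self._fits({"M153": 0.6})
        rec = relative_intensity(fits, "M223")
        assert rec.relative_intensity == 0.0 and rec.broadened_out

    def test_missing_reference_is_hard_error(self):
        fits = self._fits({"M223": 0.3})
        with pytest.raises(ValueError, match="reference"):
            relative_intensity(fits, "M223", reference_label="M153")

    def test_normalize_examples(self):
        recs = [IntensityRecord("s%d" % i, "M223", "M153", v)
                for i, v in enumerate([0.1, 0.2, 0.4])]
        normalize_series(recs)
        assert [r.normalized_intensity for r in recs] == pytest.approx([0.25, 0.5, 1.0])

    def test_normalize_single_record(self):
        recs = [IntensityRecord("s", "M223", "M153", 0.7)]
        normalize_series(recs)
        assert recs[0].normalized_intensity == 1.0

    def test_normalize_idempotent(self):
        recs = [IntensityRecord("s%d" % i, "M223", "M153", v)
                for i, v in enumerate([0.3, 0.9, 0.6])]
        once = [r.normalized_intensity for r in normalize_series(recs)]
        for r in recs:
            r.relative_intensity = r.normalized_intensity
        twice = [r.normalized_intensity for r in normalize_series(recs)]
        assert once == pytest.approx(twice)

    def test_normalize_all_zero_rejected(self):
        recs = [IntensityRecord("s", "M223", "M153", 0.0)]
        with pytest.raises(ValueError):
            normalize_series(recs)

    def test_scale_invariance_of_ratios(self, models):
        st = ReceptorStateSpec(state_kind="apo")
        sc = make_scene(models, st, noise_sigma=0.0, seed=1)
        spec, _ = render_spectrum(sc)
        picked = pick_peaks(spec, threshold_sigma=5, noise=1.0)
        truth = {p.label: (p.delta_h, p.delta_c) for p in sc.peaks
                 if p.broadening_flag == "detectable"}
        match_peaks_to_labels(picked, truth)
        sel = [p for p in picked if p.label != "unassigned"]
        fits1 = fit_peaks(spec, sel)
        spec.intensity = spec.intensity * 7.5
        for p in sel:
            p.height *= 7.5
        fits2 = fit_peaks(spec, sel)
        r1 = relative_intensity(fits1, "M223").relative_intensity
        r2 = relative_intensity(fits2, "M223").relative_intensity
        assert r1 == pytest.approx(r2, rel=1e-6)


class TestSNRCorrection:
    def test_identity_at_reference(self):
        out, corr = correct_snr(10.0, 308.0, 308.0)
        assert out == 10.0 and corr.factor == 1.0

    def test_water_viscosity_factor(self):
        # empirical water-viscosity correlation: eta(298)/eta(308) ~ 0.890/0.719
        out, corr = correct_snr(10.0, 298.0, 308.0)
        assert corr.factor == pytest.approx(0.890 / 0.719, rel=0.01)
        assert out == pytest.approx(10.0 * corr.factor)

    def test_composition(self):
        a_b, _ = correct_snr(10.0, 288.0, 298.0)
        b_c, _ = correct_snr(a_b, 298.0, 308.0)
        a_c, _ = correct_snr(10.0, 288.0, 308.0)
        assert b_c == pytest.approx(a_c, rel=1e-9)

    def test_temperature_range_enforced(self):
        with pytest.raises(ValueError):
            water_viscosity(250.0)


class TestMatching:
    def test_ties_resolved_by_distance_one_peak_per_label(self):
        from metnmr.peaks import Peak
        peaks = [Peak(2.00, 16.0, 10.0), Peak(2.02, 16.0, 9.0)]
        match_peaks_to_labels(peaks, {"X": (2.005, 16.0)})
        labels = sorted(p.label for p in peaks)
        assert labels == ["X", "unassigned"]
        assert peaks[0].label == "X"  # closer one wins
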