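"""Ground-truth generation: shifts, broadening, titrations, determinism."""

import numpy as np
import pytest

from metnmr.binding import BindingModel
from metnmr.exchange import population_weighted_shift
from metnmr.synthetic import (
    LIGAND_EFFICACY,
    LIGAND_PLANES,
    ReceptorStateSpec,
    endpoints_from_plane,
    generate_efficacy_dataset,
    generate_state_peaks,
    generate_titration,
    make_scene,
    render_spectrum,
)


class TestReceptorStateSpec:
    def test_ligand_required_for_ligand_state(self):
        with pytest.raises(ValueError, match="requires a ligand"):
            ReceptorStateSpec(state_kind="ligand")

    def test_apo_must_not_carry_ligand(self):
        with pytest.raises(ValueError, match="must not carry"):
            ReceptorStateSpec(state_kind="apo", ligand="salbutamol")

    def test_unknown_ligand_without_efficacy_rejected(self):
        with pytest.raises(ValueError, match="unknown ligand"):
            ReceptorStateSpec(state_kind="ligand", ligand="mystery")

    def test_known_ligand_efficacy_filled_in(self):
        st = ReceptorStateSpec(state_kind="ligand", ligand="salbutamol")
        assert st.efficacy == LIGAND_EFFICACY["salbutamol"]

    def test_efficacy_bounds(self):
        with pytest.raises(ValueError):
            ReceptorStateSpec(state_kind="ligand", ligand="x", efficacy=130.0)

    def test_nanobody_state_has_zero_active_population(self):
        st = ReceptorStateSpec(state_kind="nanobody")
        assert st.active_population() == 0.0


class TestEndpointInversion:
    @pytest.mark.parametrize("plane", list(LIGAND_PLANES.values()))
    def test_endpoints_lie_on_plane(self, plane):
        a, b, c = plane
        lo, hi = endpoints_from_plane(plane, (2.0, 16.0))
        assert a * lo[0] + b * lo[1] + c == pytest.approx(0.0, abs=1e-9)
        assert a * hi[0] + b * hi[1] + c == pytest.approx(100.0, abs=1e-9)

    def test_degenerate_plane_rejected(self):
        with pytest.raises(ValueError):
            endpoints_from_plane((0.0, 0.0, 5.0), (2.0, 16.0))


class TestStatePeaks:
    def test_zero_efficacy_sits_at_inactive_endpoint(self, models):
        st = ReceptorStateSpec(state_kind="ligand", ligand="x", efficacy=0.0)
        peaks = {p.label: p for p in generate_state_peaks(models, st)}
        for m in models:
            for conf in m.conformers:
                if conf.only_state_kinds and "ligand" not in conf.only_state_kinds:
                    continue
                p = peaks[m.residue + conf.name]
                assert p.delta_h == pytest.approx(conf.delta_i[0], abs=1e-12)
                assert p.delta_c == pytest.approx(conf.delta_i[1], abs=1e-12)

    def test_ternary_endpoint_difference(self, models):
        hi = ReceptorStateSpec(state_kind="ternary", ligand="x", efficacy=100.0)
        lo = ReceptorStateSpec(state_kind="ternary", ligand="x", efficacy=0.0)
        ph = {p.label: p for p in generate_state_peaks(models, hi)}
        pl = {p.label: p for p in generate_state_peaks(models, lo)}
        conf = next(m for m in models if m.residue == "M296").conformers[0]
        dh = abs(ph["M296"].delta_h - pl["M296"].delta_h)
        dc = abs(ph["M296"].delta_c - pl["M296"].delta_c)
        assert dh == pytest.approx(abs(conf.delta_agp[0] - conf.delta_agm[0]), abs=1e-12)
        assert dc == pytest.approx(abs(conf.delta_agp[1] - conf.delta_agm[1]), abs=1e-12)

    def test_shift_is_population_weighted_average(self, models):
        st = ReceptorStateSpec(state_kind="ligand", ligand="x", efficacy=37.0)
        peaks = {p.label: p for p in generate_state_peaks(models, st)}
        conf = next(m for m in models if m.residue == "M223").conformers[0]
        expect = population_weighted_shift(
            [0.63, 0.37], [conf.delta_i[0], conf.delta_a[0]])
        assert peaks["M223"].delta_h == pytest.approx(expect, abs=1e-12)

    def test_monotone_shift_trajectory(self, models):
        hs = []
        for eps in np.linspace(0, 100, 11):
            st = ReceptorStateSpec(state_kind="ligand", ligand="x", efficacy=float(eps))
            peaks = {p.label: p for p in generate_state_peaks(models, st)}
            hs.append(peaks["M223"].delta_h)
        diffs = np.diff(hs)
        assert np.all(diffs <= 0) or np.all(diffs >= 0)

    def test_full_agonist_broadens_out_m90(self, models):
        st = ReceptorStateSpec(state_kind="ligand", ligand="isoprenaline")
        peaks = {p.label: p for p in generate_state_peaks(models, st)}
        assert peaks["M90a"].broadening_flag == "broadened_out"
        # but the reporter survives with a weak partial agonist
        st2 = ReceptorStateSpec(state_kind="ligand", ligand="cyanopindolol")
        peaks2 = {p.label: p for p in generate_state_peaks(models, st2)}
        assert peaks2["M90a"].broadening_flag == "detectable"

    def test_volume_consistent_with_height_and_linewidths(self, models):
        st = ReceptorStateSpec(state_kind="apo")
        for p in generate_state_peaks(models, st):
            expect = p.height * (np.pi**2 / 4) * p.fwhm_h * p.fwhm_c
            assert p.volume == pytest.approx(expect, rel=1e-9)

    def test_cooling_sharpens_exchange_broadened_peaks(self, models):
        warm = ReceptorStateSpec(state_kind="ligand", ligand="isoprenaline")
        cool = ReceptorStateSpec(state_kind="ligand", ligand="isoprenaline",
                                 temperature=298.0)
        pw = {p.label: p for p in generate_state_peaks(models, warm)}
        pc = {p.label: p for p in generate_state_peaks(models, cool)}
        assert pc["M223"].fwhm_c < pw["M223"].fwhm_c


class TestRenderSpectrum:
    def test_empty_scene_renders_zero(self, models, axes):
        scene = make_scene(models, ReceptorStateSpec(state_kind="apo"),
                           axes=axes, noise_sigma=0.0, seed=0)
        scene = scene.__class__(state=scene.state, peaks=(), axes=axes,
                                noise_sigma=0.0, seed=0)
        spec, fid = render_spectrum(scene)
        assert np.all(spec.intensity == 0)
        assert np.all(fid.data == 0)

    def test_single_peak_argmax_and_height(self, models, axes):
        scene = make_scene(models, ReceptorStateSpec(state_kind="apo"),
                           axes=axes, noise_sigma=0.0, seed=0)
        pk = next(p for p in scene.peaks if p.label == "M153")
        scene = scene.__class__(state=scene.state, peaks=(pk,), axes=axes,
                                noise_sigma=0.0, seed=0)
        spec, _ = render_spectrum(scene)
        i, j = np.unravel_index(spec.intensity.argmax(), spec.intensity.shape)
        step_h = np.mean(np.diff(spec.ppm_direct))
        step_c = np.mean(np.diff(spec.ppm_indirect))
        assert abs(spec.ppm_direct[i] - pk.delta_h) <= step_h
        assert abs(spec.ppm_indirect[j] - pk.delta_c) <= step_c
        assert spec.intensity[i, j] == pytest.approx(pk.height, rel=0.02)

    def test_noise_floor_matches_sigma(self, models, axes):
        scene = make_scene(models, ReceptorStateSpec(state_kind="apo"),
                           axes=axes, noise_sigma=2.5, seed=42)
        spec, _ = render_spectrum(scene)
        corner = spec.intensity[-160:, :40]  # signal-free region
        assert np.std(corner) == pytest.approx(2.5, rel=0.15)

    def test_determinism_byte_identical(self, models, axes):
        st = ReceptorStateSpec(state_kind="ligand", ligand="salbutamol")
        s1 = make_scene(models, st, axes=axes, noise_sigma=1.0, seed=9)
        s2 = make_scene(models, st, axes=axes, noise_sigma=1.0, seed=9)
        a, _ = render_spectrum(s1)
        b, _ = render_spectrum(s2)
        assert a.intensity.tobytes() == b.intensity.tobytes()
        s3 = make_scene(models, st, axes=axes, noise_sigma=1.0, seed=10)
        c, _ = render_spectrum(s3)
        assert a.intensity.tobytes() != c.intensity.tobytes()


class TestTitration:
    def test_zero_titrant_gives_zero_bound(self):
        s = generate_titration(BindingModel(8.0), 100.0,
                               titrant_totals=[0.0, 50.0, 200.0])
        assert s.volumes_bound[0] == 0.0

    def test_huge_excess_saturates(self):
        s = generate_titration(BindingModel(8.0), 1.0,
                               titrant_totals=[8.0e4])
        frac = s.volumes_bound[0] / (s.volumes_bound[0] + s.volumes_free[0])
        assert frac > 0.999

    def test_quadratic_solution_example(self):
        # oracle: numeric root of B^2 - B(R+L+Kd) + RL = 0
        s = generate_titration(BindingModel(8.0), 100.0, titrant_totals=[1500.0])
        frac = s.volumes_bound[0] / (s.volumes_bound[0] + s.volumes_free[0])
        roots = np.roots([1.0, -(100 + 1500 + 8), 100 * 1500])
        b = min(r.real for r in roots if 0 <= r.real <= 100)
        assert frac == pytest.approx(b / 100.0, rel=1e-12)
        assert frac == pytest.approx(0.994, abs=5e-4)

    def test_volume_conservation_within_noise(self):
        s = generate_titration(BindingModel(8.0), 100.0, noise_sigma=0.02, seed=3)
        tot = s.volumes_free + s.volumes_bound
        assert np.all(np.abs(tot - 1000.0) < 3 * 0.02 * 1000.0 * np.sqrt(2))

    def test_determinism(self):
        a = generate_titration(BindingModel(8.0), 100.0, noise_sigma=0.05, seed=5)
        b = generate_titration(BindingModel(8.0), 100.0, noise_sigma=0.05, seed=5)
        np.testing.assert_array_equal(a.volumes_bound, b.volumes_bound)


class TestEfficacyDataset:
    def test_noiseless_points_satisfy_plane_exactly(self):
        a, b, c = LIGAND_PLANES["M223"]
        df = generate_efficacy_dataset((a, b, c), seed=1)
        resid = df.efficacy - (a * df.delta_h + b * df.delta_c + c)
        assert np.abs(resid).max() < 1e-8

    def test_constant_plane(self):
        df = generate_efficacy_dataset((0.0, 0.0, 50.0), seed=1)
        assert np.all(df.efficacy == 50.0)

    def test_degenerate_spread_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            generate_efficacy_dataset(LIGAND_PLANES["M223"], shift_spread=0.0,
                                      efficacy_range=(50.0, 50.0), seed=0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            generate_efficacy_dataset(LIGAND_PLANES["M223"], n_ligands=2, seed=0)
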