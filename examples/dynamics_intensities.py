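"""Normalized peak intensities as a conformational-dynamics readout.

Renders the full comparison series of receptor states (apo, six ligands of
graded efficacy, nanobody-only, four ternary complexes), quantifies the
M223/M296 reporter heights relative to the M153 reference, and normalizes
each reporter across the series.  Values near 1 mean a rigid receptor;
small values mean strong μs–ms exchange broadening.
"""

from metnmr import (
    fit_peaks,
    normalize_series,
    pick_peaks,
    relative_intensity,
    render_spectrum,
)
from metnmr.peaks import match_peaks_to_labels
from metnmr.synthetic import default_residue_models, dynamics_series_states, make_scene

models = default_residue_models()
records = []
for k, state in enumerate(dynamics_series_states()):
    scene = make_scene(models, state, noise_sigma=1.0, seed=100 + 17 * k)
    spectrum, _ = render_spectrum(scene)
    picked = pick_peaks(spectrum, threshold_sigma=5)
    truth = {p.label: (p.delta_h, p.delta_c) for p in scene.peaks
             if p.broadening_flag == "detectable"}
    match_peaks_to_labels(picked, truth)
    fits = fit_peaks(spectrum, [p for p in picked if p.label != "unassigned"])
    for residue in ("M223", "M296"):
        records.append(relative_intensity(fits, residue, spectrum_id=state.label))
normalize_series(records)

print(f"{'state':<33} {'M223':>7} {'M296':>7}")
by_state = {}
for r in records:
    by_state.setdefault(r.spectrum_id, {})[r.residue] = r.normalized_intensity
for state, vals in by_state.items():
    print(f"{state:<33} {vals['M223']:>7.2f} {vals['M296']:>7.2f}")

print("\nreading: ternary complexes ~1 (rigid, IBP-coupled), nanobody-only")
print("~0.7, apo/partial agonists ~0.5, full agonists ~0.2 (the pre-active")
print("state samples several substates in intermediate exchange).")
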