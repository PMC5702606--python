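"""K_d estimation from slow-exchange titration peak volumes.

When nanobody binding is slow on the NMR timescale, the free and bound
receptor give separate peaks; integrating both across a titration yields
bound fractions that follow the exact 1:1 isotherm.  This example generates
titrations at the two apo-receptor nanobody affinities, with and without
volume noise, and re-estimates K_d with a bootstrap confidence interval.
"""

from metnmr import estimate_kd_from_volumes
from metnmr.binding import BindingModel
from metnmr.synthetic import NANOBODY_KD, generate_titration

print(f"{'nanobody':<8} {'true Kd':>8} {'noise':>6} {'fit Kd':>9} {'95% CI':>19}")
for nanobody, kd in sorted(NANOBODY_KD.items()):
    for noise in (0.0, 0.05):
        series = generate_titration(BindingModel(kd), receptor_total=100.0,
                                    noise_sigma=noise, seed=42)
        est = estimate_kd_from_volumes(series, n_bootstrap=200, seed=1)
        print(f"{nanobody:<8} {kd:>8.1f} {noise:>6.0%} {est.kd:>9.2f} "
              f"[{est.ci_low:>7.2f}, {est.ci_high:>7.2f}]")

print("\nnoiseless fits recover the ground truth exactly; 5% volume noise")
print("moves the estimate by a few percent, bracketed by the bootstrap CI.")
print("These micromolar affinities are orders of magnitude weaker than the")
print("nanomolar binding seen in agonist-bound ternary complexes.")
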