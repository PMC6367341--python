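"""Tri-exponential tail fit of a TCSPC decay and the static-quenching check.

Simulates photon-counting decays for the free and ligand-saturated
protein, fits three exponentials to each, and compares the
amplitude-weighted mean lifetimes: ground-state (static) quenching
leaves the excited-state lifetime unchanged.
"""

from albind import fit_decay, compare_lifetimes
from albind.synthetic import gen_decay, GroundTruth

truth = GroundTruth()
free_hist = gen_decay(truth.lifetime_free, peak_counts=1e4, baseline=20.0, seed=1)
bound_hist = gen_decay(truth.lifetime_bound, peak_counts=1e4, baseline=20.0, seed=2)

fit_free = fit_decay(free_hist, n_components=3, seed=1)
fit_bound = fit_decay(bound_hist, n_components=3, seed=2)

for name, fit in (("free", fit_free), ("bound", fit_bound)):
    comps = ", ".join(f"tau={t:.2f} ns (a={a:.2f})" for t, a in fit.components)
    print(f"{name:>5}: {comps}")
    print(f"       tau_avg = {fit.tau_avg:.3f} +- {fit.tau_avg_stderr:.3f} ns, "
          f"chi2_red = {fit.chi_square_reduced:.2f}")

rel, static_ok = compare_lifetimes(fit_free, fit_bound, tolerance=0.05)
print(f"lifetime change on binding: {rel:+.2%} -> "
      f"{'supports static quenching' if static_ok else 'suggests dynamic quenching'}")
# A change within a few percent (the planted truth is +1.7%) corroborates
# complex formation in the ground state rather than collisional quenching.
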