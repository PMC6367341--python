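# albind

Analysis toolkit for small-molecule binding to serum albumin — the kind of
multi-spectroscopic characterisation used to assess how food dyes, drugs
and other xenobiotics are carried in blood plasma. From routine instrument
exports (fluorescence titrations, TCSPC decay histograms, CD spectra,
site-marker competition curves, PDB coordinates) it computes:

* **Quenching analysis** — inner-filter correction
  (F_corr = F_obs·e^((A_ex+A_em)/2)), Stern–Volmer fit
  (F₀/F = 1 + K_SV[Q]), double-log binding fit
  (log₁₀((F₀−F)/F) = log₁₀K_a + n·log₁₀[Q]), static/dynamic mechanism
  classification and affinity binning.
* **Thermodynamics** — ΔG = −RT·lnK_a, van't Hoff regression of lnK_a on
  1/T for ΔH and ΔS, and the driving-force sign rules.
* **Lifetimes** — multi-exponential TCSPC tail fitting with Poisson
  weights, F-test model selection, amplitude-weighted τ_avg = Σαᵢτᵢ, and
  the lifetime-invariance check that corroborates static quenching.
* **Site competition** — displacement ratios I = F/F₀ per probe, curve
  shapes, and assignment of the binding site (Sudlow I/II, heme cleft).
* **Conformation** — mean residue ellipticity
  MRE = θ/(10·C_p·n_res·l), α-helix % = (−MRE₂₀₈−4000)/29000·100, and
  synchronous-fluorescence peak-shift detection.
* **Structure metrics** — PDB parsing (via biotite), Kabsch superposition,
  heavy-atom RMSD and mass-weighted radius of gyration with automatic
  plateau statistics, and distance-based hydrogen-bond candidate contacts.
* **Synthetic data** — seeded generators for every input with known ground
  truth, each an exact inverse of its analysis stage in the noiseless
  limit.

## Worked example

```python
from albind import fit_stern_volmer, fit_double_log, vant_hoff_fit
from albind.synthetic import gen_titration

series = gen_titration(K=1.14e5, n=1.0, temperature=298.0,
                       ife_coeffs=(3e4, 2e4), noise_cv=0.005, seed=1)
sv = fit_stern_volmer(series.correct_inner_filter())
binding = fit_double_log(series.correct_inner_filter())
print(sv.K_SV, binding.K_a, binding.n)

res = vant_hoff_fit([(298.0, 1.14e5), (304.0, 1.03e5), (310.0, 0.85e5)])
print(res.delta_H, res.delta_S, res.force_label)
```

Running `python examples/quenching_titration.py` and
`python examples/thermodynamics.py` prints:

```
K_SV uncorrected : 1.636e+05 L/mol  (inner-filter bias)
K_SV corrected   : 1.147e+05 +- 1.3e+03 L/mol (R^2 = 0.9993)
K_a              : 1.475e+05 L/mol, n = 1.021
affinity class   : moderate

dH = -18.75 +- 3.56 kJ/mol
dS = +34.03 +- 11.72 J/mol/K
dG(298 K) = -28.85 kJ/mol (spontaneous)
dG(304 K) = -29.17 kJ/mol (spontaneous)
dG(310 K) = -29.25 kJ/mol (spontaneous)
dominant force: electrostatic
```

The corrected Stern–Volmer slope recovers the planted 1.14×10⁵ L/mol
association constant (the uncorrected one is inflated by the inner-filter
attenuation); a Hill coefficient of ~1 means a single binding site of
moderate affinity. Negative ΔH with positive ΔS is the electrostatic
signature, and negative ΔG at every temperature means binding is
spontaneous. The `examples/` directory has one script per capability
(lifetimes, competition, CD, trajectory metrics) in the same style.

There is also a thin CLI, one subcommand per stage:

```sh
albind simulate --outdir inputs --seed 1
albind report --indir inputs --out report.json
albind quench inputs/titration.csv
```

## Layout

```
src/albind/        library (quenching, thermo, lifetime, competition,
                   conformation, structure, synthetic, io, cli)
examples/          one narrative script per capability
tests/             pytest suite (unit, property and end-to-end checks)
scripts/           acceptance script
docs/methods.md    models, defaults, numerical choices, limitations
```
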