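# Methods

`albind` analyses the binding of a small-molecule ligand (prototypically an
azo food dye) to serum albumin from spectroscopic and structural data. This
note documents the models, the defaults and the numerical choices, and what
the synthetic-data generators do and do not emulate.

## Fluorescence quenching

Intensities are first corrected for the inner-filter effect,
F_corr = F_obs·exp((A_ex + A_em)/2), where A_ex and A_em are the sample
absorbances at the excitation and emission wavelengths. The correction is
multiplicative, so it commutes with intensity scaling and is a no-op at zero
absorbance. Protein concentrations follow Beer–Lambert, c = A/(ε·l), with
ε = 36 850 L·mol⁻¹·cm⁻¹ for albumin at 280 nm.

Two linear stages are fitted on the corrected intensities:

* **Stern–Volmer**: F₀/F = 1 + K_SV·[Q]. The slope is the quenching
  constant; the intercept is left free and reported (a value far from 1
  flags a bad reference intensity).
* **Double-logarithm**: log₁₀((F₀−F)/F) = log₁₀K_a + n·log₁₀[Q], giving the
  association constant from the intercept and the Hill coefficient from the
  slope. "log" is taken as base 10, the convention in this literature; the
  slope is base-invariant and the intercept conversion is explicit.

Both regressions are unweighted OLS on the transformed variables, matching
the linear-regression procedure such studies report. The [Q] = 0 point is
excluded (log undefined; the ratio is 1 by construction), and points with
F ≥ F₀ at [Q] > 0 are dropped with a warning rather than aborting — they are
noise at low quencher, not information.

**Standard errors.** The transforms make the noise strongly heteroscedastic:
a fixed relative intensity error is amplified by F₀/(F₀−F), so low-quencher
points are several times noisier in log space than high-quencher points.
Classical homoscedastic OLS standard errors undercover in Monte Carlo;
the package therefore reports heteroscedasticity-consistent (HC3) standard
errors, the standard small-sample robust estimator. Point estimates are
plain OLS either way. Because K_a is exponentiated from the intercept — a
long extrapolation from data centred near log₁₀[Q] ≈ −5.5 — its sampling
distribution is log-normal with substantial spread; recovery is assessed on
the geometric mean, and the reported linear-space standard error is a
delta-method approximation.

**Mechanism classification.** Static (ground-state complex) quenching is
declared when K_SV strictly decreases with temperature and, if lifetime
evidence exists, the amplitude-weighted lifetime changes by less than the
tolerance (default 5%; the observed change in the motivating system is
+1.7%). Dynamic quenching requires K_SV increasing with temperature *and* a
lifetime shortening beyond tolerance. Anything else is inconclusive — a
single temperature with no lifetime data is not an error. Binding strength
is binned at the conventional decades: weak below 10³ L/mol, moderate in
10³–10⁶, strong above.

## Thermodynamics

ΔG = −RT·lnK_a (R = 8.314 J·mol⁻¹·K⁻¹; ΔG reported in kJ/mol — the 10³
factor is applied exactly once and unit discipline is pinned by a test).
ΔH and ΔS come from an unweighted OLS of lnK_a on 1/T: ΔH = −R·slope,
ΔS = R·intercept. Natural log is used internally (thermodynamically exact);
ΔS is taken from the intercept rather than (ΔH−ΔG)/T at one temperature so
there is a single authoritative estimate, and an internal-consistency check
verifies ΔH − T·ΔS ≈ −RT·lnK_a(fit) at every input temperature. Printed
K_a uncertainties are not propagated into the fit (matching the apparent
published procedure). Duplicate temperatures collapse to their mean lnK_a
with a warning. The driving-force label follows the Ross–Subramanian sign
rules: ΔH<0, ΔS>0 → electrostatic; ΔH<0, ΔS<0 → hydrogen bond / van der
Waals; ΔH>0, ΔS>0 → hydrophobic; otherwise mixed.

## Fluorescence lifetimes (TCSPC)

Decay histograms are tail-fitted — no instrument-response deconvolution —
with counts(t) = b + Σᵢ Aᵢ·exp(−t/τᵢ), 1–4 components, by Levenberg–
Marquardt with an analytic Jacobian and Neyman weights 1/max(counts, 1)
(zero-count channels retained). The fit window defaults to two channels
past the histogram peak. Amplitudes are referenced to t = 0 and normalised
to fractions αᵢ summing to 1; the mean lifetime is the amplitude-weighted
τ_avg = Σαᵢτᵢ, *not* the intensity-weighted Σαᵢτᵢ²/Σαᵢτᵢ. Components are
sorted by ascending τ to break the label symmetry.

Numerical choices worth knowing:

* Initial lifetimes are log-spaced across the window span; up to 5 jittered
  restarts run only if the first start fails. Convergence tolerances are
  ftol = xtol = 10⁻⁶ — tight enough for machine-precision recovery on
  noiseless data, while terminating the slow creep along the
  near-degenerate valley that closely spaced multi-exponential mixtures
  produce under Poisson noise.
* The baseline (dark counts) starts strictly inside its non-negativity
  bound: the bounded-parameter transform has zero gradient exactly at the
  boundary and would freeze the optimiser.
* The standard error of τ_avg is a delta-method propagation through the
  pseudo-inverse of JᵀJ at the solution, scaled by reduced χ². The
  pseudo-inverse handles collapsed components (Aᵢ → 0), whose lifetime
  τ_avg provably does not depend on.
* Neyman weighting carries the textbook low-count bias (downward-
  fluctuating channels get too much weight); with a realistic dark-count
  floor the bias is small relative to the τ_avg standard error.

Model order is chosen by nested F-tests at α = 0.05 on the weighted sum of
squares: the smallest model that the next-larger model fails to improve
significantly. Fitting a decaying model to a flat (no-decay) histogram is
diagnosed rather than hidden: the fit either fails or returns an
unphysically long lifetime / inflated χ², which callers should treat as a
degenerate-input flag.

Static quenching is corroborated when |τ_bound − τ_free|/τ_free is below
the tolerance (default 5%).

## Site-marker competition

Displacement is measured as I = F/F₀ at probe:ligand molar ratios 0.5–3.0.
For each probe the package reports the OLS slope of I vs ratio, the total
drop 1 − I(final), a monotonicity flag (pairwise, 1% tolerance), and a
step-then-flat flag: ≥80% of the total drop occurring at the first probe
addition with the remainder essentially flat — the cooperative-binding
signature, excluded from site assignment but still reported. The probe→site
map (warfarin → site I, ibuprofen → site II, dansyl-L-arginine → site I/FA7,
dansyl-L-sarcosine → site III/FA1) is data, not code, and extensible.

Published analyses of such curves are qualitative; the package fixes
quantitative defaults — minimum drop 10%, margin over the best other-site
probe 5 percentage points — both configurable. Below either threshold the
verdict is "ambiguous", never a guess.

## CD helicity and synchronous fluorescence

Mean residue ellipticity is MRE = θ/(10·C_p·n_res·l) with θ in mdeg, C_p
molar, l in cm (for 2 µM, 585 residues, 1 cm the denominator is 0.0117 —
pinned by a test against the hand-computed value, because the ×10 slip is
the classic error here). Helix content uses only the 208 nm point,

α-helix (%) = (−MRE₂₀₈ − 4000)/(33000 − 4000) × 100,

interpolating between the random-coil (−4000) and pure-helix (−33000)
references; no basis-set deconvolution is attempted (out of scope by
design). Values outside [0, 100] are returned unclipped with a warning —
they diagnose inconsistent inputs. The 208 nm readout takes the nearest
grid point with no smoothing by default. Synchronous-fluorescence peak
shifts are located by 3-point quadratic interpolation around the maximum
bin, so sub-grid shifts (the blue shift of interest is ~1–2 nm) are
resolved on coarse grids; the blue/red threshold is ±0.5 nm.

## Structure metrics

PDB parsing is delegated to biotite (first altloc kept, elements from
columns 77–78 with an atom-name fallback, optional water stripping;
malformed coordinate lines are skipped with a warning). Superposition is
the Kabsch SVD algorithm with the determinant correction, so reflections
are impossible; collinear or <3-atom sets are rejected as underdetermined.
Tests cross-check the resulting RMSD against an independent quaternion
search oracle to 10⁻³ Å.

Trajectory analysis superposes each frame on the reference over the
selection (default: heavy atoms — hydrogens excluded unless selected)
before computing RMSD; Rg is mass-weighted by default with an unweighted
option, since verbal definitions in the literature are ambiguous. The
RMSD plateau is detected reproducibly rather than by eye: sliding window
of 10% of the trajectory length, plateau start at the earliest frame after
which every window-to-window relative change stays below 2%. The detector
is deliberately conservative (it can start late, never early), which
leaves plateau means unbiased. A user-fixed window overrides it.

Polar contacts use a distance-only criterion: heavy-atom pairs within the
cutoff (default 3.5 Å) with both atoms N/O/S are hydrogen-bond candidates,
one polar atom gives "polar_contact", none "nonpolar". No angle term is
applied because only donor–acceptor distances are being reproduced; angle
filtering would require hydrogen positions docking outputs often lack.

## Synthetic data: what it emulates, and what it does not

Every generator is the exact right inverse of its analysis stage in the
noiseless limit, so parameter recovery can be asserted to machine
precision. Defaults are the study conditions of a moderate-affinity
dye–albumin system: 0–6 µM ligand titrations at 298/304/310 K with
K_SV ≈ 1.26×10⁵ and K_a ≈ 1.14×10⁵ L/mol, tri-exponential decays with
τ_avg ≈ 5.59 ns (free) and 5.68 ns (bound), helix contents
52.08/49.25/47.69% across molar ratios, a planted site-I displacement
panel, and trajectories plateauing near RMSD 3.4 Å / Rg 27.6 Å. All
randomness flows through one seeded `numpy.random.Generator`; no global
state.

Emulated noise: multiplicative Gaussian intensity noise (the reference
intensity is kept exact), Poisson photon counting with an optional
dark-count baseline, additive mdeg noise on CD, additive noise on
displacement ratios, isotropic coordinate perturbation with a linear ramp
(40% of the run) then hold. The trajectory generator compensates for the
~7 degrees of freedom superposition absorbs and for the Rg inflation the
noise causes, so planted plateau values are centred.

Not emulated — so passing tests do not speak to: instrument response
functions and scattering in TCSPC, wavelength-dependent CD noise and
smoothing, probe depletion and secondary-site binding in competition,
correlated (non-isotropic) protein motions, and any force-field
energetics. Docking energies and real MD plateau values require the
simulation engines themselves and are out of scope; the trajectory
analogue only shows the *metrics* are computed correctly.

A dynamic-quenching generator (K_SV rising with temperature) exists solely
to exercise the classifier's "dynamic" branch; the static generator is the
default because that is the regime the defaults describe.

## Problem sizes used in the test suite

Monte Carlo checks use 200 seeds for the linear-fit recoveries (K_SV, K_a,
n, ΔH, ΔS), 100 Poisson seeds for τ_avg confidence coverage, 50 seeds for
decay model selection, and 100 panels for site assignment; decay
histograms are 1024 channels at 50 ps. These sizes give binomial
uncertainty of a few percent on coverage rates while the full suite runs
in well under five minutes on one CPU.

## Known limitations

* The double-log K_a is an extrapolated intercept; at realistic noise its
  linear-space mean is Jensen-inflated. Compare geometric means or work in
  log space.
* Nested F-tests on weighted least squares are approximate for Poisson
  data; at very low counts model selection will favour fewer components.
* The plateau detector assumes the series actually plateaus; monotone
  drifting trajectories yield a late plateau start and a drifting "mean".
* Sphere-of-action (combined static+dynamic) quenching, dual-site binding
  models, IRF reconvolution, and competitive K_a re-estimation from
  displacement are deliberately not implemented.
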