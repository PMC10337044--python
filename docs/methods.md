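# Methods

This note documents the models implemented in `azocyd`, the numerical
choices behind them, what the synthetic-data generators emulate, and the
limits of what the test suite demonstrates.

## Equilibrium speciation

All solvers work in mol/L and return every species concentration together
with the echoed totals, so mass balance and the equilibrium quotient can
be checked directly on the result.

- **1:1 inclusion.** [HG] is the smaller root of the binding quadratic,
  evaluated in the rationalized form 2K·H_T·G_T/(b + √(b²−4K²H_TG_T))
  with b = K(H_T+G_T)+1, which avoids catastrophic cancellation at weak
  binding. K = 0 and zero totals are exact special cases.
- **Homodimerization.** [M] = 2C_T/(1+√(1+8K_dC_T)); [D] is computed as
  K_d[M]² rather than (C_T−[M])/2 because the subtraction loses relative
  precision when the dimer fraction is small.
- **Competition** (two guests, one host) reduces to one monotone scalar
  equation in free host, bracketed on [0, H_T] and solved with Brent's
  method at machine-precision tolerances. **Homodimer + heterodimer**
  reduces likewise to one equation in free monomer after eliminating free
  host analytically. Both are verified in the tests against independent
  root-finders in different parameterizations (bisection on the
  mass-action form; a high-precision multiprecision root polish).

## Titration and dilution fitting

Fits are unweighted nonlinear least squares (optional user weights) on
the exact-speciation signal model, via Levenberg–Marquardt (lmfit), with
standard errors from the Jacobian-based covariance at the optimum.
Initialization is deterministic: K is seeded by a coarse log-grid scan
over 1–10⁶ M⁻¹ in which the signal end-members are profiled out by linear
least squares (variable projection), so no random restarts are needed and
identical inputs give identical fits.

For induced-CD ellipticity the free guest carries no signal (none is
observed without host), so `s_free` is fixed at 0 by default for that
signal kind and floats for fast-exchange NMR shifts. The
Benesi–Hildebrand double-reciprocal route (K = intercept/slope of
1/signal vs 1/[H]_T) is deliberately exposed only as a cross-check: it
assumes free host ≈ total host and re-weights errors by 1/signal², so it
is biased on realistic data. The noiseless equivalence test against the
nonlinear route therefore runs at >1000-fold host excess, where the
approximation error drops below 0.1%.

Identifiability warnings: a flat signal series, a titration whose plateau
is unreachable (se(K) exceeding K), and a dilution series spanning less
than a factor of 10 in concentration all emit warnings rather than
silently returning a number.

The dilution model fits one resonance at a time (δ_M, δ_D per peak);
multiple peaks are fitted separately and reported together.

## Kinetics, PSS, fatigue, van't Hoff

Thermal relaxation is fitted as a single exponential in natural intensity
space (additive-noise assumption; a log-linear estimate both seeds the
rate and serves as a cross-check helper). τ½ = ln2/k is exposed as a
derived property so the identity holds exactly. A trace observed for less
than ~0.2/k triggers a weak-identifiability warning.

Photostationary composition is the normalization of nonnegative NMR
integrals. Fatigue is summarized by the geometric-mean per-cycle
retention (a_n/a_1)^(1/(n−1)) plus the regression slope of log amplitude
on cycle index with its standard error.

Van't Hoff analysis is ordinary least squares of ln K on 1/T with
ΔH° = −R·slope (kJ/mol) and ΔS° = R·intercept (J/(K·mol)), R = 8.314
J/(K·mol); uncertainties propagate directly from the regression. At least
three temperatures are required (two points determine the line with no
residual degrees of freedom). Temperatures are converted from °C at the
boundary (T + 273.15).

## Spectra

Spectra live on a strictly increasing nm grid; families must share one
grid (a linear-interpolation resampler is provided for callers).
Beer–Lambert regression keeps a free intercept: baseline offsets are
common, and forcing the origin would hide them.

Isosbestic points are wavelengths where the across-spectra standard
deviation has a local minimum below a user tolerance. The tolerance
should be commensurate with the grid: a crossing falling between grid
points leaves a residual deviation of roughly (local slope × grid step/2)
at the nearest grid point. Wavelengths where the family itself is silent
(mean |signal| below `min_signal`, default the tolerance) are excluded —
a crossing of zero signal is not an isosbestic point. Nearby candidates
merge to the lowest-deviation one.

Exciton-couplet amplitude uses peak heights (the sum of the positive and
negative branch magnitudes), which is how bisignate couplet intensities
are conventionally quoted; an integrated-area variant sits behind
`use_areas=True` for users who prefer lobe areas. The zero crossing
between the branches is located by linear interpolation. Band maxima
break ties to the leftmost wavelength, with a warning.

## Geometry and ICD sign prediction

The macroring "main axis" is defined operationally as the
smallest-variance singular direction (best-fit-plane normal) of the
glycosidic-oxygen selection, with the sign optionally oriented toward a
declared secondary-rim point. Dipole–axis angles are folded to [0, 90]°
(the sense of a transition moment is not observable), so the angle
statistics over a trajectory use a plain arithmetic mean and sample
standard deviation (ddof = 1; a single frame reports sd 0).

The sign rule returns sign((3cos²θ−1)/2) for an included chromophore and
its negation outside the cavity. The null band around the magic angle is
|weight| < 1e-6, wide enough that inputs quoted to four decimal places
(54.7356°) classify as null while anything a tenth of a degree away does
not. The inside/outside call uses a closed cylindrical boundary (rim
planes and radial wall count as inside) with configurable extents,
because the physical criterion — "partially outside" — has no sharp
definition; the boundary is a modeling choice the caller can move.

Torsions follow the IUPAC clockwise-positive convention on (−180, 180].

The approach scan places a rigid mobile body at each (displacement,
dihedral) pose on an inclusive-endpoint grid (e.g. 2.5 → −2.5 nm at
0.05 nm gives 101 poses; 2.5 → −0.2 nm, 55; 4.0 → 0.5 nm, 71) and scores
it with a coarse-grained pairwise energy: Lennard-Jones with
Lorentz–Berthelot combination plus Coulomb with k_e = 33.206
(kcal/mol)·nm/e² and a uniform dielectric, truncated at a cutoff. Units
are generic kcal/mol-like; the score is meant for profile shapes,
minimum-binding-energy (MBE) selection and sign-rule inputs, not for
reproducing calibrated force-field magnitudes. MBE ties break toward the
larger axial separation to avoid clash-adjacent poses.

## Synthetic data

Generators are deterministic functions of (parameters, seed) and attach
their ground truth to the returned object (and to a YAML sidecar when
written to disk). Noise is additive homoscedastic Gaussian — adequate for
detector-limited CD/UV/NMR intensities, but it does not emulate baseline
drift, wavelength-correlated noise, lineshape effects or aggregation
artifacts, so recovery tests demonstrate estimator correctness under the
stated noise model, not robustness to real-instrument systematics.

Default designs mirror the experimental protocols: ICD titration with
0.094 mM guest and 12 host points from 0 to 16.6 mM; two-fold NMR
dilution ladder from 20 mM to 0.078 mM (9 points); decay traces spanning
~3/k; two-state Gaussian-band spectral families whose component
crossings (the designed isosbestic points) are recorded as truth; a
heptagonal oxygen ring (radius 0.5 nm) with a rod chromophore at a
declared tilt and penetration.

At the 12-point titration design with 2% noise the sampling sd of the
fitted K is intrinsically ~10% (the fit is unbiased and its reported se
matches the sampling sd); recovery assertions at that design therefore
use the fitted-se scale, while the estimator-quality property test
(median error ≤ 5%, ~95% CI coverage over 100 seeds) uses a log-spaced
24-point design spanning 1/K, where the design supports that precision.

## Problem sizes

Deterministic recomputations (speciation, van't Hoff, magic angle) are
closed-form or 4-point regressions. Seeded recoveries use the design
sizes above (8–25 points per fit). Property suites run tens of randomized
solver instances and a 100-replicate titration recovery; the whole test
suite completes in a few seconds on one core.

## Known limitations

- No slow-exchange NMR lineshape analysis, 2:1 stoichiometries, or global
  multiwavelength fitting.
- The linearized (double-reciprocal) route is provided for comparison
  only; its known heteroscedasticity bias is documented, not corrected.
- The coarse-grained energy score has no solvation or conformational
  relaxation; trajectory-average angles of real MD are out of reach by
  construction.
- Spectral analysis assumes a shared wavelength grid and does no
  smoothing, baseline correction or band deconvolution.
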