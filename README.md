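# azocyd

Quantitative analysis toolkit for light-switchable host–guest chemistry of
β-cyclodextrin (βCyD) / azobenzene systems: equilibrium speciation and
binding-isotherm fitting, photoisomerization kinetics and van't Hoff
thermodynamics, spectral-family analysis (isosbestic points, exciton
couplets), and geometry-based induced-circular-dichroism (ICD) sign
prediction with a rigid-body approach-scan protocol.

It is written for supramolecular and photochemistry groups who measure
ICD/UV–vis titrations, NMR dilution series and thermal relaxation traces
on azobenzene–cyclodextrin conjugates and want reproducible, tested fits
rather than one-off spreadsheet analyses.

## Models

**1:1 inclusion** (H + G ⇌ HG, association constant *K* in M⁻¹): the
complex concentration is the physical root of
*K*·x² − (*K*(H_T+G_T)+1)·x + *K*·H_T·G_T = 0, and an observed signal
(ellipticity in mdeg, or fast-exchange chemical shift in ppm) is fitted as

  signal = s_free + (s_complex − s_free) · [HG]/G_T.

A Benesi–Hildebrand double-reciprocal linearization (1/signal vs 1/[H]_T,
*K* = intercept/slope) is provided as a cross-check in the host-excess
regime.

**Homodimerization** (2M ⇌ D, *K*_d = [D]/[M]²): exact monomer
concentration [M] = 2C_T/(1 + √(1+8*K*_d·C_T)); serial-dilution shift
series fit δ_obs = (1−f_d)·δ_M + f_d·δ_D with the molecule-wise dimer
fraction f_d = 2[D]/C_T. Competitive binding and coupled
homodimer + heterodimer systems are solved by bracketed root-finding with
exact mass balance.

**Kinetics and thermodynamics**: thermal Z→E relaxation is first order,
I(t) = I_∞ + (I₀−I_∞)e^(−kt), τ½ = ln2/*k*; temperature series of *K*
yield ΔH° and ΔS° from the linear van't Hoff equation
ln *K* = −ΔH°/(RT) + ΔS°/R.

**ICD sign rules** (Kodaka): for a chromophore inside the cavity, a
transition dipole parallel to the macroring axis gives a positive ICD
band, perpendicular gives negative, with null at the magic angle
arccos(1/√3) = 54.74°; all signs invert outside the cavity. The magnitude
weight is the second Legendre polynomial (3cos²θ−1)/2. The macroring axis
is the best-fit-plane normal of the seven glycosidic oxygens; rigid-body
approach scans over (axial displacement × dihedral) pose grids are scored
with a coarse-grained Lennard-Jones + Coulomb pair energy to locate the
minimum-binding-energy (MBE) pose.

## Worked example

```python
from azocyd.equilibria import bound_fraction, fit_titration_1to1
from azocyd.kinetics import vant_hoff
from azocyd.synth import gen_titration
from azocyd import refdata

# fraction of E-isomer guest bound at 8.31 mM host, 0.094 mM guest, K = 1450
f_E = bound_fraction(8.31e-3, 9.4e-5, 1450.0)
print(f"bound fraction (E, 25 C): {f_E:.2f}")

# van't Hoff regression over the reported E-isomer constants (5-35 C)
res = vant_hoff(refdata.k_icd_table("E"))
print(f"dH = {res.dH:.1f} +/- {res.se_dH:.1f} kJ/mol")
print(f"dS = {res.dS:.1f} +/- {res.se_dS:.1f} J/(K mol)")

# fit a noisy synthetic ICD titration generated at K = 1450 M^-1
series = gen_titration(K=1450.0, s_complex=10.0, sigma=0.2, seed=7)
fit = fit_titration_1to1(series)
print(f"K = {fit.params['K']:.0f} +/- {fit.stderr['K']:.0f} M^-1")
print(f"plateau ellipticity = {fit.params['s_complex']:.2f} mdeg")
```

prints

```
bound fraction (E, 25 C): 0.92
dH = -11.0 +/- 4.2 kJ/mol
dS = 22.5 +/- 14.2 J/(K mol)
K = 1418 +/- 97 M^-1
plateau ellipticity = 10.00 mdeg
```

0.92 is the complexed fraction of the photoswitch in its E form under
competition-experiment conditions; the negative ΔH° with positive ΔS°
marks an enthalpy-driven association that is also entropically favorable;
and the titration fit recovers the generating constant (1450 M⁻¹) within
one standard error from 2%-noise data.

A command-line interface mirrors the library
(`azocyd fit-titration|fit-dilution|fit-decay|vanthoff|pss|fatigue|
icd-sign|scan|spectra|simulate`); every command writes a deterministic
JSON report.

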