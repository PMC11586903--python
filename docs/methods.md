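# Methods

## Scope and data model

`esptools` analyzes the photophysics of fluorophores whose acid–base
chemistry changes upon excitation. All spectral energies are handled in
wavenumbers (cm⁻¹); spectra enter as two-column tables in nm and are
converted internally (ν̃ = 10⁷/λ). A `Spectrum` requires a strictly
monotone axis of ≥ 3 points; absorbance and emission traces are typed so
that operations valid only for one kind (the λ² correction) can refuse the
other.

## λ² emission correction

An emission spectrum recorded per unit wavelength must be multiplied by λ²
when replotted per unit wavenumber (|dλ/dν̃| ∝ λ²). The correction returns
the unnormalized I(λ)·λ² on an ascending cm⁻¹ axis; since the package uses
the corrected spectrum only to locate band maxima and form band integrals
(which are conserved up to the fixed 10⁷ Jacobian factor), no normalization
convention is imposed. Band maxima are located by fitting a parabola
through the three samples bracketing the discrete maximum (ties broken
toward the lower index); a maximum on the grid boundary returns the
boundary value with a warning. On ≤ 1 nm grids this gives maxima well
within 0.05 nm of the dense-grid argmax for single-band spectra.

## Speciation and global titration fitting

The protonation ladder `B + j H⁺ ⇌ BH_j` with stepwise constants
pKa₁ ≥ pKa₂ ≥ … gives fractional populations

    f_j(pH) = β_j 10^(−j·pH) / Σ_m β_m 10^(−m·pH),   β_j = 10^(Σ_{i≤j} pKa_i)

evaluated in log₁₀ space for stability. Proton activity is taken as
10^(−pH) with no activity-coefficient correction, appropriate for
titrations at fixed ionic strength reporting concentration-scale p[H];
dilution correction is assumed applied upstream.

The titration matrix obeys Beer–Lambert bilinearity, so the global fit is a
separable least-squares problem (variable projection): for a trial pKa
vector the component spectra solve a linear problem exactly, and only the
pKa values are optimized nonlinearly — bounded Brent for one step,
Nelder–Mead (with descending-sort symmetrization) for ladders. Default pKa
bounds are the sampled pH window; an optimum within 0.1% of a bound raises
an "unidentifiable" error rather than returning a boundary estimate, and a
response matrix whose second singular value is < 1e-10 of the first (no
spectral change) raises a singularity error before fitting. The linear
subproblem is unconstrained by default; non-negative component spectra
(NNLS) are available by flag since molar absorptivities are physically
non-negative.

The pKa standard error comes from the curvature of the profiled objective:
var(pKa) = 2σ̂²/(d²SSE/dpKa²) with σ̂² = SSE/(N − p), p counting the pKa and
all linear coefficients; a pH-resampling bootstrap is available as an
option. Emission titrations are fitted with the same bilinear model, which
is valid only when excitation is at an isosbestic point (species-independent
absorbed flux); the fit refuses emission input unless the caller asserts
isosbestic excitation.

The number of absorbing species is estimated factor-analytically: singular
values of the raw response matrix above `threshold × s_max` (default 0.1).
This diagnostic is meaningful for structured matrices; for pure noise the
singular spectrum of an i.i.d. matrix is nearly flat and the count
approaches min(n_pH, n_λ), so the estimate should always be read next to
the fit residuals.

## Förster cycle

    pKa* = pKa + [hc/(kT ln10)] · (ν̃_B − ν̃_BH)

with CODATA constants (hc/k = 1.43877 cm·K; the prefactor is 2.0966e-3 cm
at 298 K, the default temperature). The 0–0 energy of each protonation
state is approximated as the mean of its absorption and λ²-corrected
emission maxima, and may be supplied directly or computed from spectra. The
cycle assumes equal protonation entropy in both electronic states; this
assumption is documented, not toggled. The result is quasi-thermodynamic —
it states the driving force, not the rate, of excited-state proton
transfer.

## Lippert–Mataga analysis

Stokes shifts (absorption maximum minus λ²-corrected emission maximum, both
cm⁻¹) are regressed by OLS on the orientation polarizability
Δf = (ε_r−1)/(2ε_r+1) − (n²−1)/(2n²+1). The dipole-moment change follows in
Gaussian units, Δμ = sqrt(slope·hc·a₀³/2) with hc = 1.98645e-16 erg·cm and
a₀ in cm, reported in Debye; the slope standard error propagates by the
delta method, se(Δμ) = Δμ·se(slope)/(2·slope). A unit-sanity test pins the
CGS route against two independent slope/radius pairs. The Onsager radius is
a required user input: deriving it needs a molecular volume from quantum
chemistry, which is outside this package's scope. A bundled table ships
ε_r and n at 20–25 °C (CRC Handbook, 95th ed., sodium D line) for ten
common solvents; user tables override it. Requirements: ≥ 3 solvents with
non-degenerate Δf. Specific hydrogen-bonding effects (Kamlet–Taft α/β) are
not modeled; strongly protic solvents can deviate from the dielectric
continuum line.

## Lifetime fitting and rates

TCSPC histograms are fitted with A·exp(−t/τ) + B by weighted least squares
(lmfit). Weights start from the Neyman choice 1/max(count, 1) and are
refined once using model-based variances max(model, 1): with pure
observed-count weights, sparse tail bins (0–1 counts) misstate the Poisson
variance and bias τ low by ~1% at 10⁵ counts; one reweighting pass removes
the bias (Monte-Carlo bias ≈ 0.001% over 200 replicates) while keeping the
reduced χ² near 1 for a correct model. No instrument-response
deconvolution is performed — lifetimes of interest here (≥ 2.6 ns) are long
against typical IRFs — and the fit window is user-set (tail fitting); a
window opening before the histogram peak warns, ≥ 50 bins and ≥ 10³ counts
are required, and a perfectly noiseless fit reports zero standard error.
A reduced χ² well above 1 (e.g. > 2) flags a non-monoexponential decay.

Rates decompose as k_r = Φ/τ and k_nr = (1−Φ)/τ (so k_r + k_nr = 1/τ
identically); reports present them scaled by 10⁸ s⁻¹ with two decimals.
The ESPT bound is the plain difference k_nr(H₂O) − k_nr(D₂O), clipped at
zero with a "no isotope effect" flag — a lower bound because deuteration
may slow other vibrational deactivation channels too. Relative quantum
yields use the gradient method with a zero-intercept slope of integrated
intensity vs absorbance (absorbances restricted to (0, 0.5] against
inner-filter effects) and the n² refractive-index correction.

## Synthetic data

The generators emulate the statistical structure each fit assumes, not any
specific instrument: Gaussian absorption/emission bands in wavelength
(defaults 60 / 90 nm FWHM, typical of charge-transfer bands); bilinear
titration matrices with additive Gaussian noise (default σ = 0.002 AU for
absorbance, 1% of peak intensity for emission); solvent series whose
maxima satisfy the Lippert relation exactly, the emission trace being
constructed so that its λ²-corrected form is Gaussian in ν̃ (the generator
defines the corrected-band truth); and Poisson-sampled monoexponential
decays (10⁵ counts over 0–25 ns in 0.05 ns bins by default). All
generators are bit-reproducible given a seed.

Presets encode the study scenarios of the pyridine-acceptor photobase
family around which the package was written: two-species titrations with
band shifts 346→397 nm (pKa 4.49), 345→386 nm (pKa 2.34) and emission
489→581 nm (pKa 4.51); decays at 2.64 / 3.13 ns (H₂O / D₂O); solvent
series for dipole changes of 10.8 D (a₀ = 5.04 Å, 9173 cm⁻¹ slope) and
7.3 D (a₀ = 5.07 Å), over eight solvents spanning ε_r ≈ 2.3–35.9. Band
widths, amplitude ratios, the 4-species ladder's band centers
(335/365/392/418 nm, chosen so all four components are spectroscopically
distinguishable) and the Lippert intercepts (3900 / 3000 cm⁻¹) are
structural stand-ins — the underlying raw band shapes are not published —
so passing tests demonstrate correct recovery under the assumed structure,
not agreement with any instrument record. Real spectra add vibronic
structure, baseline drift, correlated noise and IRF convolution, none of
which are simulated.

## Problem sizes and numerical choices

Monte-Carlo recovery studies use 200 replicates (titrations: 12 pH points ×
251 wavelengths; decays: 10⁵ counts), sizes at which the estimators'
medians sit well inside the tolerances asserted while the full suite runs
in seconds. Scalar pKa optimization uses Brent with xatol 1e-8 inside the
data-window bounds; the multi-step optimizer sorts trial vectors descending
to remove label switching, warning when the raw optimum was non-monotone.
Isosbestic detection scans the relative spread sd/mean on a common
interpolated axis (linear interpolation onto the first spectrum's axis;
extrapolation forbidden), ignores positions where the mean absorbance is
below 1% of its maximum (band wings), and reports the minimum of each
below-tolerance run flanked by above-tolerance spread; identical spectra
are flagged degenerate rather than reported as crossings everywhere.

## Known limitations

Single- and multi-step speciation assume a closed system of interconverting
absorbers with pH-independent component spectra; no activity corrections,
no electrode calibration, no volume tracking. The Förster cycle inherits
the equal-entropy assumption and the ν̃₀₀ averaging convention — systematic
errors of a few hundred cm⁻¹ in ν̃₀₀ translate to a few tenths of a pKa*
unit. The Lippert analysis assumes a spherical point-dipole solute in a
continuum; slopes from hydrogen-bonding solvent sets mix specific effects
into Δμ. Lifetime fitting is monoexponential only (no global multi-λ
analysis, no TRES, no excited-state kinetic schemes).
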