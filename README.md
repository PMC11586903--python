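# esptools

Photophysical characterization of excited-state proton transfer (ESPT)
probes. `esptools` implements the standard desk analyses by which the
ground- and excited-state acid–base chemistry of a push–pull fluorophore
(e.g. a pyridine-acceptor photobase) is quantified from spectrophotometric
and time-resolved data:

* **Speciation / pKa fitting** — global separable (variable-projection)
  least squares of a multiwavelength pH titration,
  `A(pH, λ) = Σ_j f_j(pH; pKa) · c·l · ε_j(λ)`, with Henderson–Hasselbalch
  fractions `f_j`, SVD rank diagnostics and isosbestic-point detection.
* **Förster cycle** — excited-state pKa\* from the ground-state pKa and the
  electronic 0–0 transition energies of the conjugate base/acid pair,
  `pKa* = pKa + [hc/(kT ln10)] (ν̃_B − ν̃_BH)`, with ν̃₀₀ approximated as the
  mean of absorption and λ²-corrected emission maxima.
* **Lippert–Mataga analysis** — Stokes shift vs the solvent polarity
  function `Δf = (ε_r−1)/(2ε_r+1) − (n²−1)/(2n²+1)`; the regression slope
  yields the dipole-moment change upon excitation,
  `μ_e − μ_g = sqrt(slope · hc · a₀³ / 2)` (CGS), for an Onsager cavity
  radius a₀.
* **Lifetime / rate decomposition** — Poisson-weighted monoexponential
  TCSPC fits; `k_r = Φ/τ`, `k_nr = (1−Φ)/τ`; the kinetic solvent isotope
  bound `k_ESPT ≥ k_nr(H₂O) − k_nr(D₂O)`; relative quantum yields by the
  gradient method.
* **Synthetic data** — seeded generators producing titrations, solvent
  series and decay histograms with exactly the statistical structure the
  fits assume, so the whole pipeline is testable offline.

## Worked example

```python
from esptools import ForsterInput, excited_pKa, fit_single_equilibrium
from esptools.synthetic import generate_preset

series, truth = generate_preset("1b-abs", seed=42)   # noisy 12-point titration
fit = fit_single_equilibrium(series)
print(f"pKa = {fit.pKa_estimates[0]:.3f} +/- {fit.pKa_se[0]:.3f}")

res = excited_pKa(ForsterInput(pKa_ground=4.49, nu00_base=24630.0,
                               nu00_acid=21155.0, temperature=298.0))
print(f"pKa* = {res.pKa_excited:.2f}  (delta pKa = {res.delta_pKa:.2f})")
```

prints

```
pKa = 4.490 +/- 0.002
pKa* = 11.78  (delta pKa = 7.29)
```

The titration fit recovers the generating pKa (4.49) from 12 noisy spectra
(σ = 0.002 AU); the Förster cycle then shows the excited chromophore is
~7.3 orders of magnitude more basic than the ground state — the signature
of a strong photobase. The `examples/` directory holds one narrative script
per capability (`forster_cycle.py`, `titration_fit.py`,
`lippert_analysis.py`, `lifetime_and_rates.py`); each prints the quantities
it computes with a note on what they mean. A thin CLI exposes the same
stages (`esptools --help`: `titration-fit`, `forster`, `lippert`,
`lifetime-fit`, `rates`, `espt-bound`, `qy`, `simulate`, `characterize`).

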