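"""Global fit of a multiwavelength pH titration.

Generates a noisy two-species absorbance titration (Gaussian bands at
346/397 nm interconverting with pKa 4.49, sigma = 0.002 AU) and recovers the
protonation constant by separable least squares: at each trial pKa the two
molar component spectra are solved linearly, and only the pKa is optimized.
"""

import numpy as np

from esptools import fit_single_equilibrium, rank_estimate, species_fractions
from esptools.synthetic import generate_preset

series, truth = generate_preset("1b-abs", seed=42)
print(f"{series.pH_values.size} pH points x {series.axis.size} wavelengths, "
      f"true pKa = {truth['pKa'][0]}")
print(f"independent absorbing species (SVD rank): {rank_estimate(series)}")

fit = fit_single_equilibrium(series)
print(f"recovered pKa = {fit.pKa_estimates[0]:.3f} +/- {fit.pKa_se[0]:.3f}")
print(f"residual rms = {fit.residual_rms:.2e} AU")

# species distribution at a few pH values
for ph in (3.5, 4.49, 5.5):
    f = species_fractions(fit.model, ph)
    print(f"pH {ph}: neutral {f[0]:.2f}, protonated {f[1]:.2f}")
# The recovered pKa sits within ~0.01 of the generating value; the residual
# rms matches the injected noise level, confirming a two-species equilibrium.
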