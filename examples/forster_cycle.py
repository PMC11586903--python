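"""Forster-cycle estimate of an excited-state pKa*.

A photobase that absorbs/emits at higher energy in its neutral form than in
its protonated form gains basicity upon excitation. Feeding the ground-state
pKa and the two 0-0 transition energies (each the mean of absorption and
lambda^2-corrected emission maxima) into the Forster cycle quantifies that
gain in pKa units.
"""

from esptools import ForsterInput, excited_pKa, nu00_estimate, nm_to_wavenumber

# 0-0 energies straight from tabulated band maxima (nm -> cm^-1 -> mean)
nu_base = nu00_estimate(nm_to_wavenumber(346.0), nm_to_wavenumber(489.0))
nu_acid = nu00_estimate(nm_to_wavenumber(397.0), nm_to_wavenumber(581.0))
print(f"nu00(base) = {nu_base:.0f} cm-1, nu00(acid) = {nu_acid:.0f} cm-1")

# with the tabulated lambda^2-corrected 0-0 energies and pKa 4.49 at 298 K
res = excited_pKa(ForsterInput(pKa_ground=4.49, nu00_base=24630.0,
                               nu00_acid=21155.0, temperature=298.0))
print(f"pKa* = {res.pKa_excited:.2f}   (delta pKa = {res.delta_pKa:.2f})")
# pKa* ~ 11.8: the excited chromophore is ~7 orders of magnitude more basic
# than in the ground state, the signature of a strong photobase.
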