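"""Fit the D37 (dose leaving 37% of cells surviving UVC) from a
post-UV survival curve.

Survival is modelled single-hit exponential, S(D) = exp(-D/D0); the
log-linear least-squares slope gives D37 = D0. Repair-deficient cells
have D37 well below the 5.5-8.1 J m^-2 of normal cells."""

from xpakit.assays import fit_d37, hcr_relative, uds_percent
from xpakit.simulate import simulate_survival_assay

for planted in (0.7, 1.0, 6.0):
    dr = simulate_survival_assay(planted, noise_sd=0.05, seed=11)
    res = fit_d37(dr)
    print(f"planted D37 {planted:4.1f} J/m2 -> fitted {res.d37:5.2f} "
          f"(r2 {res.r_squared:.3f})")

print()
print(f"UDS 8.2 grains/nucleus vs 100 in normal = "
      f"{uds_percent(8.2, 100.0):.1f}% of normal repair synthesis")
print(f"HCR: UV-damaged reporter at 12 units vs 400 undamaged = "
      f"{hcr_relative(12.0, 400.0):.1f}% reactivation")
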