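"""Band structure and complex dispersion of the water chain.

Inverts the measured band edges (642.8 and 35.8 Trad/s) into force
constants for the H2-O chain, then samples the complex Bloch phase kl:
real in the acoustic and optical bands, pi + i*kappa in the gap where only
evanescent (tunnelling) solutions exist.
"""

import numpy as np

from aquaphonon import band_structure, complex_wavevector, water_cell

cell = water_cell()
bands = band_structure(cell)

print(f"force constants:  K1 = {cell.K1:.1f} N/m (intramolecular), "
      f"K2 = {cell.K2:.2f} N/m (hydrogen-bond)")
print(f"band edges:       acoustic top  omega_r = {bands.omega_r/1e12:6.1f} Trad/s")
print(f"                  optical bottom omega_q = {bands.omega_q/1e12:6.1f} Trad/s")
print(f"                  optical top   omega_p = {bands.omega_p/1e12:6.1f} Trad/s")
print()
print("omega (Trad/s)   Re(kl)/pi   Im(kl)    branch")
for w in np.array([10, 25, 35, 150, 339.3, 600, 643, 650]) * 1e12:
    kv = complex_wavevector(float(w), cell)
    print(f"{w/1e12:10.1f}     {kv.kl_plus.real/np.pi:9.4f}  {kv.kl_plus.imag:8.3f}"
          f"   {kv.branch}")
print()
print("Im(kl) > 0 in the gap is the per-cell decay exponent of a tunnelling")
print("phonon: transmission through N molecules falls off as exp(-2 N Im(kl)).")
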