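"""Estimate generalized Hurst exponents on processes with known scaling.

Builds three reference series — Gaussian white noise, persistent
fractional Gaussian noise, and a binomial multiplicative cascade — and
prints the fitted q=2 exponent and the multifractal spectrum width for
each. White noise and fGn are monofractal (near-zero width, h(2) near
0.5 and 0.8); the cascade is genuinely multifractal and its h(q) has a
closed form to compare against.
"""

import numpy as np

from songfractal import (CascadeSpec, cascade_hq, gen_binomial_cascade,
                         gen_fgn, gen_white_noise, hurst_spectrum)

qs = np.arange(0.5, 5.01, 0.5)

wn = hurst_spectrum(gen_white_noise(8192, seed=1), qs=qs)
print(f"white noise:  h(2) = {wn.h[qs == 2.0][0]:.3f}  width = {wn.width:.3f}")

fgn = hurst_spectrum(gen_fgn(0.8, 8192, seed=1), qs=qs)
print(f"fGn H=0.8:    h(2) = {fgn.h[qs == 2.0][0]:.3f}  width = {fgn.width:.3f}")

cas = hurst_spectrum(gen_binomial_cascade(CascadeSpec(p=0.7, levels=13,
                                                      seed=1)), qs=qs)
err = np.max(np.abs(cas.h - cascade_hq(0.7, qs)))
print(f"cascade p=0.7: width = {cas.width:.3f}  "
      f"max |h(q) - closed form| = {err:.3f}")
print("\nMonofractal series have near-zero width; the cascade's width and "
      "its agreement\nwith the closed form validate the q-order analysis.")
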