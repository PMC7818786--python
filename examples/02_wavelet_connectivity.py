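"""Wavelet connectivity indices for a delayed, correlated pair.

The complex-wavelet imaginary coherence (W-ICOH) and weighted phase-lag
index (W-wPLI) respond only to *delayed* coupling: with a delay of 8 samples
they peak at the octaves whose period matches the delay, and their
band average quantifies the connectivity strength.
"""

import numpy as np

from fractalconn import (BivariateFractalSpec, ScaleBand, band_average,
                         synthesize_bivariate, wavelet_indices)

spec = BivariateFractalSpec(H1=0.7, H2=0.8, rho=0.9, delta=8, n=2 ** 14, seed=7)
ts = synthesize_bivariate(spec)
prof = wavelet_indices(ts.data[0], ts.data[1], J=9)

print("octave  |W-COH|   W-ICOH   W-wPLI")
for j in range(1, 10):
    print(f"  {j}     {abs(prof['COH'].value(j)):6.3f}  {prof['ICOH'].value(j):+7.3f}"
          f"  {prof['wPLI'].value(j):+7.3f}")

band = ScaleBand(3, 7)
print("\nband (octaves 3..7) averages of |index|:")
for k in ("COH", "ICOH", "wPLI"):
    print(f"  W-{k}: {band_average(prof[k], band):.3f}")
print("\nLarge |W-ICOH| / |W-wPLI| at mid octaves indicate genuinely delayed "
      "coupling;\nzero-delay (volume-conduction-like) correlation would leave "
      "them at 0 while |W-COH| stays high.")
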