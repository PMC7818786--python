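"""Selfsimilarity (Hurst) exponent from the wavelet log-spectrum slope.

The per-octave wavelet spectrum of a scale-free signal is log-linear in the
octave index: slope 2H-1 for stationary fGn, 2H+1 for its running sum (fBm).
A weighted regression over octaves 3..9 recovers H.
"""

from fractalconn import (BivariateFractalSpec, ScaleBand, dtcwt_forward,
                         estimate_hurst, integrate_to_fbm,
                         synthesize_bivariate, wavelet_cross_spectrum)

band = ScaleBand(3, 9)
for H in (0.5, 0.7, 0.8):
    ts = synthesize_bivariate(
        BivariateFractalSpec(H1=H, H2=H, rho=0.0, n=2 ** 14, seed=11))
    c = dtcwt_forward(ts.data[0], 9)
    est = estimate_hurst(wavelet_cross_spectrum(c, c), band, "fGn")
    cb = dtcwt_forward(integrate_to_fbm(ts.data[0]), 9)
    estb = estimate_hurst(wavelet_cross_spectrum(cb, cb), band, "fBm")
    print(f"true H={H}: fGn estimate {est.H:.3f} (slope {est.slope:+.2f}, "
          f"se {est.se:.3f}); integrated-to-fBm estimate {estb.H:.3f} "
          f"(slope {estb.slope:+.2f})")
print("\nSlopes near 2H-1 (fGn) and 2H+1 (fBm) confirm the scale-free "
      "signature;\nthe class declaration only changes the slope-to-H mapping.")
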