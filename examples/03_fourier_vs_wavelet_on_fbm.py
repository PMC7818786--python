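"""Fourier vs wavelet imaginary coherence on nonstationary fBm signals.

On fractional Brownian motion the windowed-Fourier coefficients are
dominated by leakage from the local random trend — a real-valued, zero-lag
contamination that collapses F-ICOH toward 0 — while the wavelet's vanishing
moments leave W-ICOH unbiased.  A reduced version (N=60) of the Monte-Carlo
comparison; the acceptance script runs it at N=200.
"""

from fractalconn.reproduce import fbm_fourier_degradation

res = fbm_fourier_degradation(seed=1, N=60)
tbl = res["summary"]
for rho in (0.0, 0.1):
    sub = tbl[(tbl.rho == rho) & (tbl.octave != "band")]
    w = sub[sub.estimator == "W-ICOH"]
    f = sub[sub.estimator == "F-ICOH"]
    print(f"rho={rho}:")
    print("  octave     reference   W mean     F mean")
    for j, wrow, frow in zip(w.octave, w.itertuples(), f.itertuples()):
        print(f"    {j}       {wrow.reference:+8.3f}  {wrow.mean:+8.3f}  "
              f"{frow.mean:+8.3f}")
print(f"\nmax over rho of the octave-averaged RMSE ratio F/W "
      f"(error of the MC mean): {res['max_ratio']:.1f}")
print("W-ICOH tracks the model reference; F-ICOH is collapsed to ~0 by "
      "trend leakage,\nso its error is pure bias — an order of magnitude "
      "above the wavelet error.")
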