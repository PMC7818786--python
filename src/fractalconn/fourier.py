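"""Windowed-Fourier (Welch / Gabor) cross-spectral estimation and indices.

Two dialects are provided.

* :func:`fourier_frames` / :func:`fourier_indices`: a fixed window, per-frame
  short-time Fourier coefficients on the rfft bin grid, and the three indices
  per frequency bin.  This is the classical Welch periodogram machinery (the
  80 s Hanning window used for sensor data is one configuration of it).

* :func:`fourier_octave_profile`: the simulation-comparison dialect, one
  Hanning window per octave with length ``2**(j+2)`` (matching the octave's
  bandwidth), 50 % overlap, demodulated directly at the octave center
  frequency ``f0 / 2**j`` (which generically falls between DFT bins, exactly
  as the Gabor coefficients ``g(l, k)`` at frequencies ``l * nu0`` do).  No
  detrending is applied — the estimator is the plain windowed transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .indices import ConnectivityProfile
from .transform import ScaleBand

__all__ = ["WindowSpec", "FourierFrames", "fourier_frames", "fourier_indices",
           "fourier_octave_profile"]

_EPS = 1e-300


@dataclass(frozen=True)
class WindowSpec:
    """Analysis window: shape, length and hop in samples.

    The time step ``T0 = hop / fs`` and frequency step ``nu0 = fs / length``
    must satisfy the Gabor frame density condition ``T0 * nu0 <= 1``
    (at 50 % overlap ``T0 * nu0 = 1/2``).
    """

    length: int
    hop: int | None = None
    shape: str = "hann"

    def __post_init__(self):
        if self.length < 2:
            raise ValueError("window length must be >= 2")
        if self.hop is None:
            object.__setattr__(self, "hop", self.length // 2)
        if self.hop < 1:
            raise ValueError("hop must be >= 1")
        if self.hop / self.length > 1.0:
            raise ValueError(
                f"frame parameters violate the density condition T0*nu0 <= 1: "
                f"hop/length = {self.hop / self.length:.3f} > 1"
            )


@dataclass
class FourierFrames:
    """Per-frame windowed Fourier coefficients ``g(l, k)`` of one channel.

    ``coeffs`` has shape (frames, bins) on the one-sided rfft grid.
    """

    coeffs: np.ndarray
    frequencies: np.ndarray       # Hz
    window: WindowSpec
    fs: float
    n: int

    @property
    def n_frames(self) -> int:
        return self.coeffs.shape[0]


def _frame_matrix(x: np.ndarray, window: WindowSpec) -> np.ndarray:
    n = len(x)
    if window.length > n:
        raise ValueError(f"window length {window.length} exceeds signal length {n}")
    nk = (n - window.length) // window.hop + 1
    idx = np.arange(window.length)[None, :] + window.hop * np.arange(nk)[:, None]
    return x[idx]


def fourier_frames(x: np.ndarray, fs: float, window: WindowSpec) -> FourierFrames:
    """Short-time Fourier coefficients of a real signal, full frames only."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    w = get_window(window.shape, window.length, fftbins=True)
    g = np.fft.rfft(_frame_matrix(x, window) * w, axis=1)
    freqs = np.fft.rfftfreq(window.length, d=1.0 / fs)
    return FourierFrames(coeffs=g, frequencies=freqs, window=window, fs=fs, n=len(x))


def fourier_indices(fa: FourierFrames, fb: FourierFrames,
                    pair: tuple[str, str] = ("a", "b")
                    ) -> dict[str, ConnectivityProfile]:
    """Per-bin F-COH, F-ICOH and F-wPLI from identically framed channels.

    The cross-spectrum conjugates the second channel and averages across
    frames; the wPLI numerator/denominator use the per-frame imaginary parts.
    Bins with a vanishing auto-spectrum (or wPLI denominator) are 0, flagged.
    """
    if fa.coeffs.shape != fb.coeffs.shape or fa.window != fb.window:
        raise ValueError("channels are not identically framed")
    cross = fa.coeffs * np.conj(fb.coeffs)
    S12 = cross.mean(axis=0)
    S11 = (np.abs(fa.coeffs) ** 2).mean(axis=0)
    S22 = (np.abs(fb.coeffs) ** 2).mean(axis=0)
    denom2 = S11 * S22
    bad = denom2 <= 0.0
    coh = np.where(bad, 0.0, S12 / np.sqrt(np.where(bad, 1.0, denom2)))
    im = cross.imag
    wden = np.abs(im).sum(axis=0)
    wbad = wden <= 1e-12 * np.abs(cross).sum(axis=0)
    wpli = np.where(wbad, 0.0, im.sum(axis=0) / np.where(wbad, 1.0, wden))
    out = {}
    for name, vals, flags in (("COH", coh, bad),
                              ("ICOH", coh.imag, bad),
                              ("wPLI", wpli, wbad)):
        out[name] = ConnectivityProfile(index=name, basis="fourier",
                                        values=np.asarray(vals),
                                        flagged=np.asarray(flags),
                                        frequencies=fa.frequencies, pair=pair)
    return out


def fourier_octave_profile(x: np.ndarray, y: np.ndarray, octaves: range | list,
                           f0: float, fs: float = 1.0,
                           pair: tuple[str, str] = ("a", "b"),
                           window_factor: int = 4,
                           ) -> dict[str, ConnectivityProfile]:
    """Octave-matched Fourier indices for the wavelet/Fourier comparison.

    For each octave j the signals are demodulated at the octave center
    frequency ``f0 / 2**j`` (cycles/sample) under a Hanning window of length
    ``window_factor * 2**j`` with 50 % overlap; the three indices are formed
    from the per-frame coefficients.  Returns octave-indexed profiles
    directly comparable to the wavelet ones.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("channels differ in length")
    octaves = list(octaves)
    vals = {name: np.zeros(len(octaves)) for name in ("ICOH", "wPLI")}
    cvals = np.zeros(len(octaves), dtype=complex)
    flags = np.zeros(len(octaves), dtype=bool)
    for i, j in enumerate(octaves):
        W = window_factor * 2 ** j
        if W > len(x):
            flags[i] = True
            continue
        win = get_window("hann", W, fftbins=True)
        fj = f0 / 2.0 ** j
        e = win * np.exp(-2j * np.pi * fj * np.arange(W))
        hop = W // 2
        spec = WindowSpec(length=W, hop=hop)
        gx = (_frame_matrix(x, spec) * e).sum(axis=1)
        gy = (_frame_matrix(y, spec) * e).sum(axis=1)
        cross = gx * np.conj(gy)
        S12 = cross.mean()
        denom2 = (np.abs(gx) ** 2).mean() * (np.abs(gy) ** 2).mean()
        if denom2 <= 0.0:
            flags[i] = True
            continue
        coh = S12 / np.sqrt(denom2)
        cvals[i] = coh
        vals["ICOH"][i] = coh.imag
        wden = np.abs(cross.imag).sum()
        if wden <= 1e-12 * np.abs(cross).sum():
            flags[i] = True
        else:
            vals["wPLI"][i] = cross.imag.sum() / wden
    out = {"COH": ConnectivityProfile(index="COH", basis="fourier", values=cvals,
                                      flagged=flags.copy(),
                                      octaves=np.asarray(octaves), pair=pair)}
    for name in ("ICOH", "wPLI"):
        out[name] = ConnectivityProfile(index=name, basis="fourier",
                                        values=vals[name], flagged=flags.copy(),
                                        octaves=np.asarray(octaves), pair=pair)
    return out
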