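"""Wavelet cross-spectra, connectivity indices, band averaging and Hurst fits.

Conventions.  The cross-spectrum between channels a and b conjugates the
second channel, ``S_ab(j) = mean_k d_a(j,k) d_b(j,k)^*``; with an analytic
(positive-frequency) wavelet the sign of ``Im S_ab`` therefore encodes the
lead/lag direction of channel b relative to channel a, and both the imaginary
coherence and the weighted phase-lag index negate under argument swap.
Boundary-flagged coefficients are excluded from every sum; an octave whose
coefficients are all boundary-contaminated is computed anyway but flagged,
and flagged octaves are skipped by band averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transform import ComplexWaveletCoeffs, ScaleBand, dtcwt_forward, scale_to_frequency

__all__ = [
    "WaveletCrossSpectrum",
    "ConnectivityProfile",
    "HurstEstimate",
    "wavelet_cross_spectrum",
    "w_coh",
    "w_icoh",
    "w_wpli",
    "wavelet_indices",
    "band_average",
    "estimate_hurst",
]

_EPS = 1e-300


@dataclass
class WaveletCrossSpectrum:
    """Per-octave complex cross-spectral values ``S(j)`` for one channel pair."""

    values: np.ndarray            # complex, octave j at index j-1
    n_used: np.ndarray            # coefficients entering each average
    flagged: np.ndarray           # True where the octave was fully boundary-contaminated
    pair: tuple[str, str] = ("a", "b")

    @property
    def levels(self) -> int:
        return len(self.values)

    def value(self, j: int) -> complex:
        return self.values[j - 1]


@dataclass
class ConnectivityProfile:
    """Per-octave (or per-frequency) values of one connectivity index.

    ``values`` is complex for COH and real for ICOH / wPLI.  For the wavelet
    basis ``octaves`` gives the octave index per entry; for the Fourier basis
    ``frequencies`` gives the bin frequency in Hz per entry.
    """

    index: str                    # 'COH' | 'ICOH' | 'wPLI'
    basis: str                    # 'wavelet' | 'fourier'
    values: np.ndarray
    flagged: np.ndarray
    octaves: np.ndarray | None = None
    frequencies: np.ndarray | None = None
    pair: tuple[str, str] = ("a", "b")

    def value(self, j: int):
        if self.octaves is None:
            raise ValueError("profile is not octave-indexed")
        return self.values[int(np.flatnonzero(self.octaves == j)[0])]


@dataclass
class HurstEstimate:
    """Selfsimilarity exponent from the slope of the log2 wavelet spectrum."""

    H: float
    slope: float
    se: float
    octaves: tuple[int, int]
    signal_class: str


def wavelet_cross_spectrum(a: ComplexWaveletCoeffs, b: ComplexWaveletCoeffs,
                           pair: tuple[str, str] = ("a", "b")
                           ) -> WaveletCrossSpectrum:
    """``S_ab(j) = (1/n_j) sum_k d_a(j,k) d_b(j,k)^*`` over interior coefficients."""
    if a.levels != b.levels or a.n != b.n:
        raise ValueError("coefficient sets differ in length or octave count")
    if a.filter_set != b.filter_set:
        raise ValueError("coefficient sets come from different filter banks")
    vals = np.empty(a.levels, dtype=complex)
    used = np.empty(a.levels, dtype=int)
    flags = np.zeros(a.levels, dtype=bool)
    for j in range(1, a.levels + 1):
        da, db = a.interior(j), b.interior(j)
        vals[j - 1] = np.mean(da * np.conj(db))
        used[j - 1] = len(da)
        flags[j - 1] = a.octave_fully_flagged(j) or b.octave_fully_flagged(j)
    return WaveletCrossSpectrum(values=vals, n_used=used, flagged=flags, pair=pair)


def _normalized(Saa: WaveletCrossSpectrum, Sbb: WaveletCrossSpectrum,
                Sab: WaveletCrossSpectrum) -> tuple[np.ndarray, np.ndarray]:
    if not (Saa.levels == Sbb.levels == Sab.levels):
        raise ValueError("cross-spectra have mismatched octave support")
    denom2 = Saa.values.real * Sbb.values.real
    bad = denom2 <= 0.0
    ratio = Sab.values / np.sqrt(np.where(bad, 1.0, denom2))
    ratio = np.where(bad, 0.0, ratio)
    flags = Saa.flagged | Sbb.flagged | Sab.flagged | bad
    return ratio, flags


def w_coh(Saa: WaveletCrossSpectrum, Sbb: WaveletCrossSpectrum,
          Sab: WaveletCrossSpectrum) -> ConnectivityProfile:
    """Complex wavelet coherence ``S_ab(j) / sqrt(S_aa(j) S_bb(j))``."""
    ratio, flags = _normalized(Saa, Sbb, Sab)
    return ConnectivityProfile(index="COH", basis="wavelet", values=ratio,
                               flagged=flags,
                               octaves=np.arange(1, Sab.levels + 1), pair=Sab.pair)


def w_icoh(Saa: WaveletCrossSpectrum, Sbb: WaveletCrossSpectrum,
           Sab: WaveletCrossSpectrum) -> ConnectivityProfile:
    """Imaginary part of the wavelet coherence; antisymmetric under swap."""
    ratio, flags = _normalized(Saa, Sbb, Sab)
    return ConnectivityProfile(index="ICOH", basis="wavelet", values=ratio.imag,
                               flagged=flags,
                               octaves=np.arange(1, Sab.levels + 1), pair=Sab.pair)


def w_wpli(a: ComplexWaveletCoeffs, b: ComplexWaveletCoeffs,
           pair: tuple[str, str] = ("a", "b")) -> ConnectivityProfile:
    """Weighted phase-lag index from the per-coefficient imaginary parts,

        wPLI(j) = sum_k Im{d_a d_b^*} / sum_k |Im{d_a d_b^*}|,

    in [-1, 1]; a vanishing denominator (e.g. a channel with itself) yields
    the value 0 with the octave flagged."""
    if a.levels != b.levels or a.n != b.n:
        raise ValueError("coefficient sets differ in length or octave count")
    vals = np.empty(a.levels)
    flags = np.zeros(a.levels, dtype=bool)
    for j in range(1, a.levels + 1):
        prod = a.interior(j) * np.conj(b.interior(j))
        im = prod.imag
        denom = np.sum(np.abs(im))
        # a denominator at rounding level (e.g. a channel with itself, where
        # the products are real up to float error) counts as degenerate
        if denom <= 1e-12 * np.sum(np.abs(prod)):
            vals[j - 1] = 0.0
            flags[j - 1] = True
        else:
            vals[j - 1] = np.sum(im) / denom
        flags[j - 1] |= a.octave_fully_flagged(j) or b.octave_fully_flagged(j)
    return ConnectivityProfile(index="wPLI", basis="wavelet", values=vals,
                               flagged=flags,
                               octaves=np.arange(1, a.levels + 1), pair=pair)


def wavelet_indices(x: np.ndarray, y: np.ndarray, J: int, bank=None,
                    pair: tuple[str, str] = ("a", "b")
                    ) -> dict[str, ConnectivityProfile]:
    """All three wavelet indices for one channel pair in one pass."""
    a = dtcwt_forward(x, J, bank)
    b = dtcwt_forward(y, J, bank)
    Saa = wavelet_cross_spectrum(a, a, pair=(pair[0], pair[0]))
    Sbb = wavelet_cross_spectrum(b, b, pair=(pair[1], pair[1]))
    Sab = wavelet_cross_spectrum(a, b, pair=pair)
    return {"COH": w_coh(Saa, Sbb, Sab),
            "ICOH": w_icoh(Saa, Sbb, Sab),
            "wPLI": w_wpli(a, b, pair=pair)}


def band_average(p: ConnectivityProfile, band: ScaleBand,
                 skip_flagged: bool = True) -> float:
    """Mean of the absolute index values over the band; in [0, 1].

    Wavelet profiles average over octaves ``j1 <= j <= j2``; Fourier profiles
    average over bins whose frequency lies in the mapped band
    ``[f(j2), f(j1)]``.  Flagged entries are excluded; an empty band raises.
    """
    if p.octaves is not None:
        sel = (p.octaves >= band.j1) & (p.octaves <= band.j2)
        if band.j2 > p.octaves.max():
            raise ValueError(f"band ({band.j1}, {band.j2}) exceeds profile "
                             f"support (J={p.octaves.max()})")
    else:
        lo, hi = band.frequency_range()
        sel = (p.frequencies >= lo) & (p.frequencies <= hi)
    if skip_flagged:
        sel &= ~p.flagged
    if not np.any(sel):
        raise ValueError("no unflagged values in the requested band")
    return float(np.mean(np.abs(p.values[sel])))


def estimate_hurst(Sdiag: WaveletCrossSpectrum, band: ScaleBand,
                   signal_class: str = "fGn") -> HurstEstimate:
    """Selfsimilarity exponent from a weighted log2-spectrum regression.

    Fits ``log2 S(j) = zeta * j + c`` by weighted least squares over the band
    octaves, weights proportional to the per-octave coefficient counts, and
    maps the slope to H by the declared class: ``H = (zeta + 1)/2`` for fGn
    (stationary noise), ``H = (zeta - 1)/2`` for fBm (integrated motion).
    """
    if signal_class not in ("fGn", "fBm"):
        raise ValueError("signal_class must be 'fGn' or 'fBm'")
    js = np.array([j for j in band.octaves if j <= Sdiag.levels])
    if len(js) < 3:
        raise ValueError("need at least 3 octaves for a slope fit")
    S = Sdiag.values.real[js - 1]
    if np.any(S <= 0.0):
        raise ValueError("nonpositive spectrum value in the fit band")
    y = np.log2(S)
    w = Sdiag.n_used[js - 1].astype(float)
    X = np.column_stack([js.astype(float), np.ones_like(js, dtype=float)])
    W = np.diag(w)
    XtWX = X.T @ W @ X
    beta = np.linalg.solve(XtWX, X.T @ W @ y)
    resid = y - X @ beta
    dof = max(len(js) - 2, 1)
    sigma2 = float(resid @ W @ resid) / dof
    cov = sigma2 * np.linalg.inv(XtWX)
    zeta = float(beta[0])
    H = (zeta + 1.0) / 2.0 if signal_class == "fGn" else (zeta - 1.0) / 2.0
    return HurstEstimate(H=H, slope=zeta, se=float(np.sqrt(cov[0, 0])),
                         octaves=(int(js[0]), int(js[-1])),
                         signal_class=signal_class)
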