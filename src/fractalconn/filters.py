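"""Hilbert-pair (q-shift type) filter bank for the dual-tree complex wavelet transform.

The dual-tree transform runs two parallel real discrete wavelet transforms
whose mother wavelets form an approximate Hilbert pair, so that the complex
combination of the two trees' detail coefficients is approximately analytic.
For decomposition levels >= 2 this requires a pair of even-length orthonormal
conjugate-quadrature filters whose lowpass responses differ by a half-sample
delay (the "q-shift" property).  Rather than shipping coefficient tables, the
pair is *designed* here by the common-factor method: the lowpass filters share
a common factor ``q(z) (1+z^-1)^K`` and differ by a maximally-flat
fractional-delay factor ``d(z)`` versus its time reverse,

    h0a(z) = q(z) (1 + z^-1)^K d(z),      h0b(z) = q(z) (1 + z^-1)^K d~(z),

with ``d~(n) = d(L-n)``, so that h0b(z)/h0a(z) approximates z^(-1/2) in the
passband.  ``q`` is obtained by solving the orthonormality (half-band)
condition linearly for the symmetric factor Q = q * q~ and spectrally
factorizing it.  K is the number of vanishing moments, L the order of the
flat-delay factor; the filter length is 2(K+L).

Level 1 needs an integer one-sample delay between the trees instead, which is
realised with a single orthogonal filter pair (Daubechies) and opposite
decimation phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import comb

import numpy as np
import pywt
from scipy.signal import fftconvolve

__all__ = ["FilterBank", "default_filter_bank", "design_qshift_pair"]


def _flat_delay_factor(L: int, tau: float = 0.5) -> np.ndarray:
    """Maximally-flat (Thiran) fractional-delay denominator of order L."""
    d = np.zeros(L + 1)
    d[0] = 1.0
    for k in range(1, L + 1):
        prod = 1.0
        for n in range(L + 1):
            prod *= (tau - L + n) / (tau - L + k + n)
        d[k] = (-1) ** k * comb(L, k) * prod
    return d


def design_qshift_pair(K: int = 4, L: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Design the half-sample-shifted orthonormal lowpass pair (h0a, h0b).

    Returns two length ``2(K+L)`` filters, each orthonormal to its own even
    shifts, with ``sum(h) = sqrt(2)``, whose transfer functions differ by an
    approximate half-sample delay.

    Raises
    ------
    ValueError
        If the symmetric factor is not nonnegative (design infeasible) or the
        spectral factorization does not reproduce it.
    """
    if K < 1 or L < 1:
        raise ValueError("need at least one vanishing moment and delay order 1")
    d = _flat_delay_factor(L)
    r = np.convolve(d, d[::-1])                   # lags -L..L
    b = np.array([1.0])
    for _ in range(K):
        b = np.convolve(b, [1.0, 2.0, 1.0])       # (1+z)(1+z^-1), symmetric
    c = np.convolve(b, r)                         # lags -(K+L)..(K+L)
    KL, M = K + L, K + L - 1                      # Q(z) has lags -M..M

    # Half-band condition P(z) + P(-z) = 2 with P = Q * c: linear in Q.
    A = np.zeros((KL, M + 1))
    for m in range(KL):
        lag = 2 * m
        for i in range(M + 1):
            acc = 0.0
            for ii in ({0} if i == 0 else {-i, i}):
                if abs(lag - ii) <= KL:
                    acc += c[lag - ii + KL]
            A[m, i] = acc
    rhs = np.zeros(KL)
    rhs[0] = 1.0
    s = np.linalg.solve(A, rhs)

    Q = np.concatenate([s[::-1], s[1:]])
    w = np.linspace(0.0, np.pi, 8192)
    Qw = s[0] + 2.0 * (s[1:, None] * np.cos(np.outer(np.arange(1, M + 1), w))).sum(0)
    if Qw.min() < -1e-10:
        raise ValueError(f"common-factor design infeasible for K={K}, L={L}")

    roots = np.roots(Q[::-1])
    inside = roots[np.abs(roots) < 1.0]
    if len(inside) != M:
        raise ValueError(f"spectral factorization failed for K={K}, L={L}")
    q = np.real(np.poly(inside))
    q *= np.sqrt(Q[M] / np.sum(q * q))
    if np.max(np.abs(np.convolve(q, q[::-1]) - Q)) > 1e-8:
        raise ValueError("spectral factor does not reproduce the symmetric factor")

    binK = np.array([1.0])
    for _ in range(K):
        binK = np.convolve(binK, [1.0, 1.0])
    base = np.convolve(q, binK)
    h0a = np.convolve(base, d)
    h0b = np.convolve(base, d[::-1])
    h0a *= np.sqrt(2.0) / h0a.sum()
    h0b *= np.sqrt(2.0) / h0b.sum()
    return h0a, h0b


def _qmf(h: np.ndarray) -> np.ndarray:
    """Conjugate-quadrature highpass from an orthonormal lowpass."""
    return ((-1.0) ** np.arange(len(h))) * h[::-1]


@dataclass(frozen=True)
class FilterBank:
    """All filters of the dual-tree transform plus measured spectral facts.

    Attributes
    ----------
    h0_1, h1_1 : level-1 orthogonal analysis pair (shared by both trees, with
        a one-sample decimation offset between trees).
    h0a, h1a, h0b, h1b : level >= 2 analysis pairs for tree a and tree b.
    imag_sign : +1 or -1; the analytic combination is ``d_a + imag_sign*1j*d_b``
        (measured from the filters' frequency response, not assumed).
    f0 : mother-wavelet center frequency in cycles/sample, measured as the
        spectral peak of the level-5 equivalent complex wavelet, scaled back
        by 2^5.  The octave-j passband center is ``f0 / 2^j``.
    name : identifier recorded in transform outputs.
    """

    h0_1: np.ndarray
    h1_1: np.ndarray
    h0a: np.ndarray
    h1a: np.ndarray
    h0b: np.ndarray
    h1b: np.ndarray
    imag_sign: int
    f0: float
    name: str
    _eq_cache: dict = field(default_factory=dict, compare=False, repr=False)

    @classmethod
    def build(cls, K: int = 4, L: int = 4, level1: str = "db8") -> "FilterBank":
        h0a, h0b = design_qshift_pair(K, L)
        h1a, h1b = _qmf(h0a), _qmf(h0b)
        w = pywt.Wavelet(level1)
        h0_1 = np.asarray(w.dec_lo, float)
        h1_1 = np.asarray(w.dec_hi, float)
        bank = cls(
            h0_1=h0_1, h1_1=h1_1, h0a=h0a, h1a=h1a, h0b=h0b, h1b=h1b,
            imag_sign=+1, f0=0.0, name=f"commonfactor-K{K}L{L}-{level1}",
        )
        sign, f0 = bank._measure_sign_and_f0()
        return cls(
            h0_1=h0_1, h1_1=h1_1, h0a=h0a, h1a=h1a, h0b=h0b, h1b=h1b,
            imag_sign=sign, f0=f0, name=f"commonfactor-K{K}L{L}-{level1}",
        )

    # -- equivalent (undecimated) wavelet filters per level ------------------

    def equivalent_wavelets(self, level: int) -> tuple[np.ndarray, np.ndarray]:
        """Equivalent level-`level` wavelet filters for trees a and b.

        The level-j detail path is level-1 lowpass, then j-2 tree lowpasses,
        then the tree highpass, each upsampled by the accumulated decimation.
        Tree b's level-1 filters are the tree-a ones delayed by one sample.
        """
        if level in self._eq_cache:
            return self._eq_cache[level]

        def up(f: np.ndarray, s: int) -> np.ndarray:
            out = np.zeros((len(f) - 1) * s + 1)
            out[::s] = f
            return out

        if level == 1:
            wa = self.h1_1
            wb = np.concatenate([[0.0], self.h1_1])
        else:
            wa = self.h0_1
            wb = np.concatenate([[0.0], self.h0_1])
            for j in range(2, level):
                wa = fftconvolve(wa, up(self.h0a, 2 ** (j - 1)))
                wb = fftconvolve(wb, up(self.h0b, 2 ** (j - 1)))
            wa = fftconvolve(wa, up(self.h1a, 2 ** (level - 1)))
            wb = fftconvolve(wb, up(self.h1b, 2 ** (level - 1)))
        self._eq_cache[level] = (wa, wb)
        return wa, wb

    def complex_response(self, level: int, nfft: int) -> np.ndarray:
        """Response of the level-`level` complex detail coefficients to a
        complex exponential ``exp(i 2 pi f t)``, on the full frequency circle
        (frequencies ``np.fft.fftfreq(nfft)``).

        The transform *correlates* the signal with the filters, so the
        response is the conjugated filter transform,
        ``conj(Wa(f)) + i * imag_sign * conj(Wb(f))``; for a good Hilbert
        pair its energy concentrates at positive frequencies.
        """
        wa, wb = self.equivalent_wavelets(level)
        n = max(len(wa), len(wb))
        if nfft < n:
            raise ValueError(f"nfft={nfft} shorter than equivalent filter ({n})")
        return (np.conj(np.fft.fft(wa, nfft))
                + 1j * self.imag_sign * np.conj(np.fft.fft(wb, nfft)))

    def _measure_sign_and_f0(self, level: int = 5) -> tuple[int, float]:
        wa, wb = self.equivalent_wavelets(level)
        nfft = 1 << (int(np.ceil(np.log2(max(len(wa), len(wb))))) + 3)
        Wa, Wb = np.conj(np.fft.fft(wa, nfft)), np.conj(np.fft.fft(wb, nfft))
        half = nfft // 2
        best_sign, best_neg = +1, np.inf
        for sign in (+1, -1):
            E = np.abs(Wa + 1j * sign * Wb) ** 2
            neg = E[half + 1:].sum() / (E[1:half].sum() + E[half + 1:].sum())
            if neg < best_neg:
                best_sign, best_neg = sign, neg
        E = np.abs(Wa + 1j * best_sign * Wb) ** 2
        f0 = np.argmax(E[:half]) / nfft * 2 ** level
        return best_sign, float(f0)

    def negative_frequency_fraction(self, level: int = 5) -> float:
        """Spectral energy of the analytic wavelet at negative frequencies,
        as a fraction of total (small for a good Hilbert pair)."""
        wa, wb = self.equivalent_wavelets(level)
        nfft = 1 << (int(np.ceil(np.log2(max(len(wa), len(wb))))) + 3)
        W = self.complex_response(level, nfft)
        E = np.abs(W) ** 2
        half = nfft // 2
        return float(E[half + 1:].sum() / (E[1:half].sum() + E[half + 1:].sum()))

    @property
    def max_filter_len(self) -> int:
        return max(len(self.h0_1), len(self.h0a))


@lru_cache(maxsize=4)
def _cached_bank(K: int, L: int, level1: str) -> FilterBank:
    return FilterBank.build(K, L, level1)


def default_filter_bank() -> FilterBank:
    """The package default: K=4 vanishing moments, L=4 delay order (16-tap
    shifted pair), Daubechies-8 first level."""
    return _cached_bank(4, 4, "db8")
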