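"""Forward dual-tree complex wavelet transform and the scale-to-frequency map."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .filters import FilterBank, default_filter_bank

__all__ = [
    "ComplexWaveletCoeffs",
    "ScaleBand",
    "dtcwt_forward",
    "scale_to_frequency",
    "max_feasible_level",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScaleBand:
    """A contiguous range of octaves ``j1 <= j <= j2`` with its frequency map.

    ``f0`` is the mother-wavelet center frequency in cycles/sample; octave j
    maps to ``f0 * fs / 2**j`` Hz.  If ``f0`` is None the measured value of
    the default filter bank is used.
    """

    j1: int
    j2: int
    fs: float = 1.0
    f0: float | None = None

    def __post_init__(self):
        if not (1 <= self.j1 <= self.j2):
            raise ValueError(f"need 1 <= j1 <= j2, got ({self.j1}, {self.j2})")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.f0 is None:
            object.__setattr__(self, "f0", default_filter_bank().f0)
        # The octave-1 passband is (1/4, 1/2) cycles/sample, so the mother
        # center frequency f0 = 2 * peak(octave 1) lies in (1/2, 1).
        if not (0.0 < self.f0 < 1.0):
            raise ValueError(f"f0 must lie in (0, 1) cycles/sample, got {self.f0}")

    @property
    def octaves(self) -> range:
        return range(self.j1, self.j2 + 1)

    def frequency(self, j: int) -> float:
        return scale_to_frequency(j, self)

    def frequency_range(self) -> tuple[float, float]:
        """(low, high) edge frequencies in Hz: centers of the coarsest and
        finest octaves in the band."""
        return self.frequency(self.j2), self.frequency(self.j1)


def scale_to_frequency(j: int, band: ScaleBand) -> float:
    """Map octave j (scale 2**j) to its center frequency ``f0 * fs / 2**j``."""
    if j < 1:
        raise ValueError("octave index must be >= 1")
    return band.f0 * band.fs / 2.0 ** j


@dataclass
class ComplexWaveletCoeffs:
    """Per-octave complex detail coefficients of one channel.

    ``coeffs[j-1]`` holds the octave-j sequence ``d(j, k)``; its real part
    comes from tree a, its imaginary part from tree b (sign fixed so the
    effective wavelet is analytic).  ``margins[j-1]`` is the number of
    coefficients at each end whose support touches the (symmetric-extension)
    boundary; spectral averages exclude them.
    """

    coeffs: list[np.ndarray]
    margins: list[int]
    n: int
    filter_set: str

    @property
    def levels(self) -> int:
        return len(self.coeffs)

    def n_coeffs(self, j: int) -> int:
        return len(self.coeffs[j - 1])

    def interior(self, j: int) -> np.ndarray:
        """Octave-j coefficients with boundary-flagged ones removed; falls
        back to the full set when the margins swallow the whole octave."""
        d = self.coeffs[j - 1]
        m = self.margins[j - 1]
        if len(d) > 2 * m + 1:
            return d[m: len(d) - m]
        return d

    def octave_fully_flagged(self, j: int) -> bool:
        return len(self.coeffs[j - 1]) <= 2 * self.margins[j - 1] + 1


def max_feasible_level(n: int, bank: FilterBank | None = None) -> int:
    """Largest J such that the coarsest filtering still sees a full filter."""
    bank = bank or default_filter_bank()
    L = bank.max_filter_len
    if n < L:
        return 0
    return int(np.floor(np.log2(n / L))) + 1


def _analysis_step(x: np.ndarray, h: np.ndarray, phase: int) -> np.ndarray:
    """One filtering + dyadic decimation step with symmetric extension."""
    L = len(h)
    xe = np.pad(x, (L - 1, L), mode="symmetric")
    y = np.convolve(xe, h[::-1], mode="valid")     # correlation with h
    return y[phase::2][: (len(x) + 1) // 2]


def dtcwt_forward(
    x: np.ndarray,
    J: int,
    bank: FilterBank | None = None,
) -> ComplexWaveletCoeffs:
    """Dual-tree complex wavelet decomposition of a real 1-D signal.

    Parameters
    ----------
    x : real sequence.  Non-power-of-two lengths are truncated to the largest
        multiple of ``2**J`` (never zero-padded) with a logged warning.
    J : number of octaves.  Must not exceed :func:`max_feasible_level`.
    bank : filter bank; the package default if omitted.

    Returns
    -------
    ComplexWaveletCoeffs with octaves 1..J (j=1 finest).
    """
    bank = bank or default_filter_bank()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("input must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    n = len(x)
    jmax = max_feasible_level(n, bank)
    if J < 1 or J > jmax:
        raise ValueError(
            f"J={J} infeasible for n={n} with {bank.max_filter_len}-tap filters; "
            f"maximum feasible J is {jmax}"
        )
    n_use = (n >> J) << J
    if n_use != n:
        log.warning("truncating input from %d to %d samples (multiple of 2^%d)",
                    n, n_use, J)
        x = x[:n_use]

    s = bank.imag_sign
    coeffs: list[np.ndarray] = []
    margins: list[int] = []

    def out_margin(m_in: int, L: int) -> int:
        return int(np.ceil((m_in + L - 1) / 2))

    ha = _analysis_step(x, bank.h1_1, 0)
    hb = _analysis_step(x, bank.h1_1, 1)
    la = _analysis_step(x, bank.h0_1, 0)
    lb = _analysis_step(x, bank.h0_1, 1)
    coeffs.append(ha + 1j * s * hb)
    m_low = out_margin(0, len(bank.h0_1))
    margins.append(out_margin(0, len(bank.h1_1)))

    for _ in range(2, J + 1):
        ha = _analysis_step(la, bank.h1a, 0)
        hb = _analysis_step(lb, bank.h1b, 0)
        la = _analysis_step(la, bank.h0a, 0)
        lb = _analysis_step(lb, bank.h0b, 0)
        coeffs.append(ha + 1j * s * hb)
        margins.append(out_margin(m_low, len(bank.h1a)))
        m_low = out_margin(m_low, len(bank.h0a))

    return ComplexWaveletCoeffs(coeffs=coeffs, margins=margins, n=n_use,
                                filter_set=bank.name)
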