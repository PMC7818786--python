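"""Exact synthesis of correlated, delayed bivariate fGn/fBm and network fixtures.

The bivariate model is the time-reversible correlated pair of fractional
Gaussian noises: unit-variance components with autocovariances
``gamma_H1``, ``gamma_H2`` and cross-covariance ``rho * gamma_Hbar`` where
``Hbar = (H1 + H2) / 2``, so the pointwise (lag-0) correlation equals rho
exactly.  Synthesis is exact, by circulant embedding of the joint covariance
(the 2x2 spectral matrix of the embedding is factorized per frequency); if
the embedding is not nonnegative definite the synthesis fails loudly rather
than approximating.  Fractional Brownian motion components are running sums
of the fGn increments (B_H(0) = 0).  One component may be delayed by an
integer number of samples: the pair is generated with ``n + delta`` samples,
correlation is imposed instantaneously, then component 2 is shifted and both
are cropped to n.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "SynthesisError",
    "TrendSpec",
    "BivariateFractalSpec",
    "TimeSeriesSet",
    "fgn_covariance",
    "synthesize_bivariate",
    "bivariate_realizations",
    "integrate_to_fbm",
    "add_trend",
    "generate_network_dataset",
    "RHO_GRID",
    "DELTA_GRID",
    "DEFAULT_N",
]

# Simulation grids used throughout the Monte-Carlo studies.
RHO_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0, 0.1), 1))
DELTA_GRID: tuple[int, ...] = (0, 1, 2, 4, 8, 16, 32, 64)
DEFAULT_N: int = 2 ** 14


class SynthesisError(RuntimeError):
    """Raised when a requested joint covariance admits no exact synthesis."""


def fgn_covariance(H: float, lag) -> float | np.ndarray:
    """Autocovariance ``gamma_H(k)`` of unit-variance fractional Gaussian noise.

    ``gamma_H(k) = (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}) / 2``; symmetric in
    the lag, equal to 1 at lag 0, and identically 0 for |k| >= 1 when H = 1/2
    (white noise).
    """
    if not (0.0 < H < 1.0):
        raise ValueError(f"Hurst exponent must lie in (0, 1), got {H}")
    k = np.abs(np.asarray(lag, dtype=float))
    g = 0.5 * ((k + 1.0) ** (2 * H) - 2.0 * k ** (2 * H) + np.abs(k - 1.0) ** (2 * H))
    return float(g) if np.isscalar(lag) else g


@dataclass(frozen=True)
class TrendSpec:
    """An additive per-channel trend, scaled to ``amplitude`` signal-SD units.

    ``trend_kind``: 'polynomial' (random coefficients, degree <= 3),
    'sinusoid' (random phase, fixed period in samples), or 'fbm' (an
    independent slow fractional Brownian motion path).
    """

    trend_kind: Literal["polynomial", "sinusoid", "fbm"]
    amplitude: float
    order: int = 1
    period: float = 1024.0
    hurst: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("trend amplitude must be nonnegative")
        if self.trend_kind == "polynomial" and not (1 <= self.order <= 3):
            raise ValueError("polynomial trend order must be in 1..3")
        if self.trend_kind == "sinusoid" and self.period <= 0:
            raise ValueError("sinusoid period must be positive")
        if self.trend_kind == "fbm" and not (0.0 < self.hurst < 1.0):
            raise ValueError("fbm trend Hurst must lie in (0, 1)")
        if self.trend_kind not in ("polynomial", "sinusoid", "fbm"):
            raise ValueError(f"unknown trend kind {self.trend_kind!r}")


@dataclass(frozen=True)
class BivariateFractalSpec:
    """Full description of one synthetic bivariate scenario."""

    H1: float
    H2: float
    rho: float
    delta: int = 0
    n: int = DEFAULT_N
    kind1: Literal["fGn", "fBm"] = "fGn"
    kind2: Literal["fGn", "fBm"] = "fGn"
    fs: float = 1.0
    trend: TrendSpec | None = None
    seed: int = 0

    def __post_init__(self):
        for H in (self.H1, self.H2):
            if not (0.0 < H < 1.0):
                raise ValueError(f"Hurst exponents must lie in (0, 1), got {H}")
        if abs(self.rho) > 1.0:
            raise ValueError("|rho| must not exceed 1")
        if self.delta < 0 or int(self.delta) != self.delta:
            raise ValueError("delay must be a nonnegative integer")
        if self.n < 2 ** 6:
            raise ValueError("need at least 2^6 samples")
        for kind in (self.kind1, self.kind2):
            if kind not in ("fGn", "fBm"):
                raise ValueError(f"component kind must be 'fGn' or 'fBm', got {kind!r}")


@dataclass
class TimeSeriesSet:
    """M channels x n samples of real values, with sampling rate and labels."""

    data: np.ndarray
    fs: float
    labels: Sequence[str] = field(default_factory=list)
    provenance: object | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contain non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(self.data.shape[0])]
        self.labels = list(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


# --------------------------------------------------------------------------
# circulant-embedding engine


def _embedding_eigs(H1: float, H2: float, rho: float, n: int):
    """Spectral (eigenvalue) sequences of the circulant embedding, size m."""
    m = 1 << int(np.ceil(np.log2(max(2 * n, 2 * 64))))
    k = np.arange(m)
    lag = np.minimum(k, m - k)
    l11 = np.fft.fft(fgn_covariance(H1, lag)).real
    l22 = np.fft.fft(fgn_covariance(H2, lag)).real
    l12 = rho * np.fft.fft(fgn_covariance(0.5 * (H1 + H2), lag)).real
    return m, l11, l22, l12


def _embedding_factor(H1: float, H2: float, rho: float, n: int):
    """Per-frequency symmetric square root of the 2x2 embedding matrices."""
    m, l11, l22, l12 = _embedding_eigs(H1, H2, rho, n)
    det = l11 * l22 - l12 ** 2
    scale = max(l11.max(), l22.max())
    if l11.min() < -1e-9 * scale or l22.min() < -1e-9 * scale \
            or det.min() < -1e-9 * scale ** 2:
        raise SynthesisError(
            f"circulant embedding not nonnegative definite for "
            f"(H1={H1}, H2={H2}, rho={rho}); the triple admits no exact synthesis"
        )
    l11, l22 = np.maximum(l11, 0.0), np.maximum(l22, 0.0)
    s = np.sqrt(np.maximum(det, 0.0))
    t = np.sqrt(l11 + l22 + 2.0 * s)
    t = np.where(t > 0.0, t, 1.0)
    return m, (l11 + s) / t, l12 / t, (l22 + s) / t


def _draw_pair(factor, rng: np.random.Generator) -> np.ndarray:
    """Two independent exact bivariate-fGn realizations, shape (2, 2, n)."""
    m, b11, b12, b22, n = factor
    xi = (rng.standard_normal((2, m)) + 1j * rng.standard_normal((2, m))) / np.sqrt(2)
    w = np.empty((2, m), dtype=complex)
    w[0] = b11 * xi[0] + b12 * xi[1]
    w[1] = b12 * xi[0] + b22 * xi[1]
    z = np.fft.ifft(w, axis=1) * np.sqrt(m)
    out = np.empty((2, 2, n))
    out[0] = np.sqrt(2.0) * z.real[:, :n]
    out[1] = np.sqrt(2.0) * z.imag[:, :n]
    return out


def _finalize(raw: np.ndarray, spec: BivariateFractalSpec,
              rng: np.random.Generator) -> np.ndarray:
    """Apply delay, fGn->fBm integration and trend to one raw (2, n+delta) pair."""
    d, n = spec.delta, spec.n
    x1 = raw[0, d: d + n].copy()
    x2 = raw[1, :n].copy()
    if spec.kind1 == "fBm":
        x1 = integrate_to_fbm(x1)
    if spec.kind2 == "fBm":
        x2 = integrate_to_fbm(x2)
    data = np.vstack([x1, x2])
    if spec.trend is not None and spec.trend.amplitude > 0:
        data = _apply_trend(data, spec.trend, rng)
    return data


def bivariate_realizations(spec: BivariateFractalSpec, count: int,
                           rng: np.random.Generator | None = None
                           ) -> Iterator[np.ndarray]:
    """Yield ``count`` independent (2, n) realizations of the scenario.

    Exploits the fact that one circulant-embedding draw yields two
    independent realizations (real and imaginary output parts).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    m, b11, b12, b22 = _embedding_factor(spec.H1, spec.H2, spec.rho,
                                         spec.n + spec.delta)
    factor = (m, b11, b12, b22, spec.n + spec.delta)
    produced = 0
    while produced < count:
        pair = _draw_pair(factor, rng)
        for raw in pair:
            if produced >= count:
                break
            yield _finalize(raw, spec, rng)
            produced += 1


def synthesize_bivariate(spec: BivariateFractalSpec) -> TimeSeriesSet:
    """One exact realization of the scenario as a 2-channel TimeSeriesSet."""
    data = next(bivariate_realizations(spec, 1))
    return TimeSeriesSet(data=data, fs=spec.fs, labels=["x1", "x2"],
                         provenance=spec)


def integrate_to_fbm(fgn_series: np.ndarray) -> np.ndarray:
    """Running sum of fGn increments: discrete fractional Brownian motion.

    First differences of the output (with the B_H(0)=first-increment origin
    convention) reproduce the input exactly.
    """
    x = np.asarray(fgn_series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot integrate an empty series")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    return np.cumsum(x, axis=-1)


# --------------------------------------------------------------------------
# trends


def _trend_path(kind: str, n: int, trend: TrendSpec,
                rng: np.random.Generator) -> np.ndarray:
    if kind == "polynomial":
        t = np.linspace(-1.0, 1.0, n)
        coeffs = rng.standard_normal(trend.order)
        return sum(c * t ** (k + 1) for k, c in enumerate(coeffs))
    if kind == "sinusoid":
        phase = rng.uniform(0.0, 2.0 * np.pi)
        return np.sin(2.0 * np.pi * np.arange(n) / trend.period + phase)
    if kind == "fbm":
        spec = BivariateFractalSpec(H1=trend.hurst, H2=trend.hurst, rho=0.0,
                                    n=max(n, 2 ** 6))
        raw = next(bivariate_realizations(spec, 1, rng))
        return integrate_to_fbm(raw[0, :n] if raw.shape[1] >= n else raw[0])[:n]
    raise ValueError(f"unknown trend kind {kind!r}")


def _apply_trend(data: np.ndarray, trend: TrendSpec,
                 rng: np.random.Generator) -> np.ndarray:
    out = data.copy()
    for c in range(out.shape[0]):
        sd = out[c].std()
        if sd == 0.0 or trend.amplitude == 0.0:
            continue
        path = _trend_path(trend.trend_kind, out.shape[1], trend, rng)
        psd = path.std()
        if psd > 0:
            out[c] = out[c] + path * (trend.amplitude * sd / psd)
    return out


def add_trend(ts: TimeSeriesSet, trend: TrendSpec) -> TimeSeriesSet:
    """Return a copy of ``ts`` with an independent trend added per channel,
    scaled so the trend SD equals ``amplitude`` times the channel SD."""
    rng = np.random.default_rng(trend.seed)
    data = _apply_trend(ts.data, trend, rng) if trend.amplitude > 0 else ts.data.copy()
    return TimeSeriesSet(data=data, fs=ts.fs, labels=list(ts.labels),
                         provenance=ts.provenance)


# --------------------------------------------------------------------------
# multi-channel network fixtures


def generate_network_dataset(
    M: int,
    edges: Sequence[tuple[int, int, float, int]],
    H: Sequence[float] | float,
    n: int = DEFAULT_N,
    fs: float = 1.0,
    seed: int = 0,
    kinds: Sequence[str] | str = "fGn",
) -> TimeSeriesSet:
    """Multi-channel dataset with exact pairwise dependence on disjoint edges.

    Each edge ``(m, m', rho, delta)`` is realized as an exact correlated,
    delayed bivariate pair (channel m leads, channel m' is delayed); channels
    in no edge are independent.  Channels may appear in at most one edge —
    overlapping edges would require the full multivariate model, which this
    generator deliberately does not implement.
    """
    H = [float(H)] * M if np.isscalar(H) else list(H)
    kinds = [kinds] * M if isinstance(kinds, str) else list(kinds)
    if len(H) != M or len(kinds) != M:
        raise ValueError("need one Hurst exponent and one kind per channel")
    used: set[int] = set()
    for (a, b, rho, delta) in edges:
        if not (0 <= a < M and 0 <= b < M and a != b):
            raise ValueError(f"edge ({a}, {b}) references invalid channels")
        if a in used or b in used:
            raise ValueError(
                "overlapping edges are not supported (each channel may belong "
                "to at most one edge in the disjoint-pair construction)"
            )
        used.update((a, b))

    rng = np.random.default_rng(seed)
    data = np.empty((M, n))
    for (a, b, rho, delta) in edges:
        spec = BivariateFractalSpec(H1=H[a], H2=H[b], rho=rho, delta=int(delta),
                                    n=n, kind1=kinds[a], kind2=kinds[b])
        data[[a, b]] = next(bivariate_realizations(spec, 1, rng))
    for c in range(M):
        if c not in used:
            spec = BivariateFractalSpec(H1=H[c], H2=H[c], rho=0.0, n=n,
                                        kind1=kinds[c], kind2=kinds[c])
            data[c] = next(bivariate_realizations(spec, 1, rng))[0]
    labels = [f"ch{i}" for i in range(M)]
    return TimeSeriesSet(data=data, fs=fs, labels=labels,
                         provenance={"edges": list(edges), "H": H, "seed": seed})
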