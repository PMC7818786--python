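"""Connectivity matrices, density filtering, degree metrics and group contrasts.

The per-pair scalar is the band-averaged absolute index value, so matrices
are symmetric with entries in [0, 1] and an undefined (excluded) diagonal.
Network filtering follows the efficiency-cost-optimization recipe: sweep a
density grid, binarize by keeping the strongest edges, and keep the density
maximizing J(d) = (E_global + E_local) / d, with ties resolved toward the
sparser network.  Group contrasts are edge-wise paired t-tests with
Benjamini-Hochberg false-discovery-rate control across all M(M-1)/2 edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .filters import FilterBank, default_filter_bank
from .fourier import fourier_octave_profile
from .indices import band_average, wavelet_indices
from .simulate import TimeSeriesSet
from .transform import ScaleBand, dtcwt_forward, max_feasible_level
from .indices import w_coh, w_icoh, w_wpli, wavelet_cross_spectrum

__all__ = [
    "ConnectivityMatrix",
    "GroupContrast",
    "pairwise_band_indices",
    "eco_filter",
    "average_degree",
    "degree_summary",
    "paired_group_contrast",
    "correlate_deltas",
]


@dataclass
class ConnectivityMatrix:
    """M x M band-averaged absolute index values; diagonal undefined."""

    values: np.ndarray
    index: str
    basis: str
    band: ScaleBand
    labels: list[str] = field(default_factory=list)
    condition: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(v.shape[0])]
        self.values = v

    @property
    def M(self) -> int:
        return self.values.shape[0]

    def offdiagonal(self) -> np.ndarray:
        iu = np.triu_indices(self.M, k=1)
        return self.values[iu]


@dataclass
class GroupContrast:
    """Edge-wise paired t statistics with FDR-adjusted decisions."""

    t: np.ndarray                # per edge (upper triangle order)
    p: np.ndarray
    p_adjusted: np.ndarray
    rejected: np.ndarray
    flagged: np.ndarray          # zero-variance edges (t undefined)
    alpha: float
    edges: list[tuple[int, int]]
    labels: list[str]
    n_subjects: int
    conditions: tuple[str, str] = ("A", "B")


def pairwise_band_indices(ts: TimeSeriesSet, index_kind: str, basis: str,
                          band: ScaleBand, bank: FilterBank | None = None,
                          window_factor: int = 4) -> ConnectivityMatrix:
    """Band-averaged absolute index for every channel pair.

    For the wavelet basis each channel is transformed once and the three
    spectra are formed per pair; for the Fourier basis the octave-matched
    windowed estimator is used on the same octave band.
    """
    bank = bank or default_filter_bank()
    if index_kind not in ("COH", "ICOH", "wPLI"):
        raise ValueError(f"unknown index kind {index_kind!r}")
    if basis not in ("wavelet", "fourier"):
        raise ValueError(f"unknown basis {basis!r}")
    M, n = ts.n_channels, ts.n_samples
    if M < 2:
        raise ValueError("need at least two channels")
    J = band.j2
    if basis == "wavelet" and J > max_feasible_level(n, bank):
        raise ValueError(
            f"band up to octave {J} infeasible for n={n}; "
            f"maximum feasible octave is {max_feasible_level(n, bank)}")
    vals = np.zeros((M, M))
    if basis == "wavelet":
        coeffs = [dtcwt_forward(ts.data[m], J, bank) for m in range(M)]
        autos = [wavelet_cross_spectrum(c, c) for c in coeffs]
        for a in range(M):
            for b in range(a + 1, M):
                if index_kind == "wPLI":
                    prof = w_wpli(coeffs[a], coeffs[b])
                else:
                    Sab = wavelet_cross_spectrum(coeffs[a], coeffs[b])
                    prof = (w_coh if index_kind == "COH" else w_icoh)(
                        autos[a], autos[b], Sab)
                vals[a, b] = vals[b, a] = band_average(prof, band)
    else:
        for a in range(M):
            for b in range(a + 1, M):
                prof = fourier_octave_profile(ts.data[a], ts.data[b],
                                              band.octaves, bank.f0,
                                              window_factor=window_factor)
                vals[a, b] = vals[b, a] = band_average(prof[index_kind], band)
    np.fill_diagonal(vals, np.nan)
    return ConnectivityMatrix(values=vals, index=index_kind, basis=basis,
                              band=band, labels=list(ts.labels))


def _binarize_at_density(w: np.ndarray, density: float) -> np.ndarray:
    """Keep the strongest edges to reach the requested density (at least 1)."""
    M = w.shape[0]
    iu = np.triu_indices(M, k=1)
    n_possible = len(iu[0])
    k = max(1, int(round(density * n_possible)))
    order = np.argsort(w[iu])[::-1]
    adj = np.zeros_like(w, dtype=bool)
    keep = order[:k]
    adj[iu[0][keep], iu[1][keep]] = True
    return adj | adj.T


def eco_filter(cm: ConnectivityMatrix | np.ndarray,
               densities: np.ndarray | None = None
               ) -> tuple[np.ndarray, float]:
    """Efficiency-cost-optimization thresholding.

    Sweeps densities {2/M, 4/M, ..., <= 0.5}, keeps the strongest edges at
    each, scores J(d) = (E_global + E_local) / d on the binary graph, and
    returns (adjacency, chosen density); ties go to the sparser network.
    An all-zero matrix yields an empty network with a warning.
    """
    w = cm.values.copy() if isinstance(cm, ConnectivityMatrix) else \
        np.asarray(cm, dtype=float).copy()
    M = w.shape[0]
    w = np.abs(w)
    np.fill_diagonal(w, 0.0)
    w[np.isnan(w)] = 0.0
    if np.all(w == 0.0):
        warnings.warn("all-zero connectivity matrix: returning empty network")
        return np.zeros((M, M), dtype=bool), 0.0
    if densities is None:
        densities = np.arange(2, M + 1, 2) / M
        densities = densities[densities <= 0.5]
        if len(densities) == 0:
            densities = np.array([2.0 / M])
    best_J, best_adj, best_d = -np.inf, None, None
    for d in densities:                      # ascending: ties keep the sparser
        adj = _binarize_at_density(w, float(d))
        g = nx.from_numpy_array(adj)
        J = (nx.global_efficiency(g) + nx.local_efficiency(g)) / float(d)
        if J > best_J + 1e-12:
            best_J, best_adj, best_d = J, adj, float(d)
    return best_adj, best_d


def average_degree(adj: np.ndarray) -> float:
    """Mean number of connections per node, ``2 E / M``."""
    a = np.asarray(adj)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    a = a.astype(bool)
    if np.any(a != a.T):
        raise ValueError("adjacency must be symmetric")
    a = a & ~np.eye(a.shape[0], dtype=bool)
    edges = a.sum() // 2
    return 2.0 * edges / a.shape[0]


def degree_summary(adj: np.ndarray) -> dict[str, float]:
    """Mean degree together with the density normalization 2E / (M(M-1))."""
    mean_deg = average_degree(adj)
    M = np.asarray(adj).shape[0]
    return {"mean_degree": mean_deg, "density": mean_deg / (M - 1)}


def paired_group_contrast(condA, condB, alpha: float = 0.01) -> GroupContrast:
    """Edge-wise paired t-test of condition B minus A with BH-FDR control.

    ``condA`` and ``condB`` are subject-aligned lists of ConnectivityMatrix
    (or raw arrays).  Edges with zero difference variance are flagged and
    excluded from the correction.
    """
    A = np.array([c.values if isinstance(c, ConnectivityMatrix) else c
                  for c in condA], dtype=float)
    B = np.array([c.values if isinstance(c, ConnectivityMatrix) else c
                  for c in condB], dtype=float)
    if A.shape != B.shape:
        raise ValueError("conditions differ in shape")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    M = A.shape[1]
    iu = np.triu_indices(M, k=1)
    dA = A[:, iu[0], iu[1]]
    dB = B[:, iu[0], iu[1]]
    diff = dB - dA
    sd = diff.std(axis=0, ddof=1)
    flagged = sd == 0.0
    t = np.full(diff.shape[1], np.nan)
    p = np.ones(diff.shape[1])
    if np.any(~flagged):
        res = stats.ttest_rel(dB[:, ~flagged], dA[:, ~flagged], axis=0)
        t[~flagged] = res.statistic
        p[~flagged] = res.pvalue
    rejected = np.zeros(diff.shape[1], dtype=bool)
    p_adj = np.ones(diff.shape[1])
    if np.any(~flagged):
        rej, padj, _, _ = multipletests(p[~flagged], alpha=alpha,
                                        method="fdr_bh")
        rejected[~flagged] = rej
        p_adj[~flagged] = padj
    labels = (condA[0].labels if isinstance(condA[0], ConnectivityMatrix)
              else [f"ch{i}" for i in range(M)])
    return GroupContrast(t=t, p=p, p_adjusted=p_adj, rejected=rejected,
                         flagged=flagged, alpha=alpha,
                         edges=list(zip(iu[0].tolist(), iu[1].tolist())),
                         labels=list(labels), n_subjects=A.shape[0])


def correlate_deltas(u, v) -> tuple[float, float]:
    """Pearson correlation with two-sided p between per-subject changes."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or len(u) < 3:
        raise ValueError("need two equal-length 1-D sequences of length >= 3")
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ValueError("inputs contain non-finite values")
    if u.std() == 0.0 or v.std() == 0.0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(u, v)
    return float(r), float(p)
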