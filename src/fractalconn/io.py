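"""Plain-text I/O: TSV time series, long-format index tables, matrices."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .indices import ConnectivityProfile
from .network import ConnectivityMatrix, GroupContrast
from .simulate import TimeSeriesSet
from .transform import ScaleBand

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "write_profiles",
    "read_matrix",
    "write_matrix",
    "write_contrast",
    "write_manifest",
]


def write_timeseries(ts: TimeSeriesSet, path) -> None:
    """TSV dialect: a ``# fs=<Hz>`` comment line, a label header row, then
    one row per sample with one column per channel (17 significant digits,
    lossless for doubles)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={ts.fs:.17g}\n")
        fh.write("\t".join(ts.labels) + "\n")
        np.savetxt(fh, ts.data.T, fmt="%.17g", delimiter="\t")


def read_timeseries(path) -> TimeSeriesSet:
    """Read the TSV dialect written by :func:`write_timeseries`."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
        if not first.startswith("# fs="):
            raise ValueError(f"{path}: missing '# fs=' header line")
        fs = float(first.split("=", 1)[1])
        labels = fh.readline().strip().split("\t")
        rows = []
        width = len(labels)
        for lineno, line in enumerate(fh, start=3):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != width:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(parts)} fields, "
                    f"expected {width})")
            rows.append([float(p) for p in parts])
    data = np.asarray(rows, dtype=float).T
    return TimeSeriesSet(data=data, fs=fs, labels=labels)


def write_profiles(profiles: list[ConnectivityProfile], path) -> None:
    """Long-format table: pair, basis, index, octave-or-frequency, value,
    flagged.  Complex values are written as modulus and phase columns."""
    rows = []
    for p in profiles:
        axis = p.octaves if p.octaves is not None else p.frequencies
        axis_name = "octave" if p.octaves is not None else "frequency_hz"
        for i, a in enumerate(axis):
            v = p.values[i]
            rows.append({
                "pair": f"{p.pair[0]}|{p.pair[1]}", "basis": p.basis,
                "index": p.index, "axis": axis_name, "position": a,
                "value": float(np.abs(v)) if np.iscomplexobj(p.values) else float(v),
                "phase": float(np.angle(v)) if np.iscomplexobj(p.values) else 0.0,
                "flagged": bool(p.flagged[i]),
            })
    cols = ["pair", "basis", "index", "axis", "position", "value", "phase",
            "flagged"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_matrix(cm: ConnectivityMatrix, path) -> None:
    """Square TSV with label header; NaN marks the undefined diagonal."""
    df = pd.DataFrame(cm.values, index=cm.labels, columns=cm.labels)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix(path, index: str = "", basis: str = "wavelet",
                band: ScaleBand | None = None) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    band = band or ScaleBand(1, 1)
    return ConnectivityMatrix(values=df.to_numpy(dtype=float), index=index,
                              basis=basis, band=band,
                              labels=[str(c) for c in df.columns])


def write_contrast(gc: GroupContrast, path) -> None:
    rows = []
    for i, (a, b) in enumerate(gc.edges):
        rows.append({
            "edge": f"{gc.labels[a]}|{gc.labels[b]}",
            "t": gc.t[i], "p": gc.p[i], "p_adj": gc.p_adjusted[i],
            "rejected": bool(gc.rejected[i]), "flagged": bool(gc.flagged[i]),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_manifest(config: dict, path) -> None:
    from . import __version__
    payload = {"package": "fractalconn", "version": __version__, **config}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=str) + "\n")
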