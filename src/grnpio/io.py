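"""File formats: profile CSV/TSV, network JSON/CSV/SIF, run reports.

Profiles are delimited text with a leading ``time`` column and one column per
gene; networks round-trip through a JSON document
``{"names": [...], "genes": [{"alpha", "beta", "g", "h"}, ...]}``, a flat CSV
(one row per gene) or a SIF-style edge list thresholded at the zero cutoff.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ExpressionProfile, GeneParameters, SSystemNetwork

__all__ = [
    "ProfileFormatError",
    "load_profile",
    "save_profile",
    "load_network",
    "save_network",
    "network_to_csv",
    "network_from_csv",
    "network_to_sif",
]


class ProfileFormatError(ValueError):
    """A profile file violates the expected layout."""


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def load_profile(path, sep: str | None = None) -> ExpressionProfile:
    """Read a delimited profile; first column ``time``, one row per point.

    Malformed files raise :class:`ProfileFormatError` naming the offending
    row and column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    if df.shape[1] < 2:
        raise ProfileFormatError(f"{path}: need a time column plus >= 1 gene column")
    if df.columns[0].strip().lower() != "time":
        raise ProfileFormatError(f"{path}: first column must be 'time', got {df.columns[0]!r}")
    na = df.isna()
    if na.any().any():
        row = int(np.argmax(na.any(axis=1).values))
        col = df.columns[int(np.argmax(na.iloc[row].values))]
        raise ProfileFormatError(f"{path}: missing value at row {row}, column {col!r}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ProfileFormatError(f"{path}: column {col!r} is not numeric")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.any(values < 0):
        r, c = np.argwhere(values < 0)[0]
        raise ProfileFormatError(
            f"{path}: negative concentration at row {r}, column {df.columns[c + 1]!r}")
    times = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ProfileFormatError(f"{path}: time stamps must be strictly increasing")
    try:
        return ExpressionProfile(values, times, tuple(df.columns[1:]))
    except ValueError as exc:
        raise ProfileFormatError(f"{path}: {exc}") from exc


def save_profile(path, profile: ExpressionProfile, sep: str | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(profile.values, columns=list(profile.names))
    df.insert(0, "time", profile.times)
    df.to_csv(path, sep=_sep_for(path, sep), index=False)


# -- networks ----------------------------------------------------------------

def save_network(path, net: SSystemNetwork) -> None:
    doc = {
        "names": list(net.names),
        "genes": [
            {"alpha": gp.alpha, "beta": gp.beta,
             "g": gp.g.tolist(), "h": gp.h.tolist()}
            for gp in net.genes
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_network(path) -> SSystemNetwork:
    doc = json.loads(Path(path).read_text())
    genes = [
        GeneParameters(i, float(entry["alpha"]), float(entry["beta"]),
                       np.asarray(entry["g"], float), np.asarray(entry["h"], float))
        for i, entry in enumerate(doc["genes"])
    ]
    return SSystemNetwork(genes, doc.get("names"))


def network_to_csv(path, net: SSystemNetwork) -> None:
    """Flat layout: one row per gene -- name, alpha, beta, g1..gN, h1..hN."""
    n = net.n
    cols = (["name", "alpha", "beta"]
            + [f"g{j + 1}" for j in range(n)] + [f"h{j + 1}" for j in range(n)])
    rows = [[net.names[i], gp.alpha, gp.beta, *gp.g, *gp.h]
            for i, gp in enumerate(net.genes)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def network_from_csv(path) -> SSystemNetwork:
    df = pd.read_csv(path)
    n = (df.shape[1] - 3) // 2
    genes = []
    for i, row in df.iterrows():
        g = row.iloc[3:3 + n].to_numpy(dtype=float)
        h = row.iloc[3 + n:3 + 2 * n].to_numpy(dtype=float)
        genes.append(GeneParameters(i, float(row["alpha"]), float(row["beta"]), g, h))
    return SSystemNetwork(genes, tuple(df["name"]))


def network_to_sif(path, net: SSystemNetwork, zero_threshold: float = 0.1) -> None:
    """Edge list: source, process tag with sign, target (tab-separated).

    Synthesis edges come from g, degradation edges from h; the edge sign is
    the sign of the kinetic order (activation/repression).
    """
    lines = []
    for process, mat in (("synthesis", net.g), ("degradation", net.h)):
        for i in range(net.n):
            for j in range(net.n):
                v = mat[i, j]
                if abs(v) >= zero_threshold:
                    tag = f"{process}{'+' if v > 0 else '-'}"
                    lines.append(f"{net.names[j]}\t{tag}\t{net.names[i]}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
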