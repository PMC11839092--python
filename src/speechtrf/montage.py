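"""Idealized 64-channel montage: labels, top-view coordinates, channel
groups, and a distance-threshold adjacency graph.

Coordinates are parsed from standard 10-10 labels (row letter -> y,
digit -> x), good enough for grouping and neighbor relations; exact sensor
geometry is irrelevant downstream. Both the group mapping and the montage
are also shipped as editable JSON package data; loaders accept a path to a
user file.
"""

from __future__ import annotations

import json
import re
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "BIOSEMI64_LABELS",
    "default_montage",
    "default_channel_groups",
    "build_adjacency",
    "load_channel_groups",
    "load_montage",
]

BIOSEMI64_LABELS: tuple[str, ...] = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz", "Fpz",
    "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8", "FC6",
    "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4",
    "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)

_ROW_Y = {
    "Fp": 0.90, "AF": 0.70, "F": 0.50, "FT": 0.30, "FC": 0.30, "C": 0.0,
    "T": 0.0, "TP": -0.30, "CP": -0.30, "P": -0.55, "PO": -0.75, "O": -0.90,
    "I": -1.0,
}


def _label_xy(label: str) -> tuple[float, float]:
    m = re.fullmatch(r"([A-Za-z]+)(z|\d+)", label)
    if m is None:
        raise ValueError(f"cannot parse channel label {label!r}")
    row, col = m.group(1), m.group(2)
    y = _ROW_Y[row if row in _ROW_Y else row.upper()]
    if col == "z":
        x = 0.0
    else:
        d = int(col)
        side = -1.0 if d % 2 == 1 else 1.0  # odd = left, even = right
        ring = (d + 1) // 2
        x = side * min(0.18 * ring, 1.0)
        if row in ("T", "TP", "FT"):
            x = side * 0.85
        if row == "Fp":
            x = side * 0.30
        if d >= 9:  # P9/P10 sit low and lateral
            x = side * 0.95
    return x, y


def default_montage() -> dict[str, tuple[float, float]]:
    """Label -> (x, y) top-view unit-circle coordinates."""
    return {lab: _label_xy(lab) for lab in BIOSEMI64_LABELS}


def default_channel_groups(
    montage: dict[str, tuple[float, float]] | None = None,
) -> dict[str, list[str]]:
    """Six disjoint scalp groups: left/right temporal, frontal, central,
    parietal, occipital. Partition by coordinate region."""
    if montage is None:
        montage = default_montage()
    groups: dict[str, list[str]] = {
        "left temporal": [], "frontal": [], "right temporal": [],
        "central": [], "parietal": [], "occipital": [],
    }
    for lab, (x, y) in montage.items():
        if x <= -0.62:
            groups["left temporal"].append(lab)
        elif x >= 0.62:
            groups["right temporal"].append(lab)
        elif y >= 0.4:
            groups["frontal"].append(lab)
        elif y >= -0.2:
            groups["central"].append(lab)
        elif y >= -0.65:
            groups["parietal"].append(lab)
        else:
            groups["occipital"].append(lab)
    return groups


def build_adjacency(montage: dict[str, tuple[float, float]],
                    threshold: float = 0.40) -> dict[str, set[str]]:
    """Symmetric neighbor sets: channels within ``threshold`` distance."""
    labels = list(montage)
    xy = np.array([montage[l] for l in labels])
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    adj: dict[str, set[str]] = {l: set() for l in labels}
    for i, li in enumerate(labels):
        for j in range(i + 1, len(labels)):
            if d[i, j] <= threshold:
                adj[li].add(labels[j])
                adj[labels[j]].add(li)
    return adj


def _load_json(name: str, path: str | Path | None):
    if path is not None:
        return json.loads(Path(path).read_text())
    ref = resources.files("speechtrf").joinpath("data", name)
    return json.loads(ref.read_text())


def load_channel_groups(path: str | Path | None = None) -> dict[str, list[str]]:
    """Group mapping from JSON (package default or a user file)."""
    return {k: list(v) for k, v in _load_json("channel_groups.json", path).items()}


def load_montage(path: str | Path | None = None) -> dict[str, tuple[float, float]]:
    return {k: (float(v[0]), float(v[1]))
            for k, v in _load_json("montage64.json", path).items()}
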