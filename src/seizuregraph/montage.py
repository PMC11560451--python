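"""The 22-channel bipolar longitudinal montage and its schematic geometry.

Channels are bipolar derivations of the international 10-20 system (the
CHB-MIT longitudinal montage). Each derivation is treated as a graph node
located at the midpoint of its two electrode positions on a standard
top-view head schematic (unit head circle, +y toward the nasion, +x toward
the right ear; coordinates are unitless).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The canonical ordered 22 bipolar derivations.
CANONICAL_CHANNELS: tuple[str, ...] = (
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
    "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
    "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
    "FZ-CZ", "CZ-PZ",
    "P7-T7", "T7-FT9", "FT9-FT10", "FT10-T8",
)


def _ring(angle_deg: float, radius: float = 1.0) -> tuple[float, float]:
    a = math.radians(angle_deg)
    return radius * math.cos(a), radius * math.sin(a)


# Top-view schematic positions of the 10-20 electrodes used by the montage.
# Circumferential electrodes sit on the unit circle at the textbook 36-degree
# spacing; FT9/FT10 lie on an inferior ring just outside it.
ELECTRODE_POSITIONS: dict[str, tuple[float, float]] = {
    "FP1": _ring(108), "FP2": _ring(72),
    "F7": _ring(144), "F8": _ring(36),
    "T7": _ring(180), "T8": _ring(0),
    "P7": _ring(216), "P8": _ring(-36),
    "O1": _ring(252), "O2": _ring(-72),
    "FZ": (0.0, 0.5), "CZ": (0.0, 0.0), "PZ": (0.0, -0.5),
    "F3": (-0.405, 0.544), "F4": (0.405, 0.544),
    "C3": (-0.5, 0.0), "C4": (0.5, 0.0),
    "P3": (-0.405, -0.544), "P4": (0.405, -0.544),
    "FT9": _ring(162, 1.2), "FT10": _ring(18, 1.2),
}

_DUP_SUFFIX = re.compile(r"-\d+$")


def normalize_channel_name(name: str) -> str:
    """Normalize an EDF channel label to canonical form.

    Uppercases, strips whitespace, removes a trailing ``-<digit>`` duplicate
    suffix (as in ``"T8-P8-0"``), and unifies the T3/T4/T5/T6 aliases of
    T7/T8/P7/P8.
    """
    s = re.sub(r"\s+", "", name.upper())
    s = _DUP_SUFFIX.sub("", s)
    for old, new in (("T3", "T7"), ("T4", "T8"), ("T5", "P7"), ("T6", "P8")):
        s = re.sub(rf"\b{old}\b", new, s)
    return s


@dataclass
class ElectrodeLayout:
    """2-D coordinates of bipolar-derivation centers.

    ``coords[i]`` is the midpoint of the two 10-20 electrode positions
    forming derivation ``names[i]`` on the head schematic.
    """

    names: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (len(self.names), 2):
            raise ValueError("need one (x, y) coordinate per channel name")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": self.names, "x": self.coords[:, 0], "y": self.coords[:, 1]}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "ElectrodeLayout":
        df = pd.read_csv(path)
        return ElectrodeLayout(df["name"].tolist(), df[["x", "y"]].to_numpy())


def canonical_layout(channels: tuple[str, ...] = CANONICAL_CHANNELS) -> ElectrodeLayout:
    """Build the layout of derivation midpoints for the canonical montage.

    Note that ``T7-P7`` and ``P7-T7`` share a midpoint: the montage reuses
    that electrode pair in both chains, so the distance graph legitimately
    contains one coincident node pair.
    """
    coords = []
    for ch in channels:
        a, b = ch.split("-", 1)
        try:
            pa, pb = ELECTRODE_POSITIONS[a], ELECTRODE_POSITIONS[b]
        except KeyError as e:
            raise KeyError(f"no schematic position for electrode {e.args[0]!r}") from e
        coords.append(((pa[0] + pb[0]) / 2.0, (pa[1] + pb[1]) / 2.0))
    return ElectrodeLayout(list(channels), np.array(coords))
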