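"""Template 10-10 electrode montage with unit-sphere positions.

Positions are schematic: each label is placed on a planar 10-10 grid
(anterior-posterior row, left-right column) and projected onto the unit
sphere so that the outermost ring sits on the equator.  This is sufficient
for topographic statistics and synthetic map generation; no physical
head-model claims are made.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChannelMontage", "default_montage", "DEFAULT_LABELS"]

# Row letter -> anterior-posterior grid coordinate (anterior positive).
_ROW_Y = {
    "Fp": 4.0, "AF": 3.0, "F": 2.0, "FC": 1.0, "FT": 1.0,
    "C": 0.0, "T": 0.0, "CP": -1.0, "TP": -1.0,
    "P": -2.0, "PO": -3.0, "O": -4.0,
}

# 61-channel template: a 64-channel 10-10 cap with the mastoids (TP9/TP10)
# and the ground electrode excluded, as configured in the analyses here.
DEFAULT_LABELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)


def _parse_label(label: str) -> tuple[str, float]:
    """Split a 10-10 label into (row letters, signed column coordinate)."""
    i = 0
    while i < len(label) and not (label[i].isdigit() or label[i] == "z"):
        i += 1
    row, col = label[:i], label[i:]
    if row not in _ROW_Y:
        raise ValueError(f"unrecognized 10-10 label: {label!r}")
    if col == "z":
        x = 0.0
    else:
        n = int(col)
        x = float((n + 1) // 2)
        if n % 2 == 1:  # odd numbers are left-hemisphere
            x = -x
        # T7/T8, FT/TP rows occupy the outermost (10%) ring
        if row in ("T", "FT", "TP"):
            x = -4.0 if x < 0 else 4.0
    return row, x


def _grid_to_sphere(x: float, y: float) -> tuple[float, float, float]:
    u, v = x / 5.0, y / 5.0
    rho = float(np.hypot(u, v))
    if rho < 1e-12:
        return 0.0, 0.0, 1.0
    theta = min(rho, 1.0) * np.pi / 2.0  # polar angle from vertex
    s = np.sin(theta) / rho
    return float(u * s), float(v * s), float(np.cos(theta))


@dataclass(frozen=True)
class ChannelMontage:
    """Ordered channel labels with unit-sphere 3-D positions.

    Parameters
    ----------
    names : tuple of str
        Unique 10-10 channel labels (x = right, y = anterior, z = up).
    positions : ndarray, shape (n_channels, 3)
        Unit-norm positions, one row per label.
    """

    names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        pos = np.asarray(self.positions, dtype=float)
        if len(set(names)) != len(names):
            raise ValueError("montage labels must be unique")
        if pos.shape != (len(names), 3):
            raise ValueError(
                f"positions shape {pos.shape} does not match {len(names)} labels"
            )
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, label: str) -> int:
        try:
            return self.names.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def indices(self, labels) -> np.ndarray:
        return np.array([self.index(lbl) for lbl in labels], dtype=int)

    def subset(self, labels) -> "ChannelMontage":
        idx = self.indices(labels)
        return ChannelMontage(tuple(labels), self.positions[idx])

    def geodesic_distances(self, anchor: np.ndarray) -> np.ndarray:
        """Great-circle distance (radians) of every electrode to ``anchor``."""
        a = np.asarray(anchor, dtype=float)
        a = a / np.linalg.norm(a)
        cosd = np.clip(self.positions @ a, -1.0, 1.0)
        return np.arccos(cosd)


def default_montage(labels=DEFAULT_LABELS) -> ChannelMontage:
    """Build the template montage for the given 10-10 labels."""
    parsed = [_parse_label(lbl) for lbl in labels]
    pos = np.array([_grid_to_sphere(x, _ROW_Y[row]) for row, x in parsed])
    return ChannelMontage(tuple(labels), pos)
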