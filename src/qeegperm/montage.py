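"""The 19-channel 10-20 montage: labels, 2-D scalp positions, spatial adjacency.

Positions are an azimuthal-equidistant projection of the standard 10-20
electrode coordinates (vertex at the origin, nose along +y), rescaled so the
outermost electrode sits at radius 0.5.  Two channels are spatial neighbors
when their projected distance is below ``DEFAULT_NEIGHBOR_RADIUS``; the
threshold is exposed so a different neighborhood can be injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical ordering of the 19-channel 10-20 montage used throughout.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

# Projection of the standard 10-20 coordinates (x: left->right, y: back->front).
_POSITIONS_2D: dict[str, tuple[float, float]] = {
    "Fp1": (-0.1596, +0.4550),
    "Fp2": (+0.1600, +0.4548),
    "F7":  (-0.4276, +0.2585),
    "F3":  (-0.2104, +0.2224),
    "Fz":  (+0.0011, +0.2110),
    "F4":  (+0.2166, +0.2269),
    "F8":  (+0.4272, +0.2598),
    "T3":  (-0.4823, -0.0918),
    "C3":  (-0.2305, -0.0410),
    "Cz":  (+0.0012, -0.0267),
    "C4":  (+0.2363, -0.0384),
    "T4":  (+0.4837, -0.0854),
    "T5":  (-0.3274, -0.3320),
    "P3":  (-0.1695, -0.2519),
    "Pz":  (+0.0009, -0.2269),
    "P4":  (+0.1757, -0.2480),
    "T6":  (+0.3298, -0.3298),
    "O1":  (-0.1106, -0.4228),
    "O2":  (+0.1124, -0.4224),
}

DEFAULT_NEIGHBOR_RADIUS = 0.35

LEFT_TEMPOROFRONTAL = ("F7", "T3", "T5")
RIGHT_OCCIPITOTEMPORAL = ("O2", "T6")


@dataclass
class MontageGraph:
    """Channel layout plus a symmetric, irreflexive neighbor relation."""

    channels: tuple[str, ...]
    positions: np.ndarray          # (n_channels, 2)
    adjacency: np.ndarray          # (n_channels, n_channels) bool

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        n = len(self.channels)
        if self.positions.shape != (n, 2):
            raise ValueError("positions must be (n_channels, 2)")
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square over channels")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("adjacency must be irreflexive")
        if n > 1 and not np.all(self.adjacency.sum(axis=1) >= 1):
            lonely = [c for c, d in zip(self.channels, self.adjacency.sum(axis=1)) if d == 0]
            raise ValueError(f"channels without neighbors: {lonely}")

    def index(self, channel: str) -> int:
        return self.channels.index(channel)

    def neighbors(self, channel: str) -> list[str]:
        i = self.index(channel)
        return [self.channels[j] for j in np.where(self.adjacency[i])[0]]

    @classmethod
    def standard_1020(cls, neighbor_radius: float = DEFAULT_NEIGHBOR_RADIUS) -> "MontageGraph":
        """The 19-channel montage with distance-threshold adjacency."""
        pos = np.array([_POSITIONS_2D[c] for c in CHANNELS_1020])
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        adj = (d < neighbor_radius) & (d > 0)
        return cls(channels=CHANNELS_1020, positions=pos, adjacency=adj)


def check_montage_labels(labels) -> None:
    """Require exactly the 19-channel 10-20 set (any order)."""
    if sorted(labels) != sorted(CHANNELS_1020):
        raise ValueError(
            "channel labels must be the 19-channel 10-20 set "
            f"{sorted(CHANNELS_1020)}, got {sorted(labels)}"
        )
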