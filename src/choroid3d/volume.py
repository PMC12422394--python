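"""Core volume containers shared by every stage of the pipeline.

Arrays are indexed ``[bscan, axial, ascan]`` throughout the package, and all
physical coordinates are micrometres in the same axis order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

LATERALITIES = ("OD", "OS")


class Spacing(NamedTuple):
    """Voxel spacing in micrometres, aligned with the array axes.

    ``bscan`` is the distance between consecutive B-scans, ``axial`` the
    depth sampling within an A-scan, ``ascan`` the lateral sampling within
    a B-scan.
    """

    bscan: float
    axial: float
    ascan: float

    def validate(self) -> "Spacing":
        if any(not np.isfinite(s) or s <= 0 for s in self):
            raise ValueError(f"spacing components must be positive, got {tuple(self)}")
        return self

    @property
    def voxel_volume(self) -> float:
        return float(self.bscan * self.axial * self.ascan)

    @property
    def minimum(self) -> float:
        return float(min(self))

    def as_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)


@dataclass
class OCTVolume:
    """A 3D OCT intensity stack with physical metadata.

    ``intensities`` has shape ``(n_bscans, n_axial, n_ascans)`` with values
    in [0, 1]. ``fovea_index`` is the ``(bscan, ascan)`` en face location of
    the fovea; it defaults to the field centre.
    """

    intensities: np.ndarray
    spacing: Spacing
    laterality: str = "OD"
    fovea_index: tuple[int, int] | None = None
    id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array [bscan, axial, ascan]")
        lo = float(self.intensities.min())
        hi = float(self.intensities.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"intensities must lie in [0, 1], got range [{lo}, {hi}]")
        self.spacing = Spacing(*self.spacing).validate()
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be one of {LATERALITIES}")
        nb, _, na = self.intensities.shape
        if self.fovea_index is None:
            self.fovea_index = (nb // 2, na // 2)
        fb, fa = self.fovea_index
        if not (0 <= fb < nb and 0 <= fa < na):
            raise ValueError(f"fovea_index {self.fovea_index} outside grid {(nb, na)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def n_bscans(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_axial(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_ascans(self) -> int:
        return self.intensities.shape[2]

    def enface_extent_um(self) -> tuple[float, float]:
        """Physical (bscan-direction, ascan-direction) extent of the en face field."""
        return (
            self.n_bscans * self.spacing.bscan,
            self.n_ascans * self.spacing.ascan,
        )
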