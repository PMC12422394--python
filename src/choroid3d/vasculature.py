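"""3D vasculature labelling, optic-disc exclusion, en face projections and
the fovea-centered five-sector grid.

The grid partitions the en face plane into a central disc (default 4 mm
diameter) plus four wedges cut by the 45-degree diagonals through the fovea;
the left/right wedges map to nasal/temporal according to laterality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import LATERALITIES, Spacing

SECTOR_NAMES = ("central", "superior", "inferior", "nasal", "temporal")
SECTOR_CODES = {name: i for i, name in enumerate(SECTOR_NAMES)}


@dataclass(frozen=True)
class SectorGrid:
    """Fovea-centered en face partition into five sectors.

    ``fovea_um`` is the (bscan-direction, ascan-direction) position in µm.
    Smaller bscan coordinates are superior. Pixels exactly on a diagonal are
    assigned to the superior/inferior wedges (fixed priority), so the five
    sectors partition the plane exactly.
    """

    fovea_um: tuple[float, float]
    central_radius_um: float = 2000.0
    laterality: str = "OD"
    nasal_side: str | None = None  # "right" | "left"; None -> laterality default

    def __post_init__(self) -> None:
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be one of {LATERALITIES}")
        if self.nasal_side not in (None, "right", "left"):
            raise ValueError("nasal_side must be 'right', 'left' or None")
        if self.central_radius_um <= 0:
            raise ValueError("central_radius_um must be positive")

    @property
    def resolved_nasal_side(self) -> str:
        if self.nasal_side is not None:
            return self.nasal_side
        return "right" if self.laterality == "OD" else "left"

    @property
    def central_diameter_mm(self) -> float:
        return 2.0 * self.central_radius_um / 1000.0

    def sector_codes(self, y_um: np.ndarray, x_um: np.ndarray) -> np.ndarray:
        """Vectorized sector code for en face µm coordinates."""
        y = np.asarray(y_um, dtype=float)
        x = np.asarray(x_um, dtype=float)
        dy = y - self.fovea_um[0]
        dx = x - self.fovea_um[1]
        codes = np.empty(np.broadcast(dy, dx).shape, dtype=np.int8)
        dy, dx = np.broadcast_arrays(dy, dx)
        vertical = np.abs(dy) >= np.abs(dx)  # diagonal ties -> superior/inferior
        codes[...] = 0
        codes[vertical & (dy < 0)] = SECTOR_CODES["superior"]
        codes[vertical & (dy > 0)] = SECTOR_CODES["inferior"]
        nasal_right = self.resolved_nasal_side == "right"
        right = ~vertical & (dx > 0)
        left = ~vertical & (dx < 0)
        codes[right] = SECTOR_CODES["nasal" if nasal_right else "temporal"]
        codes[left] = SECTOR_CODES["temporal" if nasal_right else "nasal"]
        central = dy ** 2 + dx ** 2 <= self.central_radius_um ** 2
        codes[central] = SECTOR_CODES["central"]
        return codes

    def sector_of(self, y_um: float, x_um: float) -> str:
        return SECTOR_NAMES[int(self.sector_codes(np.float64(y_um), np.float64(x_um)))]

    def label_map(self, enface_shape: tuple[int, int], spacing: Spacing) -> np.ndarray:
        """(n_bscans, n_ascans) int8 map of sector codes at pixel centres."""
        spacing = Spacing(*spacing)
        y = np.arange(enface_shape[0]) * spacing.bscan
        x = np.arange(enface_shape[1]) * spacing.ascan
        return self.sector_codes(y[:, None], x[None, :])


def build_sector_grid(enface_shape: tuple[int, int], spacing: Spacing,
                      fovea_index: tuple[int, int], laterality: str = "OD",
                      central_radius_um: float = 2000.0,
                      nasal_side: str | None = None) -> SectorGrid:
    """Construct the default five-sector grid for a volume's en face field."""
    spacing = Spacing(*spacing).validate()
    fb, fa = fovea_index
    nb, na = enface_shape
    if not (0 <= fb < nb and 0 <= fa < na):
        raise ValueError(f"fovea index {fovea_index} outside en face field {enface_shape}")
    return SectorGrid(
        fovea_um=(fb * spacing.bscan, fa * spacing.ascan),
        central_radius_um=central_radius_um,
        laterality=laterality,
        nasal_side=nasal_side,
    )


@dataclass
class Vasculature3D:
    """Labelled 26-connected vessel components with physical volumes."""

    labels: np.ndarray  # int (bscan, axial, ascan); 0 = background
    volumes_um3: np.ndarray  # indexed by label; entry 0 is 0
    spacing: Spacing
    choroid_band: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return int(self.labels.max())

    def component_mask(self, label: int) -> np.ndarray:
        return self.labels == label


def mask_optic_disc(mask, disc):
    """Clear every luminal voxel under the optic-disc en face footprint.

    ``disc`` is either ``((y_um, x_um), radius_um)`` or a boolean en face
    raster of shape (n_bscans, n_ascans). Idempotent; other voxels untouched.
    """
    from .binarization import VesselMask  # local import to avoid a cycle

    nb, _, na = mask.luminal.shape
    if isinstance(disc, np.ndarray):
        footprint = disc.astype(bool)
        if footprint.shape != (nb, na):
            raise ValueError("disc raster shape must match the en face field")
    else:
        (cy, cx), radius = disc
        y = np.arange(nb) * mask.spacing.bscan
        x = np.arange(na) * mask.spacing.ascan
        footprint = ((y[:, None] - cy) ** 2 + (x[None, :] - cx) ** 2) <= radius ** 2
    luminal = mask.luminal & ~footprint[:, None, :]
    return VesselMask(luminal=luminal, choroid_band=mask.choroid_band,
                      spacing=mask.spacing)


def label_vasculature(mask) -> Vasculature3D:
    """Label 26-connected luminal components; volumes use the anisotropic
    voxel volume. An empty mask yields an empty (valid) vasculature."""
    labels, n = ndimage.label(mask.luminal, structure=np.ones((3, 3, 3)))
    counts = np.bincount(labels.ravel(), minlength=n + 1).astype(float)
    counts[0] = 0.0
    return Vasculature3D(labels=labels,
                         volumes_um3=counts * mask.spacing.voxel_volume,
                         spacing=mask.spacing,
                         choroid_band=mask.choroid_band)


def make_enface(data: np.ndarray, band: np.ndarray | None = None) -> np.ndarray:
    """En face projection along the axial axis.

    Boolean input -> max projection; intensity input -> mean projection,
    restricted to the choroid band when one is given (columns with no band
    voxels become NaN).
    """
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError("expected a 3D array [bscan, axial, ascan]")
    if data.dtype == bool:
        return data.any(axis=1)
    if band is None:
        return data.mean(axis=1)
    band = band.astype(bool)
    counts = band.sum(axis=1).astype(float)
    sums = np.where(band, data, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def aggregate_by_sector(map2d: np.ndarray, grid: SectorGrid,
                        spacing: Spacing) -> dict[str, float]:
    """Per-sector arithmetic means of an en face scalar field, plus a
    ``mean`` entry = unweighted mean of the five sector values. Sectors with
    no defined values propagate as NaN and drop out of the global mean."""
    map2d = np.asarray(map2d, dtype=float)
    sector_map = grid.label_map(map2d.shape, spacing)
    out: dict[str, float] = {}
    for code, name in enumerate(SECTOR_NAMES):
        vals = map2d[sector_map == code]
        vals = vals[np.isfinite(vals)]
        out[name] = float(vals.mean()) if vals.size else float("nan")
    sector_vals = [out[n] for n in SECTOR_NAMES if np.isfinite(out[n])]
    out["mean"] = float(np.mean(sector_vals)) if sector_vals else float("nan")
    return out
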