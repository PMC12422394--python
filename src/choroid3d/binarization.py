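"""Luminal (vessel) voxel segmentation inside the choroid band.

Phansalkar adaptive local thresholding is applied densely per B-scan (one
window centred on every pixel, edges replicated), the resulting mask is
intersected with the choroid band, opened in-plane and filtered by
26-connected component size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import ChoroidBoundaries
from .vasculature import SectorGrid, SECTOR_NAMES
from .volume import OCTVolume, Spacing


@dataclass
class BinarizationParams:
    """Phansalkar constants default to the original publication's
    k=0.25, R=0.5, p=2, q=10; only the 16x16 window is fixed upstream.
    An even window is centred by bumping it to the next odd size."""

    window: int = 16
    k: float = 0.25
    r: float = 0.5
    p: float = 2.0
    q: float = 10.0
    median_size: int = 3  # in-plane median denoise per B-scan; 1 disables
    opening_size: int = 3  # in-plane (axial x ascan) opening
    min_component_voxels: int = 50

    def __post_init__(self) -> None:
        if self.effective_window < 3:
            raise ValueError("window must be >= 3")
        if self.r <= 0:
            raise ValueError("R must be > 0")
        if self.min_component_voxels < 1:
            raise ValueError("min_component_voxels must be >= 1")

    @property
    def effective_window(self) -> int:
        return self.window if self.window % 2 == 1 else self.window + 1


@dataclass
class VesselMask:
    """Binary luminal voxels and the choroid band they live in."""

    luminal: np.ndarray  # bool (bscan, axial, ascan)
    choroid_band: np.ndarray
    spacing: Spacing

    def __post_init__(self) -> None:
        self.luminal = np.asarray(self.luminal, dtype=bool)
        self.choroid_band = np.asarray(self.choroid_band, dtype=bool)
        if self.luminal.shape != self.choroid_band.shape:
            raise ValueError("luminal and band masks must share a shape")
        if (self.luminal & ~self.choroid_band).any():
            raise ValueError("luminal voxels must lie inside the choroid band")
        self.spacing = Spacing(*self.spacing).validate()


def _window_stats(image: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Local mean and standard deviation over a dense sliding window.

    Computed via integral images on an edge-replicated pad, so every pixel
    sees a full ``window x window`` neighbourhood.
    """
    pad = window // 2
    padded = np.pad(image.astype(float), pad, mode="edge")

    def integral(a: np.ndarray) -> np.ndarray:
        out = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
        np.cumsum(np.cumsum(a, axis=0), axis=1, out=out[1:, 1:])
        return out

    s1 = integral(padded)
    s2 = integral(padded ** 2)
    h, w = image.shape

    def box(s: np.ndarray) -> np.ndarray:
        return (s[window:window + h, window:window + w]
                - s[:h, window:window + w]
                - s[window:window + h, :w]
                + s[:h, :w])

    n = float(window * window)
    m = box(s1) / n
    var = np.maximum(box(s2) / n - m ** 2, 0.0)
    return m, np.sqrt(var)


def phansalkar_threshold(bscan: np.ndarray, params: BinarizationParams,
                         return_threshold: bool = False):
    """Dense Phansalkar thresholding of one B-scan.

    Per-pixel threshold ``T = m * (1 + p*exp(-q*m) + k*(s/R - 1))`` with m, s
    the local mean and standard deviation of the window centred at the pixel;
    a pixel is luminal iff its intensity is strictly below T (lumens are
    hyporeflective).
    """
    bscan = np.asarray(bscan, dtype=float)
    if bscan.ndim != 2:
        raise ValueError("expected a 2D B-scan")
    w = params.effective_window
    if w > min(bscan.shape):
        raise ValueError(
            f"window {w} larger than image {bscan.shape}")
    m, s = _window_stats(bscan, w)
    thresh = m * (1.0 + params.p * np.exp(-params.q * m)
                  + params.k * (s / params.r - 1.0))
    mask = bscan < thresh
    if return_threshold:
        return mask, thresh
    return mask


def binarize_vessels(volume: OCTVolume, boundaries: ChoroidBoundaries,
                     params: BinarizationParams | None = None) -> VesselMask:
    """Segment luminal voxels: Phansalkar per B-scan, intersect with the
    choroid band, then morphological opening and small-component removal."""
    params = params or BinarizationParams()
    band = boundaries.band_mask(volume.n_axial)
    if not band.any():
        raise ValueError("empty choroid band")

    data = volume.intensities
    if params.median_size > 1:
        data = ndimage.median_filter(
            data, size=(1, params.median_size, params.median_size))

    luminal = np.zeros(volume.shape, dtype=bool)
    for b in range(volume.n_bscans):
        luminal[b] = phansalkar_threshold(data[b], params)
    luminal &= band

    if params.opening_size > 1:
        structure = np.ones((1, params.opening_size, params.opening_size), dtype=bool)
        luminal = ndimage.binary_opening(luminal, structure=structure)
        luminal &= band

    labels, n = ndimage.label(luminal, structure=np.ones((3, 3, 3)))
    if n:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        keep = sizes >= params.min_component_voxels
        luminal = keep[labels]
    return VesselMask(luminal=luminal, choroid_band=band, spacing=volume.spacing)


@dataclass
class CVIResult:
    """Choroidal vascularity index, overall and per sector (percent)."""

    global_pct: float
    per_sector: dict[str, float | None] | None = None

    @property
    def mean_of_sectors(self) -> float | None:
        if self.per_sector is None:
            return None
        vals = [v for v in self.per_sector.values() if v is not None]
        if not vals:
            return None
        return float(np.mean(vals))


def compute_cvi(mask: VesselMask, grid: SectorGrid | None = None) -> CVIResult:
    """CVI = 100 x luminal voxels / choroid-band voxels.

    With a grid, CVI is additionally computed within each sector's en face
    footprint; a sector with no band voxels is flagged missing (None), not
    zero.
    """
    band_total = int(mask.choroid_band.sum())
    if band_total == 0:
        raise ValueError("empty choroid band")
    global_pct = 100.0 * float(mask.luminal.sum()) / band_total
    if grid is None:
        return CVIResult(global_pct=global_pct)

    nb, _, na = mask.luminal.shape
    sector_map = grid.label_map((nb, na), mask.spacing)
    lum_cols = mask.luminal.sum(axis=1)
    band_cols = mask.choroid_band.sum(axis=1)
    per_sector: dict[str, float | None] = {}
    for code, name in enumerate(SECTOR_NAMES):
        sel = sector_map == code
        band_n = int(band_cols[sel].sum())
        if band_n == 0:
            per_sector[name] = None
        else:
            per_sector[name] = 100.0 * float(lum_cols[sel].sum()) / band_n
    return CVIResult(global_pct=global_pct, per_sector=per_sector)
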