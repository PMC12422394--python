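"""Choroid boundary delineation and thickness mapping.

Per B-scan classical pipeline: median denoising, contrast-limited adaptive
histogram equalization, Otsu binarization, morphological cleanup, largest
bright-band connected-component analysis for initial inner/outer estimates,
then robust locally weighted regression along each B-scan followed by a
second robust pass across B-scans for volumetric smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import exposure, filters
from statsmodels.nonparametric.smoothers_lowess import lowess

from .volume import OCTVolume, Spacing

log = logging.getLogger(__name__)


class DelineationError(RuntimeError):
    pass


@dataclass
class SegmentationParams:
    """Tunables of the boundary pipeline; no constant here is canonical and
    everything is config-exposed."""

    median_size: int = 3
    volumetric_median: bool = True  # 3D median pass before per-B-scan work
    clahe_clip: float = 0.01
    clahe_kernel: int | None = None  # None -> skimage default (1/8 of image)
    opening_size: int = 3
    closing_size: int = 5
    min_band_area_fraction: float = 0.02  # of the B-scan, else the B-scan failed
    lowess_frac: float = 0.3
    lowess_iters: int = 2
    max_failed_fraction: float = 0.25


@dataclass
class ChoroidBoundaries:
    """Inner/outer choroid surfaces as fractional axial pixels per A-scan."""

    inner: np.ndarray  # (n_bscans, n_ascans)
    outer: np.ndarray
    corrected: np.ndarray  # bool per B-scan
    n_axial: int

    def __post_init__(self) -> None:
        self.inner = np.asarray(self.inner, dtype=float)
        self.outer = np.asarray(self.outer, dtype=float)
        self.corrected = np.asarray(self.corrected, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if self.inner.shape != self.outer.shape:
            raise ValueError("inner and outer surfaces must share a shape")
        if not (np.isfinite(self.inner).all() and np.isfinite(self.outer).all()):
            raise ValueError("boundaries must be finite everywhere")
        bad = self.inner > self.outer
        if bad.any():
            b, a = (int(x[0]) for x in np.nonzero(bad))
            raise ValueError(f"inner > outer at (bscan={b}, ascan={a})")
        if self.inner.min() < 0 or self.outer.max() > self.n_axial:
            raise ValueError("boundaries outside the axial extent")

    def band_mask(self, n_axial: int | None = None) -> np.ndarray:
        """Boolean (bscan, axial, ascan) mask of the choroid band.

        A small tolerance absorbs float noise from the smoothing stages so
        an outer boundary of ``k + 1e-9`` does not leak row ``k`` in.
        """
        nz = n_axial or self.n_axial
        eps = 1e-6
        z = np.arange(nz)[None, :, None]
        return ((z >= self.inner[:, None, :] - eps)
                & (z < self.outer[:, None, :] - eps))


@dataclass
class ThicknessMap:
    thickness_um: np.ndarray  # (n_bscans, n_ascans)

    def __post_init__(self) -> None:
        self.thickness_um = np.asarray(self.thickness_um, dtype=float)
        if (self.thickness_um < -1e-9).any():
            raise ValueError("thickness must be nonnegative")


def _brightest_class(img: np.ndarray) -> np.ndarray:
    """Pixels of the brightest of three intensity classes (stroma).

    Multi-Otsu separates retina/lumen, sclera and stroma; the thresholds are
    bin centres, so half a bin is added to keep the sclera's own bin below
    the cut. Degenerate histograms fall back to plain Otsu.
    """
    try:
        th = filters.threshold_multiotsu(img, classes=3)
        half_bin = (float(img.max()) - float(img.min())) / 256.0 / 2.0
        return img > th[1] + half_bin
    except ValueError:
        return img > filters.threshold_otsu(img)


def _initial_band_estimate(bscan: np.ndarray, params: SegmentationParams
                           ) -> tuple[np.ndarray, np.ndarray] | None:
    """Inner/outer row per column of one preprocessed B-scan, or None."""
    lo, hi = float(bscan.min()), float(bscan.max())
    if hi - lo < 1e-6:
        return None
    norm = (bscan - lo) / (hi - lo)  # affine-invariant normalization
    eq = exposure.equalize_adapthist(
        norm, kernel_size=params.clahe_kernel, clip_limit=params.clahe_clip)
    try:
        # CLAHE can inflate flat regions; requiring both the equalized and
        # the normalized image to vote keeps the bright band stable.
        bright = _brightest_class(eq) & _brightest_class(norm)
    except ValueError:
        return None
    if params.opening_size > 1:
        bright = ndimage.binary_opening(
            bright, structure=np.ones((params.opening_size,) * 2))
    if params.closing_size > 1:
        bright = ndimage.binary_closing(
            bright, structure=np.ones((params.closing_size,) * 2))
    labels, n = ndimage.label(bright)
    if n == 0:
        return None
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    largest = int(sizes.argmax())
    if sizes[largest] < params.min_band_area_fraction * bscan.size:
        return None
    band = ndimage.binary_fill_holes(labels == largest)

    n_axial, n_ascans = bscan.shape
    inner = np.full(n_ascans, np.nan)
    outer = np.full(n_ascans, np.nan)
    any_col = band.any(axis=0)
    if not any_col.any():
        return None
    first = band.argmax(axis=0).astype(float)
    last = n_axial - band[::-1].argmax(axis=0).astype(float)  # exclusive
    inner[any_col] = first[any_col]
    outer[any_col] = last[any_col]
    # fill columns where the band vanished by linear interpolation
    if (~any_col).any():
        x = np.arange(n_ascans)
        inner = np.interp(x, x[any_col], inner[any_col])
        outer = np.interp(x, x[any_col], outer[any_col])
    return inner, outer


def _lowess_smooth(values: np.ndarray, frac: float, iters: int, axis: int) -> np.ndarray:
    out = np.array(values, dtype=float)
    moved = np.moveaxis(out, axis, 0)
    n = moved.shape[0]
    if n < 5:
        return out
    x = np.arange(n, dtype=float)
    for j in range(moved.shape[1]):
        moved[:, j] = lowess(moved[:, j], x, frac=frac, it=iters,
                             return_sorted=False)
    return out


def delineate_choroid(volume: OCTVolume,
                      params: SegmentationParams | None = None) -> ChoroidBoundaries:
    """Delineate the choroid inner/outer boundaries on every B-scan.

    B-scans without a candidate band are flagged and interpolated from their
    neighbours; if more than ``max_failed_fraction`` of B-scans fail the
    whole volume is rejected with a diagnostic.
    """
    params = params or SegmentationParams()
    nb, nz, na = volume.shape
    data = volume.intensities
    if params.volumetric_median and params.median_size > 1:
        data = ndimage.median_filter(data, size=params.median_size)
    elif params.median_size > 1:
        data = ndimage.median_filter(data, size=(1, params.median_size, params.median_size))

    inner = np.full((nb, na), np.nan)
    outer = np.full((nb, na), np.nan)
    failed = np.zeros(nb, dtype=bool)
    for b in range(nb):
        est = _initial_band_estimate(data[b], params)
        if est is None:
            failed[b] = True
            continue
        inner[b], outer[b] = est

    n_failed = int(failed.sum())
    if n_failed > params.max_failed_fraction * nb:
        raise DelineationError(
            f"no candidate band on {n_failed}/{nb} B-scans "
            f"(> {params.max_failed_fraction:.0%} allowed)")
    if n_failed:
        log.warning("interpolating %d failed B-scans from neighbours", n_failed)
        ok = ~failed
        idx = np.arange(nb)
        for a in range(na):
            inner[failed, a] = np.interp(idx[failed], idx[ok], inner[ok, a])
            outer[failed, a] = np.interp(idx[failed], idx[ok], outer[ok, a])

    # robust locally weighted regression along each B-scan, then across B-scans
    inner = _lowess_smooth(inner, params.lowess_frac, params.lowess_iters, axis=1)
    outer = _lowess_smooth(outer, params.lowess_frac, params.lowess_iters, axis=1)
    inner = _lowess_smooth(inner, params.lowess_frac, params.lowess_iters, axis=0)
    outer = _lowess_smooth(outer, params.lowess_frac, params.lowess_iters, axis=0)

    inner = np.clip(inner, 0, nz)
    outer = np.clip(outer, 0, nz)
    swap = inner > outer
    if swap.any():
        inner[swap], outer[swap] = outer[swap], inner[swap]
    return ChoroidBoundaries(inner=inner, outer=outer,
                             corrected=np.zeros(nb, dtype=bool), n_axial=nz)


def apply_boundary_overrides(boundaries: ChoroidBoundaries,
                             overrides: pd.DataFrame | dict) -> ChoroidBoundaries:
    """Replace boundary values at override locations and flag those B-scans.

    ``overrides`` is either a DataFrame with columns
    ``bscan, ascan, inner_px, outer_px`` or a mapping
    ``{(bscan, ascan): (inner_px, outer_px)}``. An override with
    ``inner > outer`` is rejected naming the location.
    """
    if isinstance(overrides, dict):
        if overrides:
            overrides = pd.DataFrame(
                [(b, a, i, o) for (b, a), (i, o) in overrides.items()],
                columns=["bscan", "ascan", "inner_px", "outer_px"])
        else:
            overrides = pd.DataFrame(columns=["bscan", "ascan", "inner_px", "outer_px"])
    inner = boundaries.inner.copy()
    outer = boundaries.outer.copy()
    corrected = boundaries.corrected.copy()
    nb, na = inner.shape
    for row in overrides.itertuples(index=False):
        b, a = int(row.bscan), int(row.ascan)
        if not (0 <= b < nb and 0 <= a < na):
            raise ValueError(f"override references invalid index (bscan={b}, ascan={a})")
        if row.inner_px > row.outer_px:
            raise ValueError(
                f"override inner > outer at (bscan={b}, ascan={a}): "
                f"{row.inner_px} > {row.outer_px}")
        inner[b, a] = float(row.inner_px)
        outer[b, a] = float(row.outer_px)
        corrected[b] = True
    return ChoroidBoundaries(inner=inner, outer=outer, corrected=corrected,
                             n_axial=boundaries.n_axial)


def compute_thickness_map(boundaries: ChoroidBoundaries,
                          spacing: Spacing) -> ThicknessMap:
    """Choroidal thickness in µm: (outer - inner) x axial spacing per A-scan."""
    spacing = Spacing(*spacing).validate()
    return ThicknessMap((boundaries.outer - boundaries.inner) * spacing.axial)
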