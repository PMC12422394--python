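"""Synthetic SS-OCT choroid phantoms with exact ground truth.

A phantom is a layered volume (retina / bright RPE line / choroid band /
sclera) whose choroid band contains hyporeflective tubular vessels rendered
as piecewise-linear capsules. The rendered label volume is the ground truth
for every downstream recovery test: surfaces, luminal fraction, vessel
centerlines with per-point radii, and pairwise edge-to-edge gaps.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume import OCTVolume, Spacing


def seeded_rng(seed: int, stream: str) -> np.random.Generator:
    """A named, reproducible generator: all randomness flows from one seed."""
    return np.random.default_rng([int(seed), zlib.crc32(stream.encode())])


@dataclass
class Vessel:
    """A tubular vessel: polyline control points (µm) with per-point radii.

    ``points_um`` has shape (N, 3) in (bscan, axial, ascan) micrometre
    coordinates; ``radius_um`` is a scalar or length-N array (linearly
    interpolated along segments, giving rounded-cone geometry).
    """

    points_um: np.ndarray
    radius_um: float | np.ndarray

    def __post_init__(self) -> None:
        self.points_um = np.atleast_2d(np.asarray(self.points_um, dtype=float))
        if self.points_um.shape[0] < 2 or self.points_um.shape[1] != 3:
            raise ValueError("vessel needs >= 2 control points of 3 coordinates")
        r = np.asarray(self.radius_um, dtype=float)
        if r.ndim == 0:
            r = np.full(len(self.points_um), float(r))
        if len(r) != len(self.points_um):
            raise ValueError("per-point radii must match the number of control points")
        if np.any(r <= 0):
            raise ValueError("vessel radii must be positive")
        self.radius_um = r


@dataclass
class PhantomSpec:
    """Geometry and rendering parameters of a synthetic choroid volume.

    Defaults are desk scale (96 x 160 x 128 voxels at 10 µm isotropic);
    clinical dimensions are reachable through the same fields.
    """

    n_bscans: int = 96
    n_ascans: int = 128
    n_axial: int = 160
    spacing: tuple[float, float, float] = (10.0, 10.0, 10.0)  # (bscan, axial, ascan) µm
    inner_depth_mean: float = 400.0
    choroid_thickness_mean: float = 600.0
    surface_smoothness: float = 300.0  # correlation length µm
    surface_amplitude: float = 0.0  # µm std of the surface undulation; 0 = flat
    vessels: list[Vessel] = field(default_factory=list)
    lumen_intensity: float = 0.20
    stroma_intensity: float = 0.70
    retina_intensity: float = 0.15
    sclera_intensity: float = 0.30
    rpe_intensity: float = 0.95
    rpe_thickness_um: float = 0.0  # optional bright RPE line above the inner boundary
    speckle_shape: float | None = None  # applied by the caller via apply_speckle
    disc_region: tuple[tuple[float, float], float] | None = None  # ((y, x) µm, radius µm)
    laterality: str = "OD"
    fovea_index: tuple[int, int] | None = None
    seed: int = 0

    def validate(self) -> "PhantomSpec":
        if min(self.n_bscans, self.n_ascans, self.n_axial) < 8:
            raise ValueError("all phantom dimensions must be >= 8")
        sp = Spacing(*self.spacing).validate()
        if not self.lumen_intensity < self.stroma_intensity:
            raise ValueError("vessels are hyporeflective: lumen_intensity < stroma_intensity")
        for name in ("lumen_intensity", "stroma_intensity", "retina_intensity", "sclera_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for i, v in enumerate(self.vessels):
            if np.any(np.asarray(v.radius_um) < 2 * sp.axial):
                raise ValueError(f"vessel {i}: radii must be >= 2 axial-spacing units")
        if self.surface_amplitude < 0 or self.surface_smoothness <= 0:
            raise ValueError("surface parameters must be nonnegative / positive")
        return self

    @property
    def spacing_t(self) -> Spacing:
        return Spacing(*self.spacing)


@dataclass
class GroundTruth:
    """Exact geometry of a rendered phantom."""

    inner_um: np.ndarray  # (n_bscans, n_ascans) axial position µm
    outer_um: np.ndarray
    vessel_points_um: list[np.ndarray]  # densely sampled centerline per vessel
    vessel_radii_um: list[np.ndarray]
    luminal_fraction: float
    pairwise_edge_gaps: dict[tuple[int, int], float]
    lumen: np.ndarray  # boolean (bscan, axial, ascan)
    band: np.ndarray
    disc_region: tuple[tuple[float, float], float] | None = None

    def thickness_um(self) -> np.ndarray:
        return self.outer_um - self.inner_um


class VesselEscapesBandError(ValueError):
    pass


def _smooth_surface(shape: tuple[int, int], corr_um: float, spacing: Spacing,
                    amplitude_um: float, rng: np.random.Generator) -> np.ndarray:
    if amplitude_um == 0:
        return np.zeros(shape)
    f = rng.standard_normal(shape)
    sigma = (corr_um / spacing.bscan, corr_um / spacing.ascan)
    f = gaussian_filter(f, sigma, mode="reflect")
    std = f.std()
    if std > 0:
        f = f / std * amplitude_um
    return f


def _sample_polyline(points: np.ndarray, radii: np.ndarray, step_um: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Dense samples (points, radii) along a polyline at roughly ``step_um``."""
    out_p, out_r = [points[0]], [radii[0]]
    for i in range(len(points) - 1):
        p0, p1 = points[i], points[i + 1]
        seg = float(np.linalg.norm(p1 - p0))
        n = max(int(np.ceil(seg / step_um)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[1:]
        out_p.append(p0[None] + t[:, None] * (p1 - p0)[None])
        out_r.append(radii[i] + t * (radii[i + 1] - radii[i]))
    return np.vstack([np.atleast_2d(p) for p in out_p]), np.hstack(out_r)


def _rasterize_vessel(vessel: Vessel, shape: tuple[int, int, int], sp: Spacing
                      ) -> np.ndarray:
    """Voxel mask of a rounded-cone polyline tube (voxel centres inside)."""
    lumen = np.zeros(shape, dtype=bool)
    pts = vessel.points_um
    radii = np.asarray(vessel.radius_um, dtype=float)
    spac = sp.as_array()
    for i in range(len(pts) - 1):
        p0, p1 = pts[i], pts[i + 1]
        r0, r1 = radii[i], radii[i + 1]
        rmax = max(r0, r1)
        lo = np.minimum(p0, p1) - rmax
        hi = np.maximum(p0, p1) + rmax
        i0 = np.maximum(np.floor(lo / spac).astype(int), 0)
        i1 = np.minimum(np.ceil(hi / spac).astype(int) + 1, np.asarray(shape))
        if np.any(i0 >= i1):
            continue
        grids = np.meshgrid(
            np.arange(i0[0], i1[0]) * sp.bscan,
            np.arange(i0[1], i1[1]) * sp.axial,
            np.arange(i0[2], i1[2]) * sp.ascan,
            indexing="ij",
        )
        c = np.stack(grids, axis=-1)
        d = p1 - p0
        l2 = float(d @ d)
        if l2 == 0:
            t = np.zeros(c.shape[:-1])
        else:
            t = np.clip(((c - p0) @ d) / l2, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist2 = np.sum((c - proj) ** 2, axis=-1)
        rt = r0 + t * (r1 - r0)
        inside = dist2 <= rt ** 2
        lumen[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= inside
    return lumen


def generate_phantom(spec: PhantomSpec) -> tuple[OCTVolume, GroundTruth]:
    """Render a noise-free phantom volume and its exact ground truth.

    Raises :class:`VesselEscapesBandError` (naming the vessel index) if any
    rendered luminal voxel falls outside the choroid band.
    """
    spec.validate()
    sp = spec.spacing_t
    shape = (spec.n_bscans, spec.n_axial, spec.n_ascans)
    rng = seeded_rng(spec.seed, "phantom-surfaces")

    enface = (spec.n_bscans, spec.n_ascans)
    inner = spec.inner_depth_mean + _smooth_surface(
        enface, spec.surface_smoothness, sp, spec.surface_amplitude, rng)
    outer = inner + spec.choroid_thickness_mean + _smooth_surface(
        enface, spec.surface_smoothness, sp, spec.surface_amplitude / 2.0, rng)

    axial_extent = spec.n_axial * sp.axial
    rpe_thickness = spec.rpe_thickness_um
    if inner.min() < rpe_thickness + sp.axial or outer.max() > axial_extent - 2 * sp.axial:
        raise ValueError(
            "choroid band does not fit in the axial extent; adjust depth/thickness/amplitude")

    z_um = np.arange(spec.n_axial) * sp.axial
    zc = z_um[None, :, None]
    band = (zc >= inner[:, None, :]) & (zc < outer[:, None, :])
    if rpe_thickness > 0:
        rpe = (zc >= (inner - rpe_thickness)[:, None, :]) & (zc < inner[:, None, :])
    else:
        rpe = np.zeros(shape, dtype=bool)

    lumen = np.zeros(shape, dtype=bool)
    for i, vessel in enumerate(spec.vessels):
        vmask = _rasterize_vessel(vessel, shape, sp)
        escaped = vmask & ~band
        if escaped.any():
            b, z, a = [int(x[0]) for x in np.nonzero(escaped)]
            raise VesselEscapesBandError(
                f"vessel {i} escapes the choroid band (first voxel ({b}, {z}, {a}))")
        lumen |= vmask

    intensities = np.full(shape, spec.sclera_intensity)
    intensities[zc < inner[:, None, :]] = spec.retina_intensity
    intensities[rpe] = spec.rpe_intensity
    intensities[band] = spec.stroma_intensity
    intensities[lumen] = spec.lumen_intensity

    band_voxels = int(band.sum())
    luminal_fraction = float(lumen.sum()) / band_voxels if band_voxels else 0.0

    step = sp.minimum / 2.0
    samples = [_sample_polyline(v.points_um, np.asarray(v.radius_um), step)
               for v in spec.vessels]
    gaps: dict[tuple[int, int], float] = {}
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            pi, ri = samples[i]
            pj, rj = samples[j]
            d = np.linalg.norm(pi[:, None, :] - pj[None, :, :], axis=-1)
            gap = d - ri[:, None] - rj[None, :]
            gaps[(i, j)] = float(gap.min())

    volume = OCTVolume(
        intensities=intensities,
        spacing=sp,
        laterality=spec.laterality,
        fovea_index=spec.fovea_index,
        id=f"phantom-seed{spec.seed}",
    )
    truth = GroundTruth(
        inner_um=inner,
        outer_um=outer,
        vessel_points_um=[s[0] for s in samples],
        vessel_radii_um=[s[1] for s in samples],
        luminal_fraction=luminal_fraction,
        pairwise_edge_gaps=gaps,
        lumen=lumen,
        band=band,
        disc_region=spec.disc_region,
    )
    return volume, truth


def five_sector_spec(seed: int = 0, radii_um: tuple[float, float, float] = (180.0, 150.0, 120.0),
                     tube_spacing_um: float = 700.0, iso_um: float = 60.0,
                     laterality: str = "OD") -> PhantomSpec:
    """A 12 x 12 mm full-field phantom with three parallel tubes in each of
    the five sectors of the default fovea-centered grid.

    Within every sector the tubes are ``tube_spacing_um`` apart centre to
    centre, so the true edge gaps are ``spacing - r_i - r_j`` and the true
    sector diameters are ``2 * radii_um``. Desk scale: 200 x 200 en face at
    60 µm isotropic, choroid band 480-1200 µm deep.
    """
    n = int(round(12000.0 / iso_um))
    r1, r2, r3 = radii_um
    z = 840.0  # mid-band depth
    s = tube_spacing_um

    def h(y, x0, x1, r):  # tube along the ascan axis
        return Vessel(points_um=[[y, z, x0], [y, z, x1]], radius_um=r)

    def v(x, y0, y1, r):  # tube along the bscan axis
        return Vessel(points_um=[[y0, z, x], [y1, z, x]], radius_um=r)

    c = 6000.0
    vessels = [
        # central disc (4 mm diameter): horizontal tubes through the fovea
        h(c - s, 5000, 7000, r1), h(c, 5000, 7000, r2), h(c + s, 5000, 7000, r3),
        # superior wedge
        h(2400, 5200, 6800, r1), h(2400 + s, 5200, 6800, r2), h(2400 + 2 * s, 5200, 6800, r3),
        # inferior wedge
        h(9600, 5200, 6800, r1), h(9600 - s, 5200, 6800, r2), h(9600 - 2 * s, 5200, 6800, r3),
        # right wedge (nasal for OD with the default convention)
        v(8200, 5200, 6800, r1), v(8200 + s, 5200, 6800, r2), v(8200 + 2 * s, 5200, 6800, r3),
        # left wedge
        v(3800, 5200, 6800, r1), v(3800 - s, 5200, 6800, r2), v(3800 - 2 * s, 5200, 6800, r3),
    ]
    return PhantomSpec(
        n_bscans=n, n_ascans=n, n_axial=48,
        spacing=(iso_um, iso_um, iso_um),
        inner_depth_mean=480.0, choroid_thickness_mean=720.0,
        vessels=vessels, laterality=laterality,
        fovea_index=(n // 2, n // 2), seed=seed,
    )


def apply_speckle(volume: OCTVolume, speckle_shape: float, seed: int) -> OCTVolume:
    """Multiplicative unit-mean gamma speckle, clipped to [0, 1].

    ``speckle_shape`` controls the noise level (variance 1/shape); the
    expected value of each voxel stays at its clean intensity up to the
    clipping at 1.
    """
    if not np.isfinite(speckle_shape) or speckle_shape <= 0:
        raise ValueError(f"speckle_shape must be > 0, got {speckle_shape}")
    rng = seeded_rng(seed, "speckle")
    gain = rng.gamma(speckle_shape, 1.0 / speckle_shape, size=volume.shape)
    noisy = np.clip(volume.intensities * gain, 0.0, 1.0)
    return OCTVolume(
        intensities=noisy,
        spacing=volume.spacing,
        laterality=volume.laterality,
        fovea_index=volume.fovea_index,
        id=volume.id + "+speckle",
    )
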