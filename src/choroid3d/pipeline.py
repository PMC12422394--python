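"""End-to-end per-eye analysis: boundaries -> thickness -> vessel mask ->
disc exclusion -> labelled vasculature -> sector grid -> biomarkers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binarization import BinarizationParams, CVIResult, VesselMask, binarize_vessels, compute_cvi
from .metrics import CenterlineSet, VesselMetricsResult, extract_centerlines, sector_and_global_metrics
from .segmentation import ChoroidBoundaries, SegmentationParams, ThicknessMap, compute_thickness_map, delineate_choroid
from .vasculature import SECTOR_NAMES, SectorGrid, Vasculature3D, aggregate_by_sector, build_sector_grid, label_vasculature, mask_optic_disc
from .volume import OCTVolume

ALL_SECTORS = ("mean",) + SECTOR_NAMES


@dataclass
class EyeBiomarkers:
    """Per-sector and global biomarkers of one eye."""

    eye_id: str
    mchvd_um: dict[str, float]
    ivd_um: dict[str, float]
    cth_um: dict[str, float]
    cvi_pct: dict[str, float]
    subject_id: str = ""
    group: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sector in ALL_SECTORS:
            rows.append({
                "subject_id": self.subject_id, "eye": self.eye_id,
                "group": self.group, "sector": sector,
                "mchvd_um": self.mchvd_um.get(sector, float("nan")),
                "ivd_um": self.ivd_um.get(sector, float("nan")),
                "cth_um": self.cth_um.get(sector, float("nan")),
                "cvi_pct": self.cvi_pct.get(sector, float("nan")),
            })
        return pd.DataFrame(rows)


@dataclass
class EyeAnalysis:
    """All intermediates of one analyzed eye."""

    boundaries: ChoroidBoundaries
    thickness: ThicknessMap
    mask: VesselMask
    vasculature: Vasculature3D
    grid: SectorGrid
    centerlines: CenterlineSet
    metrics: VesselMetricsResult
    cvi: CVIResult
    biomarkers: EyeBiomarkers


def analyze_eye(volume: OCTVolume, *, seed: int = 0,
                seg_params: SegmentationParams | None = None,
                bin_params: BinarizationParams | None = None,
                boundaries: ChoroidBoundaries | None = None,
                disc=None,
                central_radius_um: float = 2000.0,
                nasal_side: str | None = None,
                l_min_um: float = 100.0,
                eye_id: str | None = None,
                subject_id: str = "", group: str = "") -> EyeAnalysis:
    """Run the full semi-automated protocol on one volume.

    ``boundaries`` may be supplied to bypass the delineation stage (the
    ground-truth / manual-override hook); ``disc`` is an optional optic-disc
    footprint passed to :func:`mask_optic_disc`.
    """
    if boundaries is None:
        boundaries = delineate_choroid(volume, seg_params)
    thickness = compute_thickness_map(boundaries, volume.spacing)
    mask = binarize_vessels(volume, boundaries, bin_params)
    if disc is not None:
        mask = mask_optic_disc(mask, disc)
    grid = build_sector_grid(
        (volume.n_bscans, volume.n_ascans), volume.spacing,
        volume.fovea_index, volume.laterality,
        central_radius_um=central_radius_um, nasal_side=nasal_side)
    vasc = label_vasculature(mask)
    cs = extract_centerlines(vasc, l_min_um=l_min_um)
    metrics = sector_and_global_metrics(vasc, cs, grid, seed=seed)
    cvi = compute_cvi(mask, grid)

    cth = aggregate_by_sector(thickness.thickness_um, grid, volume.spacing)
    cvi_sectors = {k: (float("nan") if v is None else v)
                   for k, v in (cvi.per_sector or {}).items()}
    finite = [v for v in cvi_sectors.values() if np.isfinite(v)]
    cvi_sectors["mean"] = float(np.mean(finite)) if finite else float("nan")

    biomarkers = EyeBiomarkers(
        eye_id=eye_id or volume.id or "eye",
        mchvd_um=metrics.mchvd_um, ivd_um=metrics.ivd_um,
        cth_um=cth, cvi_pct=cvi_sectors,
        subject_id=subject_id, group=group)
    return EyeAnalysis(boundaries=boundaries, thickness=thickness, mask=mask,
                       vasculature=vasc, grid=grid, centerlines=cs,
                       metrics=metrics, cvi=cvi, biomarkers=biomarkers)
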