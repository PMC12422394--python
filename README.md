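# choroid3d

Semi-automated 3D analysis of the choroidal vasculature on SS-OCT volumes,
exercised end to end on synthetic phantoms with exact ground truth.

The pipeline delineates the choroid inner/outer boundaries per B-scan
(median denoising, CLAHE, Otsu-family binarization, connected-component
analysis, robust locally weighted smoothing), segments luminal voxels with
dense Phansalkar local thresholding inside the choroid band, builds a
labelled 3D vasculature with optic-disc exclusion, partitions the en face
plane into a fovea-centered five-sector grid (central sector 4 mm in
diameter), and measures per sector:

- **MChVD** — mean choroidal vessel diameter: the 3 largest vessels per
  sector, 3 random straight-run sites each (9 values), diameter from
  2 × the inscribed radius at the skeleton;
- **IVD** — intervessel distance: edge-to-edge gap to the nearest
  independent (different-component) vessel at 3 sites per vessel;
- **CTh** — choroidal thickness from the boundary surfaces;
- **CVI** — luminal / band voxel ratio in percent.

A per-vessel quality-control rule redraws any measurement triplet whose
sample SD exceeds 50 µm. Global values are the unweighted mean of the five
sector values. A cohort-statistics layer provides linear mixed models with
random subject intercepts (paired eyes), Bonferroni-adjusted pairwise
contrasts, absolute-agreement ICC with F-based confidence intervals,
Pearson correlations and Fisher exact tests.

Because clinical scans are private, the package ships a first-class
synthetic-data module: choroid phantoms (layered volumes with capsule-
geometry tubular vessels and multiplicative gamma speckle) that return the
exact rendered ground truth, and per-eye biomarker cohort generators with
paired-eye correlation structure.

## CLI

```bash
choroid3d simulate-volume --config spec.yaml --seed 1 --out vol/
choroid3d simulate-cohort --seed 1 --out cohort.csv
choroid3d segment  --in vol/volume.tiff --out seg/
choroid3d binarize --in vol/volume.tiff --boundaries seg/boundaries.npz --out mask/
choroid3d measure  --in vol/volume.tiff --seed 1 --out metrics.csv
choroid3d stats    --cohort cohort.csv --out report/
```

Volumes are multipage 16-bit TIFFs with a YAML sidecar (spacing,
laterality, fovea index). Manual boundary corrections are accepted as a CSV
(`bscan,ascan,inner_px,outer_px`) through
`choroid3d.apply_boundary_overrides`, which also serves as the hook for
external (e.g. learned) segmentations.

## Layout

- `src/choroid3d/phantom.py`, `cohort.py` — synthetic volumes and cohorts
- `src/choroid3d/segmentation.py` — boundary delineation, thickness, overrides
- `src/choroid3d/binarization.py` — Phansalkar thresholding, vessel mask, CVI
- `src/choroid3d/vasculature.py` — labelling, disc exclusion, en face, sector grid
- `src/choroid3d/metrics.py` — centerlines, vessel selection, MChVD/IVD, QC
- `src/choroid3d/stats.py` — LMM, ICC, Pearson, Fisher
- `src/choroid3d/pipeline.py` — per-eye orchestration
- `tests/` — unit, property and acceptance suites
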