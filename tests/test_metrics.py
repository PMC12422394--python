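import numpy as np
import pytest
from scipy import ndimage

from choroid3d import (VesselMask, extract_centerlines, label_vasculature,
                       measure_diameters, measure_ivd, qc_redraw,
                       sector_and_global_metrics, select_largest_vessels, triplet_sd)
from choroid3d.phantom import Vessel, generate_phantom
from choroid3d.vasculature import SECTOR_NAMES, SectorGrid
from choroid3d.volume import Spacing

from conftest import fine_spec, tube_along_bscan


def gt_vasculature(phantom):
    vol, gt = phantom
    mask = VesselMask(luminal=gt.lumen, choroid_band=gt.band, spacing=vol.spacing)
    return label_vasculature(mask)


@pytest.fixture(scope="module")
def parallel_tubes():
    """Two parallel tubes, centre spacing 300 µm, radii 50 µm -> edge gap 200."""
    spec = fine_spec([tube_along_bscan(330.0, radius=50.0),
                      tube_along_bscan(630.0, radius=50.0)])
    return generate_phantom(spec)


@pytest.fixture(scope="module")
def parallel_cs(parallel_tubes):
    return extract_centerlines(gt_vasculature(parallel_tubes))


class TestExtractCenterlines:
    def test_straight_tube_unbranched_with_correct_radius(self, parallel_cs):
        cl = parallel_cs.centerlines[1]
        assert cl.n_branch_points == 0
        # per-point inscribed radius 50 +/- spacing/2
        core = cl.radii_um[2:-2]  # ends carry half-voxel discretization
        assert np.all(np.abs(core - 50.0) <= 5.0 + 1e-9)

    def test_y_junction_single_branch_point(self):
        shared = [300.0, 550.0, 480.0]
        vessels = [Vessel(points_um=[[-100, 550, 480], shared], radius_um=40.0),
                   Vessel(points_um=[shared, [580, 550, 700]], radius_um=40.0),
                   Vessel(points_um=[shared, [580, 550, 260]], radius_um=40.0)]
        vol, gt = generate_phantom(fine_spec(vessels))
        vasc = gt_vasculature((vol, gt))
        assert vasc.n_components == 1
        cs = extract_centerlines(vasc)
        assert cs.centerlines[1].n_branch_points == 1

    def test_branch_neighbourhood_excluded_from_straight_runs(self):
        shared = [300.0, 550.0, 480.0]
        vessels = [Vessel(points_um=[[-100, 550, 480], shared], radius_um=40.0),
                   Vessel(points_um=[shared, [580, 550, 700]], radius_um=40.0),
                   Vessel(points_um=[shared, [580, 550, 260]], radius_um=40.0)]
        vol, gt = generate_phantom(fine_spec(vessels))
        cs = extract_centerlines(gt_vasculature((vol, gt)), l_min_um=100.0)
        cl = cs.centerlines[1]
        branch_pts = cl.points_um[cl.branch]
        for p in cl.points_um[cl.eligible]:
            assert np.linalg.norm(branch_pts - p, axis=1).min() >= 100.0

    def test_empty_vasculature(self, two_tube_phantom):
        vol, gt = two_tube_phantom
        empty = VesselMask(luminal=np.zeros_like(gt.lumen), choroid_band=gt.band,
                           spacing=vol.spacing)
        cs = extract_centerlines(label_vasculature(empty))
        assert cs.centerlines == {}
        assert cs.skipped == []

    def test_tiny_component_skipped(self, two_tube_phantom):
        vol, gt = two_tube_phantom
        lum = np.zeros_like(gt.lumen)
        lum[gt.band].flat[0] = True  # a single voxel inside the band
        idx = np.argwhere(gt.band)[0]
        lum = np.zeros_like(gt.lumen)
        lum[tuple(idx)] = True
        mask = VesselMask(luminal=lum, choroid_band=gt.band, spacing=vol.spacing)
        cs = extract_centerlines(label_vasculature(mask))
        assert cs.skipped == [1]


@pytest.fixture(scope="module")
def four_tube_vasc():
    radii = [80.0, 60.0, 40.0, 20.0]
    xs = [150.0, 390.0, 600.0, 780.0]
    spec = fine_spec(
        [tube_along_bscan(x, radius=r) for x, r in zip(xs, radii)],
        n_axial=160, inner_depth_mean=300.0, choroid_thickness_mean=800.0,
        spacing=(10.0, 10.0, 10.0))
    vol, gt = generate_phantom(spec)
    return gt_vasculature((vol, gt))


class TestSelectLargestVessels:

    def test_ordering_by_volume(self, four_tube_vasc):
        grid = SectorGrid(fovea_um=(240.0, 480.0), central_radius_um=10_000.0)
        ranked, volumes, shortfall = select_largest_vessels(four_tube_vasc, grid,
                                                            "central", n=3)
        vols = volumes[ranked]
        assert list(vols) == sorted(vols, reverse=True)
        assert len(ranked) == 3 and not shortfall
        # the 20 µm tube is left out
        all_vols = volumes[1:]
        assert volumes[ranked[-1]] > all_vols.min()

    def test_shortfall_flag(self, four_tube_vasc):
        grid = SectorGrid(fovea_um=(240.0, 480.0), central_radius_um=10_000.0)
        ranked, _, shortfall = select_largest_vessels(four_tube_vasc, grid,
                                                      "central", n=6)
        assert len(ranked) == 4 and shortfall

    def test_tie_break_prefers_lower_label(self, parallel_tubes):
        vasc = gt_vasculature(parallel_tubes)
        grid = SectorGrid(fovea_um=(240.0, 480.0), central_radius_um=10_000.0)
        ranked, volumes, _ = select_largest_vessels(vasc, grid, "central", n=1)
        assert volumes[1] == volumes[2]
        assert ranked == [1]

    def test_crossing_vessel_ranked_by_in_sector_volume_only(self):
        # one tube crosses the central disc, one lives inside it
        crossing = Vessel(points_um=[[240.0, 550.0, -100.0], [240.0, 550.0, 1060.0]],
                          radius_um=50.0)
        inside = tube_along_bscan(480.0, z_um=750.0, radius=40.0,
                                  y0=150.0, y1=330.0)
        vol, gt = generate_phantom(fine_spec([crossing, inside]))
        vasc = gt_vasculature((vol, gt))
        grid = SectorGrid(fovea_um=(240.0, 480.0), central_radius_um=150.0)
        _, volumes, _ = select_largest_vessels(vasc, grid, "central", n=2)
        # brute-force oracle: count voxels of each label inside the sector
        label_map = grid.label_map((vol.n_bscans, vol.n_ascans), vol.spacing)
        for lab in (1, 2):
            count = 0
            for b, z, a in np.argwhere(vasc.labels == lab):
                count += label_map[b, a] == 0
            assert volumes[lab] == pytest.approx(count * vol.spacing.voxel_volume)

    def test_unknown_sector_rejected(self, parallel_tubes):
        vasc = gt_vasculature(parallel_tubes)
        grid = SectorGrid(fovea_um=(240.0, 480.0))
        with pytest.raises(ValueError, match="sector"):
            select_largest_vessels(vasc, grid, "macular")


class TestMeasureDiameters:
    def test_straight_tube_within_one_voxel(self, parallel_cs):
        rng = np.random.default_rng(0)
        d, _ = measure_diameters(parallel_cs.centerlines[1], 3, rng)
        assert np.all(np.abs(d - 100.0) <= 10.0)

    def test_tapered_tube_monotone(self):
        tapered = Vessel(points_um=[[-100, 550, 480], [580, 550, 480]],
                         radius_um=[40.0, 80.0])
        vol, gt = generate_phantom(fine_spec([tapered]))
        cs = extract_centerlines(gt_vasculature((vol, gt)))
        cl = cs.centerlines[1]
        rng = np.random.default_rng(1)
        d, _ = measure_diameters(cl, 3, rng)
        assert np.all((d >= 80.0 - 10.0) & (d <= 160.0 + 10.0))
        # radii increase along the ordered centerline (the tube tapers up)
        core = cl.radii_um[2:-2]
        diffs = np.diff(core)
        assert np.sum(diffs >= -5.0) / len(diffs) > 0.95

    def test_fixed_seed_reproducible(self, parallel_cs):
        cl = parallel_cs.centerlines[1]
        d1, s1 = measure_diameters(cl, 3, np.random.default_rng(42))
        d2, s2 = measure_diameters(cl, 3, np.random.default_rng(42))
        assert np.array_equal(s1, s2)
        assert np.array_equal(d1, d2)

    def test_no_straight_run_raises(self, parallel_cs):
        cl = parallel_cs.centerlines[1]
        with pytest.raises(ValueError, match="no straight run"):
            measure_diameters(cl, 3, np.random.default_rng(0),
                              site_pool=np.zeros(len(cl.points_um), dtype=bool))


class TestMeasureIVD:
    def test_parallel_tubes_gap(self, parallel_cs):
        rng = np.random.default_rng(0)
        gaps, _ = measure_ivd(parallel_cs, parallel_cs.centerlines[1], 3, rng)
        assert np.all(np.abs(gaps - 200.0) <= 10.0 + 1e-9)

    def test_nearest_of_multiple_wins(self):
        spec = fine_spec([tube_along_bscan(150.0, radius=50.0),
                          tube_along_bscan(450.0, radius=50.0),  # gap 200
                          tube_along_bscan(900.0, radius=50.0)])  # gap 350 to middle
        vol, gt = generate_phantom(spec)
        cs = extract_centerlines(gt_vasculature((vol, gt)))
        rng = np.random.default_rng(0)
        gaps, _ = measure_ivd(cs, cs.centerlines[2], 3, rng)
        assert np.all(np.abs(gaps - 200.0) <= 10.0 + 1e-9)

    def test_collateral_branch_excluded(self):
        # a collateral branch of the same component lies 100 µm away;
        # the nearest independent vessel is ~250 µm away
        main = Vessel(points_um=[[-100, 550, 300], [580, 550, 300]], radius_um=40.0)
        collateral = Vessel(points_um=[[240, 550, 300], [240, 550, 480]],
                            radius_um=40.0)  # touches main -> same component
        independent = Vessel(points_um=[[-100, 550, 670], [580, 550, 670]],
                             radius_um=40.0)
        vol, gt = generate_phantom(fine_spec([main, collateral, independent]))
        vasc = gt_vasculature((vol, gt))
        assert vasc.n_components == 2
        cs = extract_centerlines(vasc, l_min_um=100.0)
        main_label = int(vasc.labels[24, 55, 30])
        cl = cs.centerlines[main_label]
        rng = np.random.default_rng(3)
        gaps, _ = measure_ivd(cs, cl, 3, rng)
        # edge gap to the independent tube: 370 - 40 - 40 = 290
        assert np.all(gaps > 200.0)
        assert np.all(np.abs(gaps - 290.0) <= 25.0)

    def test_single_vessel_returns_none(self):
        vol, gt = generate_phantom(fine_spec([tube_along_bscan(480.0)]))
        cs = extract_centerlines(gt_vasculature((vol, gt)))
        assert measure_ivd(cs, cs.centerlines[1], 3,
                           np.random.default_rng(0)) is None


class TestQCRule:
    def test_high_sd_triplet_triggers_redraw(self):
        # (100, 100, 220): sample SD ~ 69.3 µm > 50 µm
        assert triplet_sd([100.0, 100.0, 220.0]) == pytest.approx(69.282, abs=0.01)
        draws = {0: np.array([100.0, 100.0, 220.0]),
                 1: np.array([100.0, 100.0, 100.0])}
        values, _, remeasured, flagged = qc_redraw(
            lambda attempt: (draws[attempt], attempt))
        assert remeasured and not flagged
        assert np.array_equal(values, draws[1])

    def test_good_triplet_kept_unflagged(self):
        values, _, remeasured, flagged = qc_redraw(
            lambda attempt: (np.array([100.0, 110.0, 120.0]), attempt))
        assert not remeasured and not flagged

    def test_max_attempts_flag(self):
        bad = np.array([100.0, 100.0, 220.0])
        values, extra, remeasured, flagged = qc_redraw(lambda attempt: (bad, attempt))
        assert remeasured and flagged
        assert extra == 4  # the last attempt is kept


class TestSectorAndGlobalMetrics:
    def test_homogeneous_tubes_give_exact_mean(self):
        spec = fine_spec([tube_along_bscan(x, radius=50.0)
                          for x in (180.0, 480.0, 780.0)])
        vol, gt = generate_phantom(spec)
        vasc = gt_vasculature((vol, gt))
        cs = extract_centerlines(vasc)
        grid = SectorGrid(fovea_um=(240.0, 480.0), central_radius_um=10_000.0)
        res = sector_and_global_metrics(vasc, cs, grid, seed=0)
        # nine identical diameters -> sector mean equals the common value
        diam = res.mchvd_um["central"]
        assert abs(diam - 100.0) <= 10.0
        central = [m for m in res.measurements if m.sector == "central"]
        assert sum(len(m.diameters_um) for m in central) == 9
        assert res.mchvd_um["mean"] == pytest.approx(diam)  # only one sector

    def test_vessel_without_in_sector_run_replaced(self):
        # the crossing tube overlaps the central disc but its centerline
        # stays outside; the in-disc tube must be measured instead
        outside = tube_along_bscan(640.0, radius=50.0)
        inside = tube_along_bscan(480.0, z_um=750.0, radius=40.0,
                                  y0=140.0, y1=340.0)
        vol, gt = generate_phantom(fine_spec([outside, inside]))
        vasc = gt_vasculature((vol, gt))
        cs = extract_centerlines(vasc)
        grid = SectorGrid(fovea_um=(240.0, 480.0), central_radius_um=150.0)
        res = sector_and_global_metrics(vasc, cs, grid, seed=0)
        central = [m for m in res.measurements if m.sector == "central"]
        labels = {m.label for m in central}
        inside_label = int(vasc.labels[24, 75, 48])
        assert labels == {inside_label}

    def test_dilation_increases_diameter_and_decreases_ivd(self, parallel_tubes):
        vol, gt = parallel_tubes
        grid = SectorGrid(fovea_um=(240.0, 480.0), central_radius_um=10_000.0)

        def run(lum):
            mask = VesselMask(luminal=lum, choroid_band=gt.band, spacing=vol.spacing)
            vasc = label_vasculature(mask)
            cs = extract_centerlines(vasc)
            return sector_and_global_metrics(vasc, cs, grid, seed=4)

        base = run(gt.lumen)
        dilated = run(ndimage.binary_dilation(gt.lumen) & gt.band)
        assert dilated.mchvd_um["mean"] > base.mchvd_um["mean"]
        assert dilated.ivd_um["mean"] < base.ivd_um["mean"]

    def test_five_sector_protocol_counts(self, coarse_analysis):
        res = coarse_analysis.metrics
        assert res.distinct_vessels == 15
        assert res.vessels_measured == 15
        for sector in SECTOR_NAMES:
            ms = [m for m in res.measurements if m.sector == sector]
            assert len(ms) == 3
            assert sum(len(m.diameters_um) for m in ms) == 9
            assert sum(len(m.ivds_um) for m in ms) == 9

    def test_retained_triplets_satisfy_qc(self, coarse_analysis):
        for m in coarse_analysis.metrics.measurements:
            if not m.qc_max_attempts:
                assert triplet_sd(m.diameters_um) <= 50.0
                if m.ivds_um is not None:
                    assert triplet_sd(m.ivds_um) <= 50.0

    def test_global_is_mean_of_sector_values(self, coarse_analysis):
        res = coarse_analysis.metrics
        expected = np.mean([res.mchvd_um[s] for s in SECTOR_NAMES])
        assert res.mchvd_um["mean"] == pytest.approx(expected)

    def test_two_seeded_graders_agree(self, coarse_analysis):
        from choroid3d import icc_agreement
        a = coarse_analysis
        res1 = a.metrics
        res2 = sector_and_global_metrics(a.vasculature, a.centerlines, a.grid,
                                         seed=99)
        key = lambda r: {(m.sector, m.label): float(np.mean(m.diameters_um))
                         for m in r.measurements}
        k1, k2 = key(res1), key(res2)
        shared = sorted(set(k1) & set(k2))
        g1 = np.array([k1[k] for k in shared])
        g2 = np.array([k2[k] for k in shared])
        icc = icc_agreement(g1, g2)
        assert icc.icc > 0.9

    def test_determinism(self, coarse_analysis):
        a = coarse_analysis
        r1 = sector_and_global_metrics(a.vasculature, a.centerlines, a.grid, seed=5)
        r2 = sector_and_global_metrics(a.vasculature, a.centerlines, a.grid, seed=5)
        assert r1.mchvd_um == r2.mchvd_um
        assert r1.ivd_um == r2.ivd_um
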