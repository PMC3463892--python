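"""Geometry generator: morphometric oracles, calibration, clusters,
probes and determinism."""

import math

import numpy as np
import pytest

from ttflux.geometry import (FACE_OUTER, FACE_REFLECTIVE, FACE_TTUBULE,
                             PRINTED_MORPHOMETRICS, BoxSpec, GeometryError,
                             Morphometrics, TTubuleSpec, build_geometry,
                             calibrate_geometry, make_probes,
                             measure_morphometrics, place_lcc_clusters)

FLAT_BOX = BoxSpec(outer_relief_amplitude=0.0)
CYL = TTubuleSpec(constriction_area_fraction=1.0, eccentricity=1.0)


def test_flat_box_volume_and_area_closed_form():
    """No tubule, flat cap: volume and outer area equal the box closed
    forms exactly when the voxel size divides the dimensions."""
    g = build_geometry(None, FLAT_BOX, 0.06)
    m = measure_morphometrics(g)
    assert m.volume == pytest.approx(2.34 * 2.58 * 5.76 * 1e-3, rel=1e-12)
    assert m.area_outer == pytest.approx(2.34 * 2.58, rel=1e-12)
    assert m.area_ttubule == 0.0


def test_cylinder_lateral_area_matches_analytic_after_correction():
    """Straight circular cylinder in a flat box: corrected t-tubule area
    equals the analytic lateral + tip area; volume equals box - lumen to
    within the voxelization error at this resolution."""
    g = build_geometry(CYL, FLAT_BOX, 0.04)
    m = measure_morphometrics(g)
    r = CYL.mean_diameter / 2
    analytic = 2 * math.pi * r * CYL.length + math.pi * r ** 2
    assert m.area_ttubule == pytest.approx(analytic, rel=1e-6)
    box_vol = np.prod(g.labels.shape) * g.voxel_volume * 1e-3
    lumen = math.pi * r ** 2 * CYL.length * 1e-3
    assert m.volume == pytest.approx(box_vol - lumen, rel=0.01)
    # raw staircase area over-counts a cylinder by ~4/pi
    assert 0.7 < g.area_correction[FACE_TTUBULE] < 0.9


def test_cylinder_area_converges_with_resolution():
    r = CYL.mean_diameter / 2
    analytic = 2 * math.pi * r * CYL.length + math.pi * r ** 2
    errs = []
    for h in (0.09, 0.06, 0.04):
        m = measure_morphometrics(build_geometry(CYL, FLAT_BOX, h))
        errs.append(abs(m.area_ttubule - analytic) / analytic)
    assert errs[-1] < 1e-4


def test_default_geometry_mouth_and_depth(calibrated_specs):
    """The tubule opens at the outer face and the carved lumen depth is
    ~4.6 um below the mouth."""
    tt, bx = calibrated_specs
    g = build_geometry(tt, bx, 0.04)
    depth = g.z_tip - g.z_mouth
    assert depth == pytest.approx(4.6, rel=0.05)
    # the lumen opens into the exterior above the outer sarcolemma:
    # one connected non-cytosol component contains both
    from scipy.ndimage import label as cc_label
    comp, _ = cc_label(g.labels != 0)
    lumen_comps = set(np.unique(comp[g.labels == 2]))
    exterior_comps = set(np.unique(comp[g.labels == 1]))
    assert lumen_comps & exterior_comps


def test_calibration_hits_printed_morphometrics(calibrated_specs):
    tt, bx = calibrated_specs
    m = measure_morphometrics(build_geometry(tt, bx, 0.04))
    t = PRINTED_MORPHOMETRICS
    assert m.volume == pytest.approx(t.volume, rel=0.03)
    assert m.area_ttubule == pytest.approx(t.area_ttubule, rel=0.03)
    assert m.area_outer == pytest.approx(t.area_outer, rel=0.03)
    assert m.area_total == pytest.approx(m.area_ttubule + m.area_outer)
    # stays within the printed diameter range
    lo, hi = tt.diameter_range
    assert lo <= tt.mean_diameter <= hi


def test_calibration_tracks_perturbed_volume_target():
    t = PRINTED_MORPHOMETRICS
    perturbed = Morphometrics(volume=t.volume * 1.1, area_total=t.area_total,
                              area_ttubule=t.area_ttubule,
                              area_outer=t.area_outer)
    tt, bx = calibrate_geometry(perturbed, voxel_size=0.06)
    m = measure_morphometrics(build_geometry(tt, bx, 0.06))
    assert m.volume == pytest.approx(t.volume * 1.1, rel=0.03)


def test_flat_target_drives_relief_to_zero():
    flat = Morphometrics(volume=2.34 * 2.58 * 5.76 * 1e-3,
                         area_total=2.34 * 2.58,
                         area_ttubule=0.0, area_outer=2.34 * 2.58)
    # with no tubule the only knobs are the relief parameters
    tt, bx = calibrate_geometry(flat, voxel_size=0.06,
                                ttubule=None, box=BoxSpec())
    assert bx.outer_relief_amplitude == pytest.approx(0.0, abs=0.02)


def test_build_rejects_bad_specs():
    with pytest.raises(GeometryError):
        build_geometry(TTubuleSpec(), BoxSpec(), 0.12)  # too coarse globally
    with pytest.raises(GeometryError):
        build_geometry(TTubuleSpec(mean_diameter=0.2), FLAT_BOX, 0.06)
    with pytest.raises(GeometryError):  # tubule at the box edge
        build_geometry(TTubuleSpec(mouth_center=(0.1, 1.29)), FLAT_BOX, 0.04)
    with pytest.raises(GeometryError):
        BoxSpec(outer_relief_amplitude=1.2)  # > 20% of depth
    with pytest.raises(GeometryError):
        TTubuleSpec(constriction_area_fraction=0.0)


def test_every_boundary_face_labeled_once(calibrated_specs):
    tt, bx = calibrated_specs
    g = build_geometry(tt, bx, 0.08)
    assert set(np.unique(g.face_label)) <= {FACE_OUTER, FACE_TTUBULE,
                                            FACE_REFLECTIVE}
    # each (voxel, normal) pair appears once
    key = g.face_voxel * 16 + (g.face_normal[:, 0] + 1) * 2 \
        + (g.face_normal[:, 1] + 1) + (g.face_normal[:, 2] + 1) * 4
    assert len(np.unique(key)) == len(key)


def test_grid_and_clusters_deterministic(calibrated_specs):
    tt, bx = calibrated_specs
    a = place_lcc_clusters(build_geometry(tt, bx, 0.08, seed=11), seed=11)
    b = place_lcc_clusters(build_geometry(tt, bx, 0.08, seed=11), seed=11)
    assert np.array_equal(a.labels, b.labels)
    assert np.array_equal(a.face_patch, b.face_patch)
    c = place_lcc_clusters(build_geometry(tt, bx, 0.08, seed=12), seed=12)
    assert not np.array_equal(a.face_patch, c.face_patch)


class TestClusters:
    def test_three_disjoint_patches_of_expected_area(self, calibrated_specs):
        tt, bx = calibrated_specs
        g = place_lcc_clusters(build_geometry(tt, bx, 0.04, seed=5),
                               n=3, diameter=0.2, pinned_depth=2.0, seed=5)
        target = math.pi * 0.1 ** 2
        for k in range(3):
            sel = g.face_patch == k
            assert sel.any()
            # raw staircase area of a ~200 nm disc on a curved wall;
            # generous band for staircase + curvature bias
            area = sel.sum() * g.face_area
            assert target / 3 < area < target * 3
            assert (g.face_label[sel] == FACE_TTUBULE).all()
        # pinned cluster depth
        z = g.cluster_centers[:, 2] - g.z_mouth
        assert z[0] == pytest.approx(2.0, abs=0.05)

    def test_patches_never_touch_outer_membrane(self, calibrated_specs):
        tt, bx = calibrated_specs
        for seed in (1, 2, 3):
            g = place_lcc_clusters(build_geometry(tt, bx, 0.08, seed=seed),
                                   seed=seed)
            on = g.face_patch >= 0
            assert (g.face_label[on] == FACE_TTUBULE).all()

    def test_spacing_scan_gives_distinct_layouts(self, calibrated_specs):
        tt, bx = calibrated_specs
        layouts = set()
        for s in (0.57, 0.8, 1.07, 1.8):
            g = place_lcc_clusters(build_geometry(tt, bx, 0.08),
                                   spacing=s)
            layouts.add(tuple(np.round(g.cluster_centers[:, 2], 3)))
        assert len(layouts) == 4

    def test_zero_clusters_leaves_grid_unchanged(self, calibrated_specs):
        tt, bx = calibrated_specs
        g = build_geometry(tt, bx, 0.08)
        before = g.face_patch.copy()
        g2 = place_lcc_clusters(g, n=0)
        assert np.array_equal(g2.face_patch, before)

    def test_excessive_spacing_rejected(self, calibrated_specs):
        tt, bx = calibrated_specs
        g = build_geometry(tt, bx, 0.08)
        with pytest.raises(GeometryError):
            place_lcc_clusters(g, spacing=5.0)


class TestProbes:
    def test_subsarc_is_membrane_voxel_shell(self, calibrated_specs):
        tt, bx = calibrated_specs
        g = place_lcc_clusters(build_geometry(tt, bx, 0.08, seed=7), seed=7)
        p = make_probes(g, shell_depth=50.0)
        mem_vox = np.unique(g.face_voxel[g.membrane_faces()])
        assert np.array_equal(np.flatnonzero(p.subsarc_mask), mem_vox)

    def test_linescan_spans_box_depth(self, calibrated_specs):
        tt, bx = calibrated_specs
        g = place_lcc_clusters(build_geometry(tt, bx, 0.08, seed=7), seed=7)
        p = make_probes(g)
        nz = g.labels.shape[2]
        assert p.linescan_voxels.size >= nz - 1
        assert p.linescan_positions.max() > bx.dimensions[2] - 2 * 0.08
        # spots at 1.5 and 5.3 um along the line
        for spot, want in zip(p.cytosol_spots, (1.5, 5.3)):
            z = (g.cyt_ijk[spot][2] + 0.5) * g.voxel_size
            assert z == pytest.approx(want, abs=0.08)

    def test_distal_probe_adjacent_to_deepest_cluster(self, calibrated_specs):
        tt, bx = calibrated_specs
        g = place_lcc_clusters(build_geometry(tt, bx, 0.08, seed=7), seed=7)
        p = make_probes(g)
        deepest = np.argmax(g.cluster_centers[:, 2])
        pf = np.flatnonzero(g.face_patch == deepest)
        assert p.distal_point in set(g.face_voxel[pf])

    def test_all_probe_points_cytosolic(self, calibrated_specs):
        tt, bx = calibrated_specs
        g = place_lcc_clusters(build_geometry(tt, bx, 0.08, seed=7), seed=7)
        p = make_probes(g)
        n = g.n_cytosol
        pts = [p.mouth_point, p.distal_point, *p.cytosol_spots,
               *p.linescan_voxels]
        assert all(0 <= q < n for q in pts)

    def test_shell_depth_bounds_enforced(self, calibrated_specs):
        tt, bx = calibrated_specs
        g = build_geometry(tt, bx, 0.08)
        with pytest.raises(GeometryError):
            make_probes(g, shell_depth=30.0)
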