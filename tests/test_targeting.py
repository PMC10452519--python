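"""Targeting constructions: closed-form sphere oracles, frame invariance,
and exhaustive mask predicates."""

import dataclasses

import numpy as np
import pytest

import tmstarget as tt
from tmstarget.geometry import rotate_about_axis, sphere_geodesic, unit
from tmstarget.targeting import ScalpPoint, scalp_point


class TestFiveCm:
    def test_zero_distance_returns_hotspot(self, default_head):
        hs = scalp_point(default_head, default_head.landmarks.motor_hotspot)
        out = tt.five_cm_target(default_head, hs, distance=0.0)
        assert np.allclose(out.position, hs.position, atol=1e-9)

    def test_closed_form_circle_geometry(self, default_head):
        # hotspot in the plane x = -55: section circle radius sqrt(85^2-55^2)
        rho = np.sqrt(85.0**2 - 55.0**2)
        alpha0 = np.deg2rad(100.0)
        hs = ScalpPoint(
            position=np.array([-55.0, rho * np.cos(alpha0), rho * np.sin(alpha0)]),
            outward_normal=unit([-55.0, rho * np.cos(alpha0), rho * np.sin(alpha0)]),
        )
        out = tt.five_cm_target(default_head, hs, distance=50.0)
        a_exp = alpha0 - 50.0 / rho  # anterior advance by the arc angle
        expected = np.array([-55.0, rho * np.cos(a_exp), rho * np.sin(a_exp)])
        assert np.allclose(out.position, expected, atol=1e-6)
        assert np.rad2deg(50.0 / rho) == pytest.approx(44.2, abs=0.1)

    def test_stays_in_parasagittal_plane_and_moves_anterior(self, default_head):
        hs = scalp_point(default_head, default_head.landmarks.motor_hotspot)
        out = tt.five_cm_target(default_head, hs, distance=50.0)
        assert out.position[0] == pytest.approx(hs.position[0], abs=1e-6)
        assert out.position[1] > hs.position[1]

    def test_geodesic_distance_monotone(self, default_head):
        hs = scalp_point(default_head, default_head.landmarks.motor_hotspot)
        d1 = tt.five_cm_target(default_head, hs, distance=30.0)
        d2 = tt.five_cm_target(default_head, hs, distance=60.0)
        g1 = sphere_geodesic(hs.position, d1.position, 85.0)
        g2 = sphere_geodesic(hs.position, d2.position, 85.0)
        assert g1 < g2
        # in-plane arc equals the requested distance within tolerance
        assert g1 == pytest.approx(30.0, abs=0.5)

    def test_chord_shorter_than_arc(self, default_head):
        hs = scalp_point(default_head, default_head.landmarks.motor_hotspot)
        arc = tt.five_cm_target(default_head, hs, distance=50.0)
        chord = tt.five_cm_target(default_head, hs, distance=50.0, chord=True)
        assert sphere_geodesic(hs.position, chord.position, 85.0) > sphere_geodesic(
            hs.position, arc.position, 85.0
        ) - 1e-9


class TestTenTwenty:
    def test_cz_at_vertex_on_symmetric_head(self, default_head):
        pts = tt.ten_twenty_positions(default_head)
        assert np.allclose(pts["Cz"].position, [0, 0, 85.0], atol=1e-9)

    def test_fz_closed_form(self, default_head):
        ang = 0.3 * np.pi
        expected = np.array([0.0, 85 * np.cos(ang), 85 * np.sin(ang)])
        assert np.allclose(
            tt.ten_twenty_positions(default_head)["Fz"].position, expected, atol=1e-9
        )

    def test_left_right_mirror_symmetry(self, default_head):
        pts = tt.ten_twenty_positions(default_head)
        for left, right in (("F3", "F4"), ("F7", "F8"), ("Fp1", "Fp2")):
            pl, pr = pts[left].position, pts[right].position
            assert pl[0] == pytest.approx(-pr[0], abs=0.5)
            assert pl[1] == pytest.approx(pr[1], abs=0.5)
            assert pl[2] == pytest.approx(pr[2], abs=0.5)

    def test_cz_equidistant_from_cardinal_landmarks(self):
        head = tt.make_head(
            85.0, seed=3,
            jitter_spec=tt.JitterSpec(rotation_deg_sd=8.0),
        )
        pts = tt.ten_twenty_positions(head)
        lm = head.landmarks
        cz = pts["Cz"].position
        g = lambda p: sphere_geodesic(cz, p, 85.0)
        assert abs(g(lm.nasion) - g(lm.inion)) < 0.5
        assert abs(g(lm.lpa) - g(lm.rpa)) < 0.5

    def test_f3_scales_radially_with_head_size(self):
        f3_80 = tt.ten_twenty_positions(tt.make_head(80.0, seed=0))["F3"].position
        f3_90 = tt.ten_twenty_positions(tt.make_head(90.0, seed=0))["F3"].position
        assert np.allclose(f3_90, f3_80 * 90.0 / 80.0, atol=0.5)

    def test_all_positions_on_scalp(self, default_head):
        for sp in tt.ten_twenty_positions(default_head).values():
            assert abs(np.linalg.norm(sp.position) - 85.0) < 0.1


class TestDbt:
    def test_axis_aligned_slab_arithmetic(self, default_head):
        res = tt.dbt_construct(default_head)
        an = default_head.anatomy
        # canonical anatomy: inferior CC plane is near-horizontal, slab normal +y
        assert res.slab_normal[1] > 0.99
        genu_y = an.cc_genu_anterior @ res.slab_normal
        s = res.center @ res.slab_normal
        assert genu_y + 10 - 10 <= s <= genu_y + 10 + 10

    def test_rigid_rotation_equivariance(self, default_head):
        res0 = tt.dbt_construct(default_head)
        axis, ang = np.array([0.3, 0.5, 0.8]), 0.4
        head_rot = dataclasses.replace(
            default_head,
            anatomy=dataclasses.replace(
                default_head.anatomy,
                **{
                    k: rotate_about_axis(v, axis, ang)
                    for k, v in default_head.anatomy.points().items()
                },
            ),
        )
        res1 = tt.dbt_construct(head_rot)
        assert np.allclose(rotate_about_axis(res0.center, axis, ang), res1.center, atol=1e-6)

    def test_random_anatomies_respect_slab_bound(self):
        for seed in range(20):
            head = tt.make_head(
                85.0, seed=seed,
                jitter_spec=tt.JitterSpec(anatomy_sd=4.0),
            )
            res = tt.dbt_construct(head)
            s = res.center @ res.slab_normal
            assert res.slab_center_coord - 10 - 1e-9 <= s <= res.slab_center_coord + 10 + 1e-9

    def test_out_of_slab_point_clamped_and_flagged(self, default_head):
        an = default_head.anatomy
        far = dataclasses.replace(an, sfs_deep_point=an.sfs_deep_point + np.array([0, 40.0, 0]))
        res = tt.dbt_construct(dataclasses.replace(default_head, anatomy=far))
        assert res.clamped


class TestScalpProject:
    def test_radial_projection(self, default_head):
        out = tt.scalp_project(np.array([0.0, 40.0, 40.0]), default_head)
        assert np.allclose(out.position, 85.0 * np.array([0, 1, 1]) / np.sqrt(2), atol=1e-9)

    def test_center_degenerate_tie_flagged(self, default_head):
        out = tt.scalp_project(np.zeros(3), default_head)
        assert out.degenerate_tie
        assert np.allclose(out.position, default_head.scalp_surface.vertices[0])

    def test_mesh_vs_analytic_within_edge_length(self, default_head):
        p = np.array([-20.0, 35.0, 30.0])
        analytic = tt.scalp_project(p, default_head)
        mesh = tt.scalp_project(p, default_head, method="mesh")
        edge = default_head.scalp_surface.edges_unique_length.max()
        assert np.linalg.norm(analytic.position - mesh.position) < edge

    def test_outside_point_rejected(self, default_head):
        with pytest.raises(ValueError):
            tt.scalp_project(np.array([0.0, 0.0, 90.0]), default_head)


class TestDlpfcMask:
    def test_plane_arithmetic_inclusion(self, default_head):
        mask = tt.build_dlpfc_mask(default_head)
        an = default_head.anatomy
        d = an.frontal_pole[1] - an.temporal_pole_left[1]
        y_post = an.temporal_pole_left[1] + 0.2 * d
        y_ant = an.frontal_pole[1] - 0.4 * d
        z_inf = an.brain_inferior_extreme[2] + 0.5 * (
            an.brain_superior_extreme[2] - an.brain_inferior_extreme[2]
        )
        centers = mask.voxel_centers
        assert (centers[:, 0] < 0).all()
        assert (centers[:, 1] >= y_post).all() and (centers[:, 1] <= y_ant).all()
        assert (centers[:, 2] >= z_inf).all()

    def test_count_matches_bruteforce_predicate(self):
        head = tt.make_head(85.0, seed=2, voxel_size=5.0)
        mask = tt.build_dlpfc_mask(head)
        an = head.anatomy
        d = an.frontal_pole[1] - an.temporal_pole_left[1]
        y_post = an.temporal_pole_left[1] + 0.2 * d
        y_ant = an.frontal_pole[1] - 0.4 * d
        z_inf = an.brain_inferior_extreme[2] + 0.5 * (
            an.brain_superior_extreme[2] - an.brain_inferior_extreme[2]
        )
        n = 0
        gm = head.gm_grid
        for idx in np.argwhere(gm.data):
            c = idx @ gm.affine[:3, :3].T + gm.affine[:3, 3]
            if c[0] < 0 and y_post <= c[1] <= y_ant and c[2] >= z_inf:
                n += 1
        assert mask.n_voxels == n

    def test_degenerate_fractions_keep_everything_anterior(self, default_head):
        spec = tt.MaskSpec(post_fraction=0.0, ant_fraction=0.0, inf_fraction=0.0)
        mask = tt.build_dlpfc_mask(default_head, spec)
        an = default_head.anatomy
        centers = mask.voxel_centers
        assert (centers[:, 1] >= an.temporal_pole_left[1]).all()
        assert (centers[:, 2] >= an.brain_inferior_extreme[2]).all()

    def test_equivalent_radius_definition_and_band(self, default_head):
        mask = tt.build_dlpfc_mask(default_head)
        vol = mask.n_voxels * mask.voxel_size**3
        assert mask.equivalent_radius == pytest.approx((3 * vol / (4 * np.pi)) ** (1 / 3))
        lo, hi = 9.0, 15.0  # plausibility band around the study-scale ROI radius
        assert lo < 11.4 < hi
        assert lo < mask.equivalent_radius < hi

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            tt.MaskSpec(post_fraction=0.7, ant_fraction=0.5).validate()


class TestCrossMethodGeometry:
    def test_all_targets_on_scalp_and_ordering(self):
        """5 cm targets sit farther from the anatomical scalp target than F3."""
        gaps_5cm, gaps_f3 = [], []
        for seed in range(5):
            head = tt.make_head(
                80.0 + 2.5 * seed, seed=seed,
                jitter_spec=tt.JitterSpec(hotspot_sd=5.0, anatomy_sd=1.0, rotation_deg_sd=10.0),
            )
            R = head.scalp_radius
            p5 = tt.five_cm_target(head)
            f3 = tt.ten_twenty_positions(head)["F3"]
            dst = tt.scalp_project(tt.dbt_construct(head).center, head)
            for sp in (p5, f3, dst):
                assert abs(np.linalg.norm(sp.position) - R) < 0.1
            gaps_5cm.append(sphere_geodesic(p5.position, dst.position, R))
            gaps_f3.append(sphere_geodesic(f3.position, dst.position, R))
        assert np.mean(gaps_5cm) > np.mean(gaps_f3)
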