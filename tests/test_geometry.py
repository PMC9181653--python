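"""Geometry construction and point-in-volume queries."""

import math

import numpy as np
import pytest

from chromofiber.errors import GeometryInfeasibleError, InvalidArgumentError
from chromofiber.geometry import (
    FiberConfig,
    FiberGeometry,
    NucleusEnvelope,
    build_double_helix,
    build_fiber,
    build_linker,
    build_nucleosome,
    geometry_summary,
    locate,
)
from chromofiber.transforms import Frame, rot_z

from oracles import brute_force_locate

CFG = FiberConfig()


class TestDoubleHelix:
    def test_rejects_empty(self):
        with pytest.raises(InvalidArgumentError):
            build_double_helix(0)

    def test_single_pair_is_identity(self):
        (pair,) = build_double_helix(1)
        assert pair.frame.almost_equal(Frame())

    def test_ten_bp_is_one_full_turn(self):
        """10 bp span 3.4 nm of axis and 360 degrees of twist."""
        pairs = build_double_helix(10)
        extent = pairs[-1].frame.origin[2] - pairs[0].frame.origin[2] + CFG.rise_nm
        assert extent == pytest.approx(3.4, abs=1e-12)
        for i, p in enumerate(pairs):
            assert np.allclose(p.frame.rotation, rot_z(math.radians(36.0 * i)), atol=1e-12)
        # the 10-step twist closes the turn
        assert np.allclose(rot_z(math.radians(36.0 * 10)), np.eye(3), atol=1e-12)

    def test_step_composition(self):
        """Pair 2's frame equals the single-step transform applied twice."""
        pairs = build_double_helix(3)
        step = Frame(rot_z(CFG.twist_rad), np.array([0.0, 0.0, CFG.rise_nm]))
        composed = pairs[0].frame.compose(step).compose(step)
        assert pairs[2].frame.almost_equal(composed, tol_nm=1e-9, tol_rad=1e-9)


@pytest.fixture(scope="module")
def wrapped():
    frame, pairs = build_nucleosome(Frame())
    return frame, pairs


class TestNucleosome:
    def test_wrapped_bp_matches_arc_length_oracle(self, wrapped):
        """Independent numeric arc-length integration of the wrap helix."""
        _, pairs = wrapped
        a, pitch, turns = CFG.wrap_radius_nm, CFG.wrap_pitch_nm, CFG.wrap_turns
        u = np.linspace(0.0, turns, 200001)
        pts = np.stack([a * np.cos(2 * np.pi * u), a * np.sin(2 * np.pi * u), pitch * u], axis=1)
        arc = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
        assert round(arc / CFG.rise_nm) == len(pairs) == CFG.wrapped_bp

    def test_left_handed_1p65_turns(self, wrapped):
        _, pairs = wrapped
        xy = np.array([p.frame.origin[:2] for p in pairs])
        phi = np.unwrap(np.arctan2(xy[:, 1], xy[:, 0]))
        assert np.all(np.diff(phi) < 0)  # left-handed: azimuth decreases
        per_turn = math.hypot(2 * math.pi * CFG.wrap_radius_nm, CFG.wrap_pitch_nm)
        expected_turns = (len(pairs) - 1) * CFG.rise_nm / per_turn
        assert -(phi[-1] - phi[0]) / (2 * math.pi) == pytest.approx(expected_turns, rel=1e-9)
        assert CFG.wrap_turns == 1.65

    def test_path_centered_on_histone_axis(self, wrapped):
        """Every path point sits at the wrap radius; the path centroid stays
        well inside the wrap radius (exact axial symmetry only holds for an
        integer number of turns)."""
        _, pairs = wrapped
        origins = np.array([p.frame.origin for p in pairs])
        radii = np.hypot(origins[:, 0], origins[:, 1])
        assert np.allclose(radii, CFG.wrap_radius_nm, atol=1e-9)
        centroid = origins.mean(axis=0)
        assert np.hypot(centroid[0], centroid[1]) < 1.0

    def test_volumes_clear_histone_surface(self, wrapped):
        _, pairs = wrapped
        origins = np.array([p.frame.origin for p in pairs])
        inner_reach = np.hypot(origins[:, 0], origins[:, 1]) - CFG.backbone_radius_nm
        assert np.all(inner_reach >= CFG.histone_radius_nm - 1e-9)


class TestLinker:
    def test_empty(self):
        assert build_linker(Frame(), Frame(), 0) == []

    def test_straight_degenerate(self):
        """Collinear ends with matching tangents -> straight, evenly spaced
        placement with exact end-frame continuity."""
        n = 40
        length = (n - 1) * CFG.rise_nm
        end_a = Frame()
        end_b = Frame(rot_z((n - 1) * CFG.twist_rad), np.array([0.0, 0.0, length]))
        pairs = build_linker(end_a, end_b, n)
        assert len(pairs) == n
        origins = np.array([p.frame.origin for p in pairs])
        assert np.allclose(origins[:, :2], 0.0, atol=1e-9)
        spacing = np.diff(origins[:, 2])
        assert np.allclose(spacing, CFG.rise_nm, atol=1e-6)
        assert pairs[0].frame.almost_equal(end_a, 1e-6, 1e-6)
        assert pairs[-1].frame.almost_equal(end_b, 1e-6, 1e-6)
        # interior twist follows the 36 deg/bp schedule
        for k in (1, 20, 38):
            assert pairs[k].frame.almost_equal(
                Frame(rot_z(k * CFG.twist_rad), np.array([0.0, 0.0, k * CFG.rise_nm])), 1e-6, 1e-6
            )

    def test_end_continuity_generic(self):
        """C0/C1 continuity at both ends for a bent linker."""
        end_a = Frame()
        rot = rot_z(0.3) @ np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0.0]])
        end_b = Frame(rot, np.array([5.0, 8.0, 9.0]))
        pairs = build_linker(end_a, end_b, 40, FiberConfig(linker_spacing_tol_nm=1.0))
        assert np.allclose(pairs[0].frame.origin, end_a.origin, atol=1e-6)
        assert np.allclose(pairs[-1].frame.origin, end_b.origin, atol=1e-6)
        assert np.allclose(pairs[0].frame.z_axis, end_a.z_axis, atol=1e-6)
        assert np.allclose(pairs[-1].frame.z_axis, end_b.z_axis, atol=1e-6)
        assert pairs[-1].frame.almost_equal(end_b, 1e-6, 1e-6)

    def test_incompatible_arc_length(self):
        end_b = Frame(np.eye(3), np.array([0.0, 0.0, 40.0]))
        with pytest.raises(GeometryInfeasibleError):
            build_linker(Frame(), end_b, 10)


class TestFiber:
    def test_headline_numbers(self, fiber):
        summary = geometry_summary(fiber)
        assert summary["nucleosome_count"] == 61
        assert summary["total_kbp"] == 10.8
        assert summary["density_per_11nm"] == 4.2

    def test_bp_allocation_is_exact(self, fiber):
        cfg = fiber.config
        assert fiber.total_bp == cfg.nucleosomes * (cfg.wrapped_bp + cfg.linker_bp)
        assert cfg.wrapped_bp + cfg.linker_bp == cfg.nucleosome_repeat_bp
        # bp indices are contiguous: positions of consecutive bp are close
        gaps = np.linalg.norm(np.diff(fiber.origins, axis=0), axis=1)
        assert gaps.max() < 3 * cfg.rise_nm

    def test_all_volumes_inside_envelope(self, fiber):
        cfg = fiber.config
        bound = cfg.bp_bound_radius_nm
        radial = np.hypot(fiber.origins[:, 0], fiber.origins[:, 1])
        assert (radial + bound).max() <= cfg.fiber_radius_nm
        assert (np.abs(fiber.origins[:, 2]) + bound).max() <= cfg.fiber_length_nm / 2

    def test_wrapped_origins_clear_their_histone(self, fiber):
        cfg = fiber.config
        for j in range(0, cfg.nucleosomes, 13):
            sel = fiber.nucleosome_ids == j
            h = Frame(fiber.histone_rotations[j], fiber.histone_origins[j])
            local = h.to_local(fiber.origins[sel])
            r = np.hypot(local[:, 0], local[:, 1])
            assert np.all(r - cfg.backbone_radius_nm >= cfg.histone_radius_nm - 1e-6)

    def test_solenoid_six_per_turn(self, fiber):
        """Nucleosome centers advance 60 degrees of fiber azimuth each."""
        xy = fiber.histone_origins[:, :2]
        phi = np.unwrap(np.arctan2(xy[:, 1], xy[:, 0]))
        assert np.allclose(np.diff(phi), math.radians(60.0), atol=1e-9)


class TestLocate:
    def test_backbone_centroids(self, fiber):
        for bp, strand in [(0, 0), (0, 1), (5000, 0), (140, 1)]:  # 140 is linker DNA
            hit = locate(fiber.backbone_centroid(bp, strand), fiber)
            assert (hit.kind, hit.strand, hit.bp_index) == ("backbone", strand, bp)

    def test_base_centroid(self, fiber):
        hit = locate(fiber.base_centroid(300, 1), fiber)
        assert (hit.kind, hit.strand, hit.bp_index) == ("base", 1, 300)

    def test_far_point_is_water(self, fiber):
        assert locate([1e4, 1e4, 1e4], fiber).kind == "water"

    def test_histone_center(self, fiber):
        hit = locate(fiber.histone_origins[17], fiber)
        assert (hit.kind, hit.nucleosome_id) == ("histone", 17)

    def test_rejects_non_finite(self, fiber):
        with pytest.raises(InvalidArgumentError):
            locate([np.nan, 0, 0], fiber)

    def test_purity(self, fiber, rng):
        pts = rng.uniform(-18, 18, size=(200, 3))
        first = fiber.locate_many(pts)
        second = fiber.locate_many(pts)
        for a, b in zip(first, second):
            assert np.array_equal(a, b)

    def test_agrees_with_exhaustive_scan(self, fiber, rng):
        """Spatial-index answers match a brute-force scan over all volumes,
        so priority resolution is unambiguous on random points."""
        n = 1000
        pts = np.column_stack(
            [rng.uniform(-17, 17, n), rng.uniform(-17, 17, n), rng.uniform(-79, 79, n)]
        )
        kind, strand, bp_index, _ = fiber.locate_many(pts)
        okind, ostrand, obp = brute_force_locate(fiber, pts)
        assert np.array_equal(kind, okind)
        assert np.array_equal(strand, ostrand)
        assert np.array_equal(bp_index, obp)


class TestExport:
    def test_json_snapshot(self, fiber, tmp_path):
        import json

        path = tmp_path / "geom.json"
        fiber.to_json(str(path))
        payload = json.loads(path.read_text())
        assert payload["config"]["nucleosomes"] == 61
        assert len(payload["bp"]["origins_nm"]) == fiber.total_bp
        assert len(payload["histones"]["origins_nm"]) == 61

    def test_centroid_point_cloud(self, fiber, tmp_path):
        path = tmp_path / "centroids.xyz"
        fiber.write_centroids_xyz(str(path))
        lines = path.read_text().splitlines()
        assert int(lines[0]) == 4 * fiber.total_bp
        assert len(lines) == 2 + 4 * fiber.total_bp


class TestSummary:
    def test_density_halves_when_length_doubles(self, fiber):
        cfg2 = FiberConfig(fiber_length_nm=2 * CFG.fiber_length_nm)
        geom2 = FiberGeometry(
            cfg2, fiber.origins, fiber.rotations, fiber.nucleosome_ids,
            fiber.histone_origins, fiber.histone_rotations,
        )
        s1, s2 = geometry_summary(fiber), geometry_summary(geom2)
        assert s2["density_per_11nm"] == pytest.approx(s1["density_per_11nm"] / 2, abs=0.06)

    def test_nucleus_bp_density(self, fiber):
        env = NucleusEnvelope()
        expected = 6e9 / (math.pi * 9850.0 * 7100.0 * 2500.0)
        assert env.bp_density_per_nm3 == pytest.approx(expected, rel=1e-12)
        assert geometry_summary(fiber, env)["nucleus_bp_density_per_nm3"] == pytest.approx(expected, rel=1e-12)
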