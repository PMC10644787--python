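"""Region partitioning, axis construction, origin placement, end-to-end ACS."""

import numpy as np
import pytest

import footacs as fa
from conftest import uv_sphere_mesh
from footacs.acs_core import (
    ACS,
    DegenerateGeometryError,
    assemble_acs,
    assign_acs,
    compute_primary_axis,
    compute_secondary_axis,
    compute_third_point,
    partition_regions,
    place_origin,
)
from footacs.registry import get_bone_spec


def brute_force_partition(samples, axis_i, n):
    """Independent slab-membership oracle: assign each point to its slab by
    direct interval comparison, centroids by plain averaging."""
    coords = samples[:, axis_i]
    lo, hi = coords.min(), coords.max()
    edges = [lo + (hi - lo) * k / n for k in range(n + 1)]
    members = [[] for _ in range(n)]
    for p in samples:
        c = p[axis_i]
        for k in range(n):
            last = k == n - 1
            if (edges[k] <= c < edges[k + 1]) or (last and edges[k] <= c <= edges[k + 1]):
                members[k].append(p)
                break
    centroids = [np.mean(m, axis=0) if m else None for m in members]
    counts = [len(m) for m in members]
    return edges, centroids, counts


class TestPartitionRegions:
    def test_collinear_points_worked_example(self):
        """10 points at x = 0..9 into 3 slabs: boundaries (0,3,6,9); extreme
        centroids x = 1.0 (members 0,1,2) and x = 7.5 (members 6,7,8,9)."""
        pts = np.array([[float(i), 0, 0] for i in range(10)])
        part = partition_regions(pts, "ML", 3)
        assert np.allclose(part.boundaries, [0, 3, 6, 9])
        assert np.isclose(part.region_centroids[0][0], 1.0)
        assert np.isclose(part.region_centroids[-1][0], 7.5)
        assert part.region_counts.tolist() == [3, 3, 4]

    def test_single_region_is_global_mean(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(50, 3))
        part = partition_regions(pts, "AP", 1)
        assert np.allclose(part.region_centroids[0], pts.mean(axis=0))

    def test_symmetric_points_mirror_centroids(self):
        rng = np.random.default_rng(1)
        half = rng.normal(size=(200, 3)) + [5, 0, 0]
        pts = np.vstack([half, half * [-1, 1, 1]])
        part = partition_regions(pts, "ML", 3)
        a, b = part.region_centroids[0], part.region_centroids[-1]
        assert np.isclose(a[0], -b[0], atol=1e-12)
        assert np.allclose(a[1:], b[1:], atol=1e-12)

    @pytest.mark.parametrize("n", [3, 5, 10])
    def test_matches_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        pts = rng.uniform(-20, 20, size=(500, 3))
        for axis_i, axis in enumerate(["ML", "AP", "SI"]):
            part = partition_regions(pts, axis, n)
            edges, centroids, counts = brute_force_partition(pts, axis_i, n)
            assert np.allclose(part.boundaries, edges)
            assert part.region_counts.tolist() == counts
            for k in range(n):
                assert np.allclose(part.region_centroids[k], centroids[k])

    def test_empty_slab_raises(self):
        # two tight clusters leave the middle slab empty
        pts = np.vstack([np.zeros((10, 3)), np.ones((10, 3)) * [9, 0, 0]])
        pts += np.random.default_rng(0).normal(0, 0.01, pts.shape)
        with pytest.raises(DegenerateGeometryError, match="ML"):
            partition_regions(pts, "ML", 3)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            partition_regions(np.zeros((2, 3)), "ML", 3)


class TestPrimaryAxis:
    def test_axis_through_two_centroids(self):
        pts = np.array([[float(i), 0, 0] for i in range(10)])
        part = partition_regions(pts, "ML", 3)
        vec, (lo, hi) = compute_primary_axis(part)
        assert np.allclose(vec, [1, 0, 0])
        assert lo[0] < hi[0]

    def test_normalization(self):
        part = partition_regions(
            np.array([[0.0, -40, 5], [0, -39, 5], [0, 0, 0], [0, 39, -5], [0, 40, -5]]), "AP", 3
        )
        vec, _ = compute_primary_axis(part)
        expected = np.array([0.0, 79.0, -10.0])  # centroids (0,-39.5,5) -> (0,39.5,-5)
        assert np.allclose(vec, expected / np.linalg.norm(expected))

    def test_synthetic_metatarsal_long_axis(self, registry):
        """An AP-elongated metatarsal's primary axis matches the generator's
        long axis within 5 degrees."""
        from footacs.surface import sample_surface

        rec = fa.generate_bone(fa.default_params("metatarsal2", seed=4))
        samples = sample_surface(rec.mesh, 20000, seed=0)
        part = partition_regions(samples, "AP", 3)
        vec, _ = compute_primary_axis(part)
        ang = np.degrees(np.arccos(abs(vec @ np.array([0, 1, 0]))))
        assert ang < 5.0

    def test_coincident_centroids_raise(self):
        from footacs.acs_core import RegionPartition

        part = RegionPartition(
            "ML", 3, np.array([0.0, 1, 2, 3]), np.zeros((3, 3)), np.array([5, 5, 5])
        )
        with pytest.raises(DegenerateGeometryError):
            compute_primary_axis(part)


class TestThirdPointAndSecondary:
    def test_superior_rule_takes_top_slab(self):
        pts = np.array([[0.0, 0, z] for z in np.linspace(2, 18, 30)])
        part = partition_regions(pts, "SI", 3)
        spec = get_bone_spec("cuboid")
        third = compute_third_point(part, spec)
        assert third[2] == pytest.approx(part.region_centroids[-1][2])
        assert third[2] > 12

    def test_lateral_rule_takes_lowest_x_slab(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-10, 10, size=(300, 3))
        part = partition_regions(pts, "ML", 3)
        spec = get_bone_spec("tibia")
        third = compute_third_point(part, spec)
        # oracle: plain mean of points with x in [-10, -10 + 20/3)
        lo = pts[:, 0].min()
        width = (pts[:, 0].max() - lo) / 3
        members = pts[pts[:, 0] < lo + width]
        assert np.allclose(third, members.mean(axis=0))

    def test_wrong_partition_axis_rejected(self):
        pts = np.random.default_rng(0).uniform(-5, 5, (50, 3))
        part = partition_regions(pts, "AP", 3)
        with pytest.raises(ValueError):
            compute_third_point(part, get_bone_spec("cuboid"))

    def test_secondary_closed_form(self):
        sec = compute_secondary_axis(np.array([1.0, 0, 0]), np.zeros(3), np.array([5.0, 0, 7]))
        assert np.allclose(sec, [0, 0, 1])

    def test_secondary_projection_arithmetic(self):
        """Oracle: project (3,12,4) onto the y-axis -> foot (0,12,0), offset
        (3,0,4), normalized (0.6,0,0.8)."""
        sec = compute_secondary_axis(np.array([0.0, 1, 0]), np.zeros(3), np.array([3.0, 12, 4]))
        assert np.allclose(sec, [0.6, 0, 0.8])

    def test_secondary_orthogonal_for_random_configs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = rng.normal(size=3)
            p /= np.linalg.norm(p)
            anchor = rng.normal(size=3) * 10
            third = anchor + rng.normal(size=3) * 10
            if np.linalg.norm(np.cross(third - anchor, p)) < 1e-3:
                continue
            sec = compute_secondary_axis(p, anchor, third)
            assert abs(sec @ p) < 1e-12

    def test_third_point_on_primary_line_raises(self):
        with pytest.raises(DegenerateGeometryError):
            compute_secondary_axis(np.array([1.0, 0, 0]), np.zeros(3), np.array([5.0, 0, 0]))


class TestAssembleACS:
    def test_canonical_frame(self):
        spec = get_bone_spec("cuboid")  # AP primary, SI secondary, ML tertiary
        acs = assemble_acs(np.array([0.0, 1, 0]), np.array([0.0, 0, 1]), spec, np.zeros(3))
        assert np.allclose(acs.ML, [1, 0, 0])
        assert np.linalg.det(acs.axes) == pytest.approx(1.0)

    def test_sign_correction(self):
        spec = get_bone_spec("cuboid")
        acs = assemble_acs(np.array([0.0, -1, 0]), np.array([0.0, 0, 1]), spec, np.zeros(3))
        assert np.allclose(acs.AP, [0, 1, 0])
        acs.validate()

    def test_handedness_failure_detected(self):
        """A frame whose ML/AP pass the sign checks but whose cross product
        points inferiorly signals catastrophic misalignment."""
        from footacs.acs_core import AlignmentFailureError

        spec = get_bone_spec("cuboid")  # primary -> AP, secondary -> SI
        ML = np.array([0.2, 0.7, 0.0])
        ML[2] = np.sqrt(1 - ML @ ML)  # (0.2, 0.7, 0.686)
        AP = np.array([0.7, 0.2, 0.0])
        AP -= (AP @ ML) * ML
        AP /= np.linalg.norm(AP)
        assert AP[1] > 0 and ML[0] > 0 and np.cross(ML, AP)[2] < 0
        SI = np.cross(ML, AP)
        with pytest.raises(AlignmentFailureError):
            assemble_acs(AP, SI, spec, np.zeros(3))

    def test_random_valid_inputs_always_satisfy_invariants(self):
        rng = np.random.default_rng(11)
        spec = get_bone_spec("navicular")  # ML primary
        for _ in range(200):
            # primary near +x, secondary near +z, both randomly perturbed
            p = np.array([1.0, 0, 0]) + 0.2 * rng.normal(size=3)
            p /= np.linalg.norm(p)
            s = np.array([0.0, 0, 1]) + 0.2 * rng.normal(size=3)
            s -= (s @ p) * p
            s /= np.linalg.norm(s)
            acs = assemble_acs(p, s, spec, rng.normal(size=3))
            acs.validate(tol=1e-9)


class TestPlaceOrigin:
    def test_joint_origin_on_analytic_sphere(self):
        sphere = uv_sphere_mesh(radius=1.0)
        spec = get_bone_spec("talus", "talonavicular")  # joint direction +y
        acs = ACS(np.zeros(3), [1, 0, 0], [0, 1, 0], [0, 0, 1], space="aligned")
        origin = place_origin(sphere, spec, acs, mode="joint_surface")
        assert np.abs(origin - [0, 1, 0]).max() < 1e-6

    def test_offcenter_sphere_along_x(self):
        sphere = uv_sphere_mesh(radius=10.0, center=(2.0, 0, 0))
        spec = get_bone_spec("navicular")
        # navicular joint direction is anterior; rotate the ACS so the mapped
        # joint ray points along +x instead
        acs2 = ACS(np.zeros(3), [0, -1, 0], [1, 0, 0], [0, 0, 1], space="aligned")
        origin = place_origin(sphere, spec, acs2, mode="joint_surface")
        assert np.abs(origin - [12, 0, 0]).max() < 1e-6

    def test_bone_center_of_symmetric_shape(self):
        sphere = uv_sphere_mesh(radius=10.0)
        spec = get_bone_spec("cuboid")
        acs = ACS(np.zeros(3), [1, 0, 0], [0, 1, 0], [0, 0, 1], space="aligned")
        origin = place_origin(sphere, spec, acs, mode="bone_center")
        assert np.abs(origin).max() < 1e-6  # exact area-weighted centroid


class TestAssignACS:
    def test_ground_truth_recovery_identity_pose(self, registry):
        rec = fa.generate_bone(fa.default_params("calcaneus", "calcaneocuboid", seed=5))
        res = assign_acs(rec.mesh, "calcaneus", "calcaneocuboid", registry, seed=1)
        diff = fa.angle_difference(res.acs_original, rec.true_acs)
        assert max(diff.as_array()) < 5.0
        res.acs_aligned.validate(tol=1e-9)
        res.acs_original.validate(tol=1e-9)

    def test_rigid_invariance(self, registry):
        params = fa.default_params("navicular", seed=8)
        base = assign_acs(fa.generate_bone(params).mesh, "navicular", "default", registry, seed=2)
        pose = fa.random_rigid_transform(np.random.default_rng(21))
        posed = fa.generate_bone(params, pose=pose)
        res = assign_acs(posed.mesh, "navicular", "default", registry, seed=2)
        mapped = pose.rotation @ base.acs_original.axes
        ang = np.degrees(np.arccos(np.clip((mapped * res.acs_original.axes).sum(axis=0), -1, 1)))
        assert ang.max() < 0.5

    def test_mirror_consistency(self, registry):
        params = fa.default_params("talus", "subtalar_talus", seed=3)
        left = fa.generate_bone(params, side="left")
        right = fa.generate_bone(params, side="right")
        rl = assign_acs(left.mesh, "talus", "subtalar_talus", registry, side="left", seed=2)
        rr = assign_acs(right.mesh, "talus", "subtalar_talus", registry, side="right", seed=2)
        diff = fa.angle_difference(rl.acs_aligned, rr.acs_aligned)
        assert max(diff.as_array()) <= 0.5

    def test_scale_equivariance(self, registry, tmp_path):
        """Doubling the bone and its template leaves the axes unchanged:
        directions are scale-free."""
        import json
        import os

        from footacs.mesh_io import read_mesh, write_mesh
        from footacs.registry import TemplateRegistry

        # build a scaled copy of the template directory (one bone suffices)
        src = registry.root
        dst = tmp_path / "scaled"
        manifest = json.load(open(os.path.join(src, "manifest.json")))
        small = {"cuboid": manifest["cuboid"]}
        for variant, entry in small["cuboid"].items():
            for which, e in entry.items():
                mesh = read_mesh(os.path.join(src, e["file"]))
                mesh.vertices *= 2.0
                out = dst / e["file"]
                out.parent.mkdir(parents=True, exist_ok=True)
                write_mesh(mesh, str(out))
                e["extent_along_primary"] *= 2.0
        (dst / "manifest.json").write_text(json.dumps(small))
        scaled_reg = TemplateRegistry(str(dst))

        params = fa.default_params("cuboid", seed=12)
        rec = fa.generate_bone(params)
        # the mm-valued convergence threshold must scale with the geometry
        res1 = assign_acs(rec.mesh, "cuboid", "default", registry, seed=3, icp_tolerance=1e-5)
        big = fa.TriangleMesh(rec.mesh.vertices * 2.0, rec.mesh.faces.copy())
        res2 = assign_acs(big, "cuboid", "default", scaled_reg, seed=3, icp_tolerance=2e-5)
        assert np.abs(res1.acs_aligned.axes - res2.acs_aligned.axes).max() < 1e-6

    def test_tessellation_robustness(self, registry):
        """Half/double remeshing moves each axis by at most 2 degrees."""
        from footacs.synthetic import perturb_segmentation

        rec = fa.generate_bone(fa.default_params("cuboid", seed=6))
        base = assign_acs(rec.mesh, "cuboid", "default", registry, seed=4)
        for factor in (0.5, 2.0):
            twin = perturb_segmentation(rec, noise_sd=0.0, remesh_factor=factor, seed=1)
            res = assign_acs(twin.mesh, "cuboid", "default", registry, seed=4)
            diff = fa.angle_difference(base.acs_aligned, res.acs_aligned)
            assert max(diff.as_array()) <= 2.0

    def test_partial_tibia_uses_partial_template(self, registry):
        rec = fa.generate_bone(fa.default_params("tibia", seed=3))
        v, f = rec.mesh.vertices, rec.mesh.faces
        cut = v[:, 2].min() + 0.45 * (v[:, 2].max() - v[:, 2].min())
        keep = (v[f][:, :, 2] < cut).all(axis=1)
        used = np.unique(f[keep])
        remap = -np.ones(len(v), dtype=int)
        remap[used] = np.arange(len(used))
        partial = fa.TriangleMesh(v[used], remap[f[keep]], name="tib_partial")
        res = assign_acs(partial, "tibia", "default", registry, seed=1)
        diff = fa.angle_difference(res.acs_original, rec.true_acs)
        assert diff.theta_SI < 5.0
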