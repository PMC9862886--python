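from math import cos, pi, radians

import numpy as np
import pytest

from fhnquant.mask_io import LabelVolume
from fhnquant.phantom_sim import PhantomSpec, generate_phantom
from fhnquant.quant3d import (
    CutPlane,
    NeckCutNotFoundError,
    SurfaceMesh,
    compute_volumes,
    extract_surface,
    fit_neck_cut_plane,
    quantify_case,
    trim_mesh,
    write_ply,
)


def brute_force_voxel_face_area(mask: np.ndarray, spacing) -> float:
    """Independent oracle: total area of exposed voxel faces (mm^2)."""
    sx, sy, sz = spacing
    face_areas = (sy * sz, sx * sz, sx * sy)
    padded = np.pad(mask.astype(np.int8), 1)
    total = 0.0
    for ax, fa in enumerate(face_areas):
        diff = np.abs(np.diff(padded, axis=ax))
        total += fa * diff.sum()
    return float(total)


class TestComputeVolumes:
    def test_single_necrotic_voxel(self):
        labels = np.zeros((4, 4, 4), dtype=np.int16)
        labels[2, 2, 2] = 2
        vol = LabelVolume("v", labels, (0.8, 0.8, 0.8))
        necro, unaff, pct = compute_volumes(vol)
        assert necro == pytest.approx(0.000512)
        assert unaff == 0.0
        assert pct == 100.0

    def test_equal_counts_give_exactly_half(self):
        labels = np.zeros((4, 4, 4), dtype=np.int16)
        labels[0] = 1
        labels[1] = 2
        vol = LabelVolume("v", labels, (1.0, 1.0, 1.0))
        _, _, pct = compute_volumes(vol)
        assert pct == 50.0

    def test_phantom_within_2pct_of_closed_form(self, iso_phantom):
        vol, truth = iso_phantom
        necro, _, _ = compute_volumes(vol)
        assert necro == pytest.approx(truth.necrotic_volume, rel=0.02)

    def test_volume_conservation_exact(self, coarse_phantom):
        vol, _ = coarse_phantom
        necro, unaff, _ = compute_volumes(vol)
        fg_total = int(np.count_nonzero(vol.labels)) * vol.voxel_volume_mm3 / 1000
        assert necro + unaff == fg_total

    def test_empty_foreground_errors(self):
        vol = LabelVolume("e", np.zeros((3, 3, 3), dtype=np.int16), (1, 1, 1))
        with pytest.raises(ValueError, match="not quantifiable"):
            compute_volumes(vol)


class TestExtractSurface:
    def test_digital_cube_area(self):
        labels = np.zeros((14, 14, 14), dtype=np.int16)
        labels[2:12, 2:12, 2:12] = 1
        vol = LabelVolume("cube", labels, (1.0, 1.0, 1.0))
        # the voxel-face oracle is exact for an axis-aligned cube
        assert brute_force_voxel_face_area(labels > 0, vol.spacing) == 600.0
        mesh = extract_surface(vol)
        assert mesh.total_area == pytest.approx(600.0, rel=0.12)

    def test_sphere_area_within_5pct(self):
        n, sp = 72, 0.8
        c = (n - 1) / 2 * sp
        ax = np.arange(n) * sp - c
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        labels = ((X**2 + Y**2 + Z**2) <= 25.0**2).astype(np.int16)
        vol = LabelVolume("sphere", labels, (sp, sp, sp))
        mesh = extract_surface(vol)
        assert mesh.total_area == pytest.approx(4 * pi * 25**2, rel=0.05)

    def test_no_lesion_no_necrotic_faces(self, theta0_phantom):
        vol, _ = theta0_phantom
        mesh = extract_surface(vol)
        assert (mesh.face_label != 2).all()
        assert mesh.necrotic_area == 0.0

    def test_lesion_faces_on_top(self, coarse_phantom):
        vol, _ = coarse_phantom
        mesh = extract_surface(vol)
        necro_z = mesh.face_centroids[mesh.face_label == 2][:, 2]
        other_z = mesh.face_centroids[mesh.face_label == 1][:, 2]
        assert necro_z.mean() > other_z.mean()  # lesion is superior

    def test_boundary_contact_warning(self):
        labels = np.ones((6, 6, 6), dtype=np.int16)
        vol = LabelVolume("block", labels, (1, 1, 1))
        mesh = extract_surface(vol)
        assert any(f.code == "open-boundary" for f in mesh.warnings)
        # padding still closes the surface: area close to the block's own
        assert mesh.total_area == pytest.approx(6 * 36.0, rel=0.2)


def _disk_mesh(center, normal_axis, radius, n_seg=64, jitter=0.0, rng=None):
    """Fan-triangulated flat disk for plane-fit fixtures."""
    angles = np.linspace(0, 2 * pi, n_seg, endpoint=False)
    axes = [a for a in range(3) if a != normal_axis]
    verts = [np.asarray(center, dtype=float)]
    for a in angles:
        p = np.asarray(center, dtype=float)
        p[axes[0]] += radius * np.cos(a)
        p[axes[1]] += radius * np.sin(a)
        if jitter and rng is not None:
            p[normal_axis] += rng.uniform(-jitter, jitter)
        verts.append(p)
    faces = [[0, i, i % n_seg + 1] for i in range(1, n_seg + 1)]
    return np.asarray(verts), np.asarray(faces)


class TestFitNeckCutPlane:
    def test_phantom_plane_location_and_normal(self, iso_phantom):
        vol, _ = iso_phantom
        mesh = extract_surface(vol)
        plane = fit_neck_cut_plane(mesh, dist_tol=0.75 * max(vol.spacing))
        axis = np.array([0.0, 0.0, 1.0])
        angle = np.degrees(np.arccos(abs(np.dot(plane.normal, axis))))
        assert angle < 3.0
        center = (np.asarray(vol.shape) - 1) / 2 * np.asarray(vol.spacing)
        offset = np.dot(np.asarray(plane.point) - center, axis)
        assert offset == pytest.approx(-15.0, abs=max(vol.spacing))
        assert plane.normal[2] < 0  # oriented toward the neck side
        assert 0 < plane.inlier_fraction <= 1

    def test_flat_disk_on_sphere_rms_near_zero(self):
        # analytic sphere with a cap replaced by a flat fan-triangulated disk
        R, alpha = 25.0, 0.7
        n_th, n_ph = 40, 60
        thetas = np.linspace(alpha, pi, n_th)
        phis = np.linspace(0, 2 * pi, n_ph, endpoint=False)
        grid = np.array(
            [
                [R * np.sin(t) * np.cos(p), R * np.sin(t) * np.sin(p), R * np.cos(t)]
                for t in thetas
                for p in phis
            ]
        )
        faces = []
        for i in range(n_th - 1):
            for j in range(n_ph):
                a = i * n_ph + j
                b = i * n_ph + (j + 1) % n_ph
                c = (i + 1) * n_ph + j
                d = (i + 1) * n_ph + (j + 1) % n_ph
                faces += [[a, b, c], [b, d, c]]
        # flat disk closing the removed cap, at z = R cos(alpha)
        dv, dfaces = _disk_mesh([0, 0, R * cos(alpha)], 2, R * np.sin(alpha), n_seg=n_ph)
        verts = np.vstack([grid, dv])
        faces = np.asarray(faces + (dfaces + len(grid)).tolist())
        mesh = SurfaceMesh(verts, faces, np.ones(len(faces)))
        plane = fit_neck_cut_plane(mesh, dist_tol=0.5)
        assert plane.rms_residual < 1e-6
        assert abs(plane.normal[2]) > 0.999

    def test_equal_clusters_lower_rms_wins(self):
        rng = np.random.default_rng(0)
        v1, f1 = _disk_mesh([0, 0, 0], 2, 10.0)
        v2, f2 = _disk_mesh([40, 0, 8.0], 2, 10.0, jitter=0.3, rng=rng)
        verts = np.vstack([v1, v2])
        faces = np.vstack([f1, f2 + len(v1)])
        mesh = SurfaceMesh(verts, faces, np.ones(len(faces)))
        plane = fit_neck_cut_plane(mesh, dist_tol=0.5, min_support=0.01)
        # the perfectly flat disk (at x ~ 0) should be chosen
        assert abs(plane.point[0]) < 5.0
        assert plane.rms_residual < 1e-6

    def test_sphere_without_flat_region_raises(self):
        n, sp = 46, 1.0
        c = (n - 1) / 2 * sp
        ax = np.arange(n) * sp - c
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        labels = ((X**2 + Y**2 + Z**2) <= 20.0**2).astype(np.int16)
        vol = LabelVolume("sphere", labels, (sp, sp, sp))
        mesh = extract_surface(vol)
        with pytest.raises(NeckCutNotFoundError):
            fit_neck_cut_plane(mesh, dist_tol=0.75)

    def test_empty_mesh_errors(self):
        mesh = SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0))
        with pytest.raises(ValueError):
            fit_neck_cut_plane(mesh)


class TestTrimMesh:
    def test_far_plane_zero_margin_is_identity(self, coarse_phantom):
        vol, _ = coarse_phantom
        mesh = extract_surface(vol)
        plane = CutPlane(point=(0.0, 0.0, -500.0), normal=(0.0, 0.0, -1.0),
                         inlier_fraction=1.0, rms_residual=0.0)
        trimmed = trim_mesh(mesh, plane, margin=0.0)
        assert trimmed.n_faces == mesh.n_faces
        assert trimmed.total_area == pytest.approx(mesh.total_area)

    def test_trimmed_area_matches_spherical_zone(self, iso_phantom):
        vol, truth = iso_phantom
        mesh = extract_surface(vol)
        plane = fit_neck_cut_plane(mesh, dist_tol=0.75 * max(vol.spacing))
        trimmed = trim_mesh(mesh, plane, margin=3.0)
        zone = 2 * pi * 25 * (25 + 15 - 3)  # mm^2
        assert trimmed.total_area == pytest.approx(zone, rel=0.05)

    def test_trim_is_monotone(self, iso_phantom):
        vol, _ = iso_phantom
        mesh = extract_surface(vol)
        plane = fit_neck_cut_plane(mesh, dist_tol=0.75 * max(vol.spacing))
        trimmed = trim_mesh(mesh, plane, margin=3.0)
        assert trimmed.total_area < mesh.total_area
        assert trimmed.n_faces < mesh.n_faces

    def test_trimming_everything_errors(self, coarse_phantom):
        vol, _ = coarse_phantom
        mesh = extract_surface(vol)
        plane = CutPlane(point=(0.0, 0.0, 500.0), normal=(0.0, 0.0, -1.0),
                         inlier_fraction=1.0, rms_residual=0.0)
        with pytest.raises(ValueError, match="every face"):
            trim_mesh(mesh, plane, margin=3.0)


class TestQuantifyCase:
    def test_reference_phantom_metrics(self, iso_phantom):
        vol, truth = iso_phantom
        m = quantify_case(vol)
        assert m.necrotic_volume == pytest.approx(truth.necrotic_volume, rel=0.02)
        assert m.head_surface == pytest.approx(truth.head_surface, rel=0.05)
        assert m.necrotic_surface == pytest.approx(truth.necrotic_surface, rel=0.05)
        assert abs(m.pct_necrotic_surface - truth.pct_necrotic_surface) < 3.0
        assert m.provenance["cut_plane"] is not None

    def test_no_lesion_all_zero(self, theta0_phantom):
        vol, _ = theta0_phantom
        m = quantify_case(vol)
        assert m.necrotic_volume == 0
        assert m.necrotic_surface == 0
        assert m.pct_necrotic_volume == 0
        assert m.pct_necrotic_surface == 0

    def test_deterministic(self, coarse_phantom):
        vol, _ = coarse_phantom
        assert quantify_case(vol) == quantify_case(vol)

    def test_percent_invariants(self, coarse_phantom):
        vol, _ = coarse_phantom
        m = quantify_case(vol)
        assert m.pct_necrotic_volume == pytest.approx(
            100 * m.necrotic_volume / (m.necrotic_volume + m.unaffected_volume)
        )
        assert m.pct_necrotic_surface == pytest.approx(
            100 * m.necrotic_surface / m.head_surface
        )
        assert 0 <= m.necrotic_surface <= m.head_surface

    def test_no_trim_fallback_records_warning(self):
        # a plain sphere has no flat cut: quantify degrades to no-trim mode
        n, sp = 40, 1.2
        c = (n - 1) / 2 * sp
        ax = np.arange(n) * sp - c
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        labels = ((X**2 + Y**2 + Z**2) <= 20.0**2).astype(np.int16)
        vol = LabelVolume("sphere", labels, (sp, sp, sp))
        m = quantify_case(vol)
        assert m.provenance["cut_plane"] is None
        assert any("no-trim" in w for w in m.provenance["warnings"])
        assert m.head_surface == pytest.approx(4 * pi * 400 / 100, rel=0.05)

    def test_origin_translation_invariance(self, coarse_phantom):
        vol, _ = coarse_phantom
        moved = LabelVolume(vol.case_id, vol.labels.copy(), vol.spacing, origin=(11.5, -40.25, 7.0))
        m0 = quantify_case(vol)
        m1 = quantify_case(moved)
        for key, val in m0.as_dict().items():
            assert m1.as_dict()[key] == pytest.approx(val, abs=1e-8)

    def test_anisotropic_grid_volume_within_8pct(self):
        vol, truth = generate_phantom(PhantomSpec(grid="aniso2d"))
        m = quantify_case(vol)
        assert m.necrotic_volume == pytest.approx(truth.necrotic_volume, rel=0.08)
        assert m.unaffected_volume == pytest.approx(truth.unaffected_volume, rel=0.08)

    def test_ply_export(self, tmp_path, coarse_phantom):
        vol, _ = coarse_phantom
        mesh = extract_surface(vol)
        path = tmp_path / "mesh.ply"
        write_ply(mesh, path)
        text = path.read_text()
        assert text.startswith("ply")
        assert f"element face {mesh.n_faces}" in text
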