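"""Six-parameter necrosis quantification from a label volume.

Pipeline: voxel volumetry -> outer-surface mesh extraction -> neck-cut
plane fit -> 3 mm trim -> per-face tissue attribution. Everything internal
is mm / mm^2 / mm^3; reported metrics are cm^3 and cm^2.

The label map is pre-smoothed with a small Gaussian (0.625 voxels per
axis) before the 0.5-level marching-cubes extraction; this removes the
voxelization staircase that otherwise inflates curved-surface area by
~9 %, while leaving genuinely flat regions flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import cos, radians
from pathlib import Path
from typing import Any

import numpy as np
from scipy import ndimage
from skimage import measure

from .mask_io import Finding, LabelVolume, validate_for_quantification

__all__ = [
    "SurfaceMesh",
    "CutPlane",
    "NecrosisMetrics",
    "NeckCutNotFoundError",
    "compute_volumes",
    "extract_surface",
    "fit_neck_cut_plane",
    "trim_mesh",
    "quantify_case",
    "write_ply",
]

#: Gaussian pre-smoothing, in voxels per axis, applied before isosurfacing.
SMOOTHING_SIGMA_VOX = 0.625

#: tissue-attribution sampling: Gaussian sigma (voxels) for the per-tissue
#: indicator fields, and the inward retraction depth in units of the cubic
#: voxel edge length (volume^(1/3)). Sampling slightly inside the bone
#: localizes the necrotic/unaffected interface with subvoxel accuracy and
#: avoids the corner bias right at the outer surface.
ATTRIBUTION_SIGMA_VOX = 0.8
ATTRIBUTION_DEPTH_VOX = 1.5

#: defaults for the consensus plane fit
NORMAL_TOL_DEG = 10.0
MIN_SUPPORT = 0.02
N_TRIALS = 100
PLANE_SEED = 20230112


class NeckCutNotFoundError(RuntimeError):
    """No planar cluster with sufficient support was found in the mesh."""


@dataclass
class SurfaceMesh:
    """Triangulated outer surface in world coordinates (mm).

    ``face_label`` holds the tissue label (1 unaffected / 2 necrotic) of
    the foreground voxel nearest each face; derived areas/normals are
    computed lazily and cached.
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_label: np.ndarray
    face_necrotic_weight: np.ndarray | None = None
    warnings: list[Finding] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.face_label = np.asarray(self.face_label, dtype=np.uint8).reshape(-1)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("faces reference out-of-range vertex indices")
        if len(self.face_label) != len(self.faces):
            raise ValueError("face_label length must equal number of faces")
        if self.face_necrotic_weight is None:
            self.face_necrotic_weight = (self.face_label == 2).astype(np.float64)
        else:
            self.face_necrotic_weight = np.asarray(self.face_necrotic_weight, dtype=np.float64).reshape(-1)
            if len(self.face_necrotic_weight) != len(self.faces):
                raise ValueError("face_necrotic_weight length must equal number of faces")
        self._cache: dict[str, np.ndarray] = {}

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def _tri(self) -> np.ndarray:
        return self.vertices[self.faces]

    @property
    def face_cross(self) -> np.ndarray:
        if "cross" not in self._cache:
            t = self._tri()
            self._cache["cross"] = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return self._cache["cross"]

    @property
    def face_areas(self) -> np.ndarray:
        if "areas" not in self._cache:
            self._cache["areas"] = 0.5 * np.linalg.norm(self.face_cross, axis=1)
        return self._cache["areas"]

    @property
    def face_normals(self) -> np.ndarray:
        if "normals" not in self._cache:
            c = self.face_cross
            norm = np.linalg.norm(c, axis=1, keepdims=True)
            self._cache["normals"] = np.divide(
                c, np.where(norm > 0, norm, 1.0), out=np.zeros_like(c)
            )
        return self._cache["normals"]

    @property
    def face_centroids(self) -> np.ndarray:
        if "centroids" not in self._cache:
            self._cache["centroids"] = self._tri().mean(axis=1)
        return self._cache["centroids"]

    @property
    def total_area(self) -> float:
        return float(self.face_areas.sum())

    def area_of_label(self, label: int) -> float:
        return float(self.face_areas[self.face_label == label].sum())

    @property
    def necrotic_area(self) -> float:
        """Fractionally attributed necrotic surface area (mm^2)."""
        return float((self.face_areas * self.face_necrotic_weight).sum())

    def submesh(self, keep: np.ndarray) -> "SurfaceMesh":
        """Face-subset mesh (vertices are kept as-is; labels preserved)."""
        return SurfaceMesh(
            vertices=self.vertices,
            faces=self.faces[keep],
            face_label=self.face_label[keep],
            face_necrotic_weight=self.face_necrotic_weight[keep],
            warnings=list(self.warnings),
        )


@dataclass(frozen=True)
class CutPlane:
    """A fitted neck-cut plane.

    ``normal`` is unit length and oriented toward the neck side (the side
    holding less mesh area), so positive signed distance = neck side.
    """

    point: tuple[float, float, float]
    normal: tuple[float, float, float]
    inlier_fraction: float
    rms_residual: float

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts) - np.asarray(self.point)) @ np.asarray(self.normal)


@dataclass
class NecrosisMetrics:
    """The six necrosis parameters for one case (cm^3 / cm^2 / %)."""

    necrotic_volume: float
    unaffected_volume: float
    pct_necrotic_volume: float
    necrotic_surface: float
    head_surface: float
    pct_necrotic_surface: float
    provenance: dict[str, Any] = field(default_factory=dict, compare=False)

    def as_dict(self) -> dict[str, float]:
        return {
            "necrotic_volume": self.necrotic_volume,
            "unaffected_volume": self.unaffected_volume,
            "pct_necrotic_volume": self.pct_necrotic_volume,
            "necrotic_surface": self.necrotic_surface,
            "head_surface": self.head_surface,
            "pct_necrotic_surface": self.pct_necrotic_surface,
        }


PARAMETER_NAMES = (
    "necrotic_volume",
    "unaffected_volume",
    "pct_necrotic_volume",
    "necrotic_surface",
    "head_surface",
    "pct_necrotic_surface",
)


def _require_quantifiable(vol: LabelVolume) -> None:
    findings = validate_for_quantification(vol)
    blockers = [f for f in findings if f.blocking]
    if blockers:
        raise ValueError(f"volume not quantifiable: {'; '.join(f.message for f in blockers)}")


def compute_volumes(vol: LabelVolume) -> tuple[float, float, float]:
    """Voxel-count volumetry -> (necrotic cm^3, unaffected cm^3, percent)."""
    _require_quantifiable(vol)
    vv = vol.voxel_volume_mm3
    necro = vol.label_count(2) * vv / 1000.0
    unaff = vol.label_count(1) * vv / 1000.0
    total = necro + unaff
    pct = 100.0 * necro / total if total > 0 else 0.0
    return necro, unaff, pct


def extract_surface(vol: LabelVolume, smoothing_sigma_vox: float = SMOOTHING_SIGMA_VOX) -> SurfaceMesh:
    """Marching-cubes isosurface of the foreground, with tissue attribution.

    The volume is zero-padded by one voxel so surfaces touching the grid
    boundary still close; a warning finding is attached in that case.

    Tissue attribution samples Gaussian-smoothed necrotic/unaffected
    indicator fields at a point retracted from each face centroid into the
    bone along the inward normal; the necrotic fraction there becomes the
    face's ``face_necrotic_weight`` (and ``face_label`` is its rounding).
    The necrotic surface is thus the externally visible part of the lesion,
    not the internal necrotic-unaffected interface.
    """
    _require_quantifiable(vol)
    fg = vol.foreground
    spacing = np.asarray(vol.spacing)
    warnings: list[Finding] = []
    touches = any(fg.take(0, axis=ax).any() or fg.take(-1, axis=ax).any() for ax in range(3))
    if touches:
        warnings.append(
            Finding("open-boundary", "foreground touches the grid boundary; surface was closed by padding", "warning")
        )

    fg_field = fg.astype(np.float32)
    if smoothing_sigma_vox > 0:
        fg_field = ndimage.gaussian_filter(fg_field, smoothing_sigma_vox)
    verts, faces, _, _ = measure.marching_cubes(np.pad(fg_field, 1), level=0.5, spacing=vol.spacing)
    # undo the 1-voxel pad, then place in world coordinates
    verts = verts - spacing + np.asarray(vol.origin)

    tri = verts[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    normals = cross / np.maximum(np.linalg.norm(cross, axis=1, keepdims=True), 1e-12)
    centroids = tri.mean(axis=1)

    def _sample(field: np.ndarray, pts: np.ndarray) -> np.ndarray:
        idx = ((pts - np.asarray(vol.origin)) / spacing).T
        return ndimage.map_coordinates(field, idx, order=1, mode="nearest")

    # orient normals outward: smoothed foreground decreases outward
    step = 0.5 * float(spacing.min())
    inward = _sample(fg_field, centroids + step * normals) > _sample(fg_field, centroids - step * normals)
    normals[inward] = -normals[inward]

    s2 = ndimage.gaussian_filter((vol.labels == 2).astype(np.float32), ATTRIBUTION_SIGMA_VOX)
    s1 = ndimage.gaussian_filter((vol.labels == 1).astype(np.float32), ATTRIBUTION_SIGMA_VOX)
    depth = ATTRIBUTION_DEPTH_VOX * float(vol.voxel_volume_mm3 ** (1.0 / 3.0))
    probes = centroids - depth * normals
    v2 = _sample(s2, probes)
    v1 = _sample(s1, probes)
    weight = np.where(v1 + v2 > 0, v2 / np.maximum(v1 + v2, 1e-9), 0.0)
    face_label = np.where(weight > 0.5, 2, 1).astype(np.uint8)
    return SurfaceMesh(
        vertices=verts,
        faces=faces,
        face_label=face_label,
        face_necrotic_weight=weight,
        warnings=warnings,
    )


def _plane_from_points(pts: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted least-squares plane through points: (point, unit normal)."""
    w = weights / weights.sum()
    c = (pts * w[:, None]).sum(axis=0)
    q = (pts - c) * np.sqrt(w)[:, None]
    _, _, vt = np.linalg.svd(q, full_matrices=False)
    return c, vt[-1]


def fit_neck_cut_plane(
    mesh: SurfaceMesh,
    normal_tol_deg: float = NORMAL_TOL_DEG,
    dist_tol: float | None = None,
    min_support: float = MIN_SUPPORT,
    n_trials: int = N_TRIALS,
    seed: int = PLANE_SEED,
) -> CutPlane:
    """Seeded consensus fit of the largest near-planar face cluster.

    Trial planes are seeded from area-weighted random faces; a face is an
    inlier when its normal agrees within ``normal_tol_deg`` and its
    centroid is within ``dist_tol`` of the plane. The winning cluster is
    the one with the largest inlier area; clusters within 1 % of the best
    area are disambiguated by lower RMS residual. The fit is refined twice
    on the inlier centroids and the normal is oriented toward the neck
    side (the side carrying less mesh area).
    """
    if mesh.n_faces == 0:
        raise ValueError("mesh is empty")
    areas = mesh.face_areas
    centroids = mesh.face_centroids
    normals = mesh.face_normals
    total_area = areas.sum()
    if dist_tol is None:
        edges = mesh.vertices[mesh.faces[:, 1]] - mesh.vertices[mesh.faces[:, 0]]
        dist_tol = 1.5 * float(np.median(np.linalg.norm(edges, axis=1)))
    cos_tol = cos(radians(normal_tol_deg))

    rng = np.random.default_rng(seed)
    p = areas / total_area
    seeds = rng.choice(mesh.n_faces, size=min(n_trials, mesh.n_faces), p=p)

    candidates: list[tuple[float, float, np.ndarray]] = []  # (area, rms, inlier mask)
    for fi in seeds:
        n0 = normals[fi]
        c0 = centroids[fi]
        ang_ok = normals @ n0 >= cos_tol
        dist = (centroids - c0) @ n0
        inl = ang_ok & (np.abs(dist) <= dist_tol)
        a = float(areas[inl].sum())
        if a <= 0:
            continue
        rms = float(np.sqrt(np.average(dist[inl] ** 2, weights=areas[inl])))
        candidates.append((a, rms, inl))
    if not candidates:
        raise NeckCutNotFoundError("no flat neck cut found (no planar consensus)")

    best_area = max(c[0] for c in candidates)
    near_best = [c for c in candidates if c[0] >= 0.99 * best_area]
    near_best.sort(key=lambda c: (c[1], -c[0]))  # lower rms, then larger area
    _, _, inliers = near_best[0]

    point = normal = None
    for _ in range(2):  # refinement passes
        point, normal = _plane_from_points(centroids[inliers], areas[inliers])
        dist = (centroids - point) @ normal
        ang_ok = np.abs(normals @ normal) >= cos_tol
        inliers = ang_ok & (np.abs(dist) <= dist_tol)
        if not inliers.any():
            raise NeckCutNotFoundError("no flat neck cut found (refinement lost all inliers)")

    dist = (centroids - point) @ normal
    inlier_area = float(areas[inliers].sum())
    if inlier_area / total_area < min_support:
        raise NeckCutNotFoundError(
            f"no flat neck cut found: best planar cluster holds "
            f"{100 * inlier_area / total_area:.1f}% of surface area "
            f"(minimum {100 * min_support:.0f}%)"
        )
    rms = float(np.sqrt(np.average(dist[inliers] ** 2, weights=areas[inliers])))

    # orient normal toward the neck side = side with less area
    pos_area = float(areas[dist > 0].sum())
    neg_area = float(areas[dist < 0].sum())
    if pos_area > neg_area:
        normal = -normal
    return CutPlane(
        point=tuple(float(v) for v in point),
        normal=tuple(float(v) for v in normal),
        inlier_fraction=inlier_area / total_area,
        rms_residual=rms,
    )


def trim_mesh(mesh: SurfaceMesh, plane: CutPlane, margin: float = 3.0) -> SurfaceMesh:
    """Remove faces within ``margin`` mm of the plane or on its neck side.

    A face is removed when its centroid's signed distance (positive =
    neck side) exceeds ``-margin``; labels on kept faces are preserved.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    d = plane.signed_distance(mesh.face_centroids)
    keep = d < -margin
    if not keep.any():
        raise ValueError("trimming removed every face; check the fitted plane")
    return mesh.submesh(keep)


def quantify_case(
    vol: LabelVolume,
    margin: float = 3.0,
    trim: bool = True,
    plane_seed: int = PLANE_SEED,
) -> NecrosisMetrics:
    """Full six-parameter quantification of one label volume.

    Composes volumetry, surface extraction, neck-cut plane fitting and
    trimming. When no flat neck cut is found the case degrades to no-trim
    mode with a recorded warning instead of failing.
    """
    necro_vol, unaff_vol, pct_vol = compute_volumes(vol)
    mesh = extract_surface(vol)
    provenance: dict[str, Any] = {
        "case_id": vol.case_id,
        "trim_margin_mm": margin if trim else None,
        "warnings": [f.message for f in mesh.warnings],
    }
    trimmed = mesh
    if trim:
        try:
            plane = fit_neck_cut_plane(mesh, dist_tol=0.75 * max(vol.spacing), seed=plane_seed)
            trimmed = trim_mesh(mesh, plane, margin=margin)
            provenance["cut_plane"] = {
                "point": plane.point,
                "normal": plane.normal,
                "inlier_fraction": plane.inlier_fraction,
                "rms_residual": plane.rms_residual,
            }
        except NeckCutNotFoundError as exc:
            provenance["warnings"].append(f"no-trim fallback: {exc}")
            provenance["cut_plane"] = None

    head_mm2 = trimmed.total_area
    necro_mm2 = trimmed.necrotic_area
    provenance["unaffected_only_surface_cm2"] = trimmed.area_of_label(1) / 100.0
    return NecrosisMetrics(
        necrotic_volume=necro_vol,
        unaffected_volume=unaff_vol,
        pct_necrotic_volume=pct_vol,
        necrotic_surface=necro_mm2 / 100.0,
        head_surface=head_mm2 / 100.0,
        pct_necrotic_surface=100.0 * necro_mm2 / head_mm2 if head_mm2 > 0 else 0.0,
        provenance=provenance,
    )


def write_ply(mesh: SurfaceMesh, path: str | Path) -> None:
    """Export a labeled mesh as ASCII PLY (label as a per-face property)."""
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(mesh.vertices)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nproperty uchar label\n")
        fh.write("end_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f, lab in zip(mesh.faces, mesh.face_label):
            fh.write(f"3 {f[0]} {f[1]} {f[2]} {int(lab)}\n")
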