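"""Modified Kerboul angle from a label volume.

The necrotic arc is measured in the two mid-planes through the fitted
femoral head center: the midcoronal plane (perpendicular to the
posterior-anterior axis, ``axis1``) and the midsagittal plane
(perpendicular to the left-right axis, ``axis0``). Per plane, the angle is
the span of the smallest circular sector, with vertex at the head center,
containing every necrotic voxel on the external head boundary of that
slice; the two spans are summed.

Conventions fixed here (the clinical source protocol leaves them open):
a single slice nearest the center (no slab averaging), angles binned at
0.5 degrees, and the span of the extreme rays rather than the summed
coverage of disconnected arcs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .mask_io import LabelVolume
from .quant3d import (
    NeckCutNotFoundError,
    extract_surface,
    fit_neck_cut_plane,
)

__all__ = [
    "HeadFit",
    "KerboulMeasurement",
    "fit_head_sphere",
    "necrotic_arc_angle",
    "modified_kerboul",
]

ANGLE_BIN_DEG = 0.5

#: slice-normal axis per mid-plane name (axis1 = P->A, axis0 = L->R)
PLANE_NORMAL_AXIS = {"coronal": 1, "sagittal": 0}


@dataclass(frozen=True)
class HeadFit:
    """Least-squares sphere fit of the femoral head surface."""

    center: tuple[float, float, float]
    radius: float
    rms_residual: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("fitted head radius must be positive")


@dataclass(frozen=True)
class KerboulMeasurement:
    coronal_angle: float
    sagittal_angle: float
    modified_angle: float

    def __post_init__(self) -> None:
        for a in (self.coronal_angle, self.sagittal_angle):
            if not 0.0 <= a <= 360.0:
                raise ValueError("arc angles must lie in [0, 360] degrees")


def _surface_points_world(vol: LabelVolume) -> np.ndarray:
    fg = vol.foreground
    boundary = fg & ~ndimage.binary_erosion(fg)
    idx = np.argwhere(boundary)
    if idx.size == 0:
        raise ValueError("volume has no foreground surface")
    return vol.index_to_world(idx)


def _sphere_lstsq(pts: np.ndarray) -> HeadFit:
    # algebraic fit: |p|^2 = 2 c.p + (R^2 - |c|^2), linear in (c, t)
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise ValueError("degenerate geometry: surface points do not determine a sphere")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if not np.isfinite(r2) or r2 <= 0:
        raise ValueError("degenerate geometry: sphere fit produced a non-positive radius")
    radius = float(np.sqrt(r2))
    resid = np.linalg.norm(pts - center, axis=1) - radius
    return HeadFit(
        center=tuple(float(c) for c in center),
        radius=radius,
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )


def fit_head_sphere(vol: LabelVolume, margin: float = 3.0) -> HeadFit:
    """Fit a sphere to the external foreground surface voxels.

    When a neck-cut plane can be fitted, surface voxels within ``margin``
    of it (and on its neck side) are excluded so the flat cut and neck
    stub do not bias the fit.
    """
    pts = _surface_points_world(vol)
    try:
        mesh = extract_surface(vol)
        plane = fit_neck_cut_plane(mesh, dist_tol=0.75 * max(vol.spacing))
        keep = plane.signed_distance(pts) < -margin
        if np.count_nonzero(keep) >= 20:
            pts = pts[keep]
    except (NeckCutNotFoundError, ValueError):
        pass
    return _sphere_lstsq(pts)


def necrotic_arc_angle(vol: LabelVolume, head: HeadFit, plane_axis: str) -> float:
    """Angular span (degrees) of the necrotic external boundary in a mid-plane.

    ``plane_axis`` is ``"coronal"`` or ``"sagittal"``. Returns 0 when the
    slice contains no necrotic boundary points.
    """
    if plane_axis not in PLANE_NORMAL_AXIS:
        raise ValueError(f"plane_axis must be 'coronal' or 'sagittal', got {plane_axis!r}")
    ax = PLANE_NORMAL_AXIS[plane_axis]
    center = np.asarray(head.center)
    j = int(round((center[ax] - vol.origin[ax]) / vol.spacing[ax]))
    if not 0 <= j < vol.shape[ax]:
        raise ValueError(
            f"head center lies outside the grid along axis {ax} (slice {j} of {vol.shape[ax]})"
        )
    slice_labels = np.take(vol.labels, j, axis=ax)
    fg2d = slice_labels > 0
    if not fg2d.any():
        return 0.0
    boundary = fg2d & ~ndimage.binary_erosion(fg2d)
    pts2d = np.argwhere(boundary & (slice_labels == 2))
    if len(pts2d) == 0:
        return 0.0

    in_plane = [a for a in range(3) if a != ax]
    u = pts2d[:, 0] * vol.spacing[in_plane[0]] + vol.origin[in_plane[0]] - center[in_plane[0]]
    v = pts2d[:, 1] * vol.spacing[in_plane[1]] + vol.origin[in_plane[1]] - center[in_plane[1]]
    ang = np.degrees(np.arctan2(v, u))
    bins = np.unique(np.round(ang / ANGLE_BIN_DEG) * ANGLE_BIN_DEG)
    if len(bins) == 1:
        return 0.0
    gaps = np.diff(bins)
    wrap_gap = 360.0 - (bins[-1] - bins[0])
    all_gaps = np.append(gaps, wrap_gap)
    largest_gap = float(all_gaps.max())
    span = 360.0 - largest_gap
    # The extreme boundary voxels quantize the true arc ends inward by up
    # to one angular sampling step each; widening by the typical step (the
    # median inter-point gap) resolves the tie toward the larger span.
    others = all_gaps[all_gaps < largest_gap]
    if others.size:
        span = min(360.0, span + float(np.median(others)) + ANGLE_BIN_DEG)
    return float(span)


def modified_kerboul(vol: LabelVolume, head: HeadFit | None = None) -> KerboulMeasurement:
    """Sum of the midcoronal and midsagittal necrotic arc angles."""
    if head is None:
        head = fit_head_sphere(vol)
    cor = necrotic_arc_angle(vol, head, "coronal")
    sag = necrotic_arc_angle(vol, head, "sagittal")
    return KerboulMeasurement(coronal_angle=cor, sagittal_angle=sag, modified_angle=cor + sag)
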