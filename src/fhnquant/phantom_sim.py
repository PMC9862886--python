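"""Voxelized hip phantoms with closed-form ground truth.

The phantom is a sphere of radius ``R`` (femoral head) cut by a flat plane
at distance ``d`` below the head center along the wedge axis, with a short
cylindrical neck stub continuing below the cut so that a flat "segmentation
ends here" region exists for the plane fit to find. The necrotic lesion is
a spherical sector (cone with apex at the head center) of half-angle
``theta`` about the wedge axis, which gives every downstream quantity an
analytic oracle:

* necrotic volume          ``(2/3) * pi * R^3 * (1 - cos theta)``
* necrotic (cap) surface   ``2 * pi * R^2 * (1 - cos theta)``
* trimmed head surface     ``2 * pi * R * (R + d - margin)``  (spherical zone
  above the trim offset; ``margin`` is the neck-cut trim margin)
* per-plane necrotic arc   ``2 * theta``; modified Kerboul angle ``4 * theta``

Voxel membership is decided by the voxel-center test (no partial-volume
weighting), matching binary label maps from manual segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, cos, pi, radians
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .mask_io import ArcoGrade, CaseRecord, LabelVolume, Source

__all__ = [
    "GRID_SPACINGS",
    "NECK_STUB_MM",
    "PhantomSpec",
    "PhantomTruth",
    "NoiseSpec",
    "CohortSpec",
    "CohortCase",
    "UnreachableDiceError",
    "compute_truth",
    "generate_phantom",
    "perturb_segmentation",
    "draw_cohort_specs",
    "generate_cohort",
]

#: grid dialects: near-isotropic "3D MRI" and the anisotropic cropped
#: coronal "2D MRI" grid (0.44 x 2.4 x 0.44 mm); ``coarse`` is a fast
#: dialect for large simulation sweeps and tests.
GRID_SPACINGS: dict[str, tuple[float, float, float]] = {
    "iso3d": (0.8, 0.8, 0.8),
    "aniso2d": (0.44, 2.4, 0.44),
    "coarse": (1.6, 1.6, 1.6),
}

#: length of the neck stub kept below the cut plane (mm). Short enough to
#: be fully removed by the default 3 mm trim, long enough that the flat
#: annulus at the cut and the stub end form distinct planar clusters.
NECK_STUB_MM = 2.5


class UnreachableDiceError(ValueError):
    """Raised when a Dice target cannot be met with boundary-band noise."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one hip phantom."""

    head_radius: float = 25.0
    wedge_half_angle_deg: float = 45.0
    wedge_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)  # superior
    neck_radius: float = 12.0
    cut_distance: float = 15.0
    grid: str = "iso3d"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.wedge_half_angle_deg <= 90.0):
            raise ValueError("wedge_half_angle_deg must be in [0, 90]")
        if not (0.0 < self.cut_distance < self.head_radius):
            raise ValueError("cut_distance must satisfy 0 < d < head_radius")
        if self.neck_radius >= self.head_radius:
            raise ValueError("neck_radius must be < head_radius")
        if self.grid not in GRID_SPACINGS:
            raise ValueError(f"unknown grid dialect {self.grid!r}; use one of {sorted(GRID_SPACINGS)}")
        ax = np.asarray(self.wedge_axis, dtype=float)
        n = np.linalg.norm(ax)
        if n == 0:
            raise ValueError("wedge_axis must be nonzero")
        object.__setattr__(self, "wedge_axis", tuple(ax / n))

    @property
    def spacing(self) -> tuple[float, float, float]:
        return GRID_SPACINGS[self.grid]


@dataclass(frozen=True)
class PhantomTruth:
    """Closed-form ground truth for one phantom (cm^3 / cm^2 / degrees).

    ``head_surface`` is the trimmed head surface, i.e. the spherical zone
    remaining after removing everything within ``trim_margin`` of the
    neck-cut plane — the quantity the surface pipeline measures.
    """

    necrotic_volume: float
    unaffected_volume: float
    pct_necrotic_volume: float
    necrotic_surface: float
    head_surface: float
    pct_necrotic_surface: float
    kerboul_coronal: float
    kerboul_sagittal: float
    kerboul_modified: float
    trim_margin: float = 3.0


@dataclass(frozen=True)
class NoiseSpec:
    """Boundary-noise calibration targets for segmentation perturbation."""

    target_dice_necrotic: float = 0.75
    target_dice_unaffected: float = 0.91
    seed: int = 0

    def __post_init__(self) -> None:
        for t in (self.target_dice_necrotic, self.target_dice_unaffected):
            if not (0.0 < t <= 1.0):
                raise ValueError("Dice targets must be in (0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic early/advanced cohort.

    The default half-angle ranges give the advanced group stochastically
    larger lesions (the ranges overlap, as real cohorts do).
    """

    n_early: int = 6
    n_advanced: int = 24
    theta_range_early: tuple[float, float] = (20.0, 40.0)
    theta_range_advanced: tuple[float, float] = (40.0, 62.0)
    r_range: tuple[float, float] = (20.0, 30.0)
    grid: str = "iso3d"
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.theta_range_early, self.theta_range_advanced, self.r_range):
            if not lo <= hi:
                raise ValueError("ranges must satisfy lo <= hi")
        if self.n_early < 0 or self.n_advanced < 0 or self.n_early + self.n_advanced == 0:
            raise ValueError("cohort must contain at least one case")
        me = sum(self.theta_range_early) / 2
        ma = sum(self.theta_range_advanced) / 2
        if ma <= me:
            raise ValueError("advanced theta range must dominate the early range")


class CohortCase(NamedTuple):
    record: CaseRecord
    volume: LabelVolume
    truth: PhantomTruth


def compute_truth(spec: PhantomSpec, trim_margin: float = 3.0) -> PhantomTruth:
    """Closed-form volumes (cm^3), surfaces (cm^2) and angles (degrees)."""
    R = spec.head_radius
    d = spec.cut_distance
    theta = radians(spec.wedge_half_angle_deg)
    necro_mm3 = (2.0 / 3.0) * pi * R**3 * (1.0 - cos(theta))
    h = R + d  # height of the spherical cap kept above the cut plane
    above_mm3 = pi * h * h * (3.0 * R - h) / 3.0
    stub_mm3 = pi * spec.neck_radius**2 * NECK_STUB_MM
    unaff_mm3 = above_mm3 - necro_mm3 + stub_mm3
    necro_mm2 = 2.0 * pi * R**2 * (1.0 - cos(theta))
    head_mm2 = 2.0 * pi * R * (R + d - trim_margin)
    total_mm3 = necro_mm3 + unaff_mm3
    arc = 2.0 * spec.wedge_half_angle_deg
    return PhantomTruth(
        necrotic_volume=necro_mm3 / 1000.0,
        unaffected_volume=unaff_mm3 / 1000.0,
        pct_necrotic_volume=100.0 * necro_mm3 / total_mm3 if total_mm3 > 0 else 0.0,
        necrotic_surface=necro_mm2 / 100.0,
        head_surface=head_mm2 / 100.0,
        pct_necrotic_surface=100.0 * necro_mm2 / head_mm2 if head_mm2 > 0 else 0.0,
        kerboul_coronal=arc,
        kerboul_sagittal=arc,
        kerboul_modified=2.0 * arc,
        trim_margin=trim_margin,
    )


def generate_phantom(
    spec: PhantomSpec,
    case_id: str = "phantom",
    trim_margin: float = 3.0,
    shape: tuple[int, int, int] | None = None,
) -> tuple[LabelVolume, PhantomTruth]:
    """Voxelize the phantom and return it with its analytic truth.

    A voxel is necrotic (label 2) iff its center lies inside the sphere,
    above the cut plane, and within the wedge half-angle of the wedge axis;
    unaffected bone (label 1) is the rest of the sphere above the plane
    plus the neck stub cylinder.
    """
    spacing = np.asarray(spec.spacing)
    R, d = spec.head_radius, spec.cut_distance
    axis = np.asarray(spec.wedge_axis)

    half_extent = R + NECK_STUB_MM  # bounding half-width, any wedge axis
    if shape is None:
        shape = tuple(int(ceil(2.0 * half_extent / s)) + 5 for s in spacing)
    required = 2.0 * half_extent + 2.0 * spacing
    extent = np.asarray(shape) * spacing
    if np.any(extent < required):
        raise ValueError(
            f"grid shape {shape} at spacing {tuple(spacing)} spans {tuple(np.round(extent, 1))} mm "
            f"but the phantom needs at least {tuple(np.round(required, 1))} mm"
        )

    center = (np.asarray(shape) - 1) / 2.0 * spacing  # world origin at voxel (0,0,0)
    coords = [np.arange(n) * s - c for n, s, c in zip(shape, spacing, center)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")  # centered world coords

    axial = X * axis[0] + Y * axis[1] + Z * axis[2]
    r2 = X * X + Y * Y + Z * Z
    inside = r2 <= R * R
    above = axial >= -d
    radial2 = np.maximum(r2 - axial * axial, 0.0)
    neck = (radial2 <= spec.neck_radius**2) & (axial < -d) & (axial >= -d - NECK_STUB_MM)

    labels = np.zeros(shape, dtype=np.int16)
    labels[(inside & above) | neck] = 1
    if spec.wedge_half_angle_deg > 0:
        r = np.sqrt(r2)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.where(r > 0, axial / np.where(r > 0, r, 1.0), 1.0)
        necrotic = inside & above & (cosang >= cos(radians(spec.wedge_half_angle_deg)))
        labels[necrotic] = 2

    vol = LabelVolume(case_id=case_id, labels=labels, spacing=tuple(spacing), origin=(0.0, 0.0, 0.0))
    return vol, compute_truth(spec, trim_margin=trim_margin)


# -- segmentation perturbation -------------------------------------------

def _band_candidates(mask: np.ndarray, outward: bool, rings: int) -> np.ndarray:
    """Boolean band of width ``rings`` voxels just inside/outside ``mask``."""
    if outward:
        grown = ndimage.binary_dilation(mask, iterations=rings)
        return grown & ~mask
    shrunk = ndimage.binary_erosion(mask, iterations=rings)
    return mask & ~shrunk


def _pick(rng: np.random.Generator, candidates: np.ndarray, k: int, what: str) -> np.ndarray:
    """Flat indices of ``k`` voxels chosen uniformly from a boolean mask."""
    idx = np.flatnonzero(candidates)
    if idx.size < k:
        raise UnreachableDiceError(
            f"need {k} {what} candidate voxels but only {idx.size} are available"
        )
    return rng.choice(idx, size=k, replace=False)


def _grow_until(mask_fn, need: int, max_rings: int = 6) -> np.ndarray:
    for rings in range(1, max_rings + 1):
        cand = mask_fn(rings)
        if np.count_nonzero(cand) >= need:
            return cand
    return mask_fn(max_rings)


def perturb_segmentation(vol: LabelVolume, noise: NoiseSpec) -> LabelVolume:
    """Emulate rater/network disagreement by seeded boundary-band label flips.

    Balanced flips are used: removing ``k`` voxels from a region and adding
    ``k`` others at its boundary leaves the region size unchanged and gives
    Dice ``1 - k/n`` exactly, so the achieved Dice equals the target up to
    the integer rounding of ``k``. Grid geometry is never altered.
    """
    rng = np.random.default_rng(noise.seed)
    labels = vol.labels.copy()
    A2 = labels == 2
    A1 = labels == 1
    A0 = labels == 0
    n2 = int(A2.sum())
    n1 = int(A1.sum())
    if n1 == 0:
        raise ValueError("volume has no unaffected bone to perturb")

    if noise.target_dice_necrotic == 1.0 and noise.target_dice_unaffected == 1.0:
        return LabelVolume(vol.case_id, labels, vol.spacing, vol.origin)

    # Error budgets. Balanced flips (k out / k in) keep region sizes fixed,
    # so Dice = 1 - k/n per label exactly. Necrotic errors partner with
    # unaffected bone where the unaffected budget allows (c flips) and with
    # background for the remainder, so large lesions can still reach a
    # tight unaffected target.
    k = int(round((1.0 - noise.target_dice_necrotic) * n2)) if n2 else 0
    budget1 = int(round((1.0 - noise.target_dice_unaffected) * n1))
    c = min(k, budget1)
    j = budget1 - c

    if k > 0:
        out_band = _grow_until(lambda r: _band_candidates(A2, outward=False, rings=r), k)
        out_sel = _pick(rng, out_band, k, "necrotic-shrink")
        out_flat = np.zeros(labels.size, dtype=bool)
        out_flat[out_sel] = True
        # partition the outgoing voxels between label-1 and background
        labels.ravel()[out_sel[:c]] = 1
        labels.ravel()[out_sel[c:]] = 0

        in1_band = _grow_until(
            lambda r: _band_candidates(A2, outward=True, rings=r) & A1, max(c, 1)
        )
        in0_band = _grow_until(
            lambda r: _band_candidates(A2, outward=True, rings=r) & A0, max(k - c, 1)
        )
        if c > 0:
            in_sel = _pick(rng, in1_band, c, "necrotic-grow-into-bone")
            labels.ravel()[in_sel] = 2
        if k - c > 0:
            in_sel = _pick(rng, in0_band & ~out_flat.reshape(labels.shape), k - c,
                           "necrotic-grow-into-background")
            labels.ravel()[in_sel] = 2

    # unaffected <-> background flips at the outer bone boundary cover the
    # remaining unaffected error budget
    if j > 0:
        fg = labels > 0
        cur2 = labels == 2

        def out_fn(r: int) -> np.ndarray:
            return _band_candidates(fg, outward=False, rings=r) & A1 & (labels == 1)

        def in_fn(r: int) -> np.ndarray:
            return (
                _band_candidates(fg, outward=True, rings=r)
                & ~A1
                & (labels == 0)
                & ndimage.binary_dilation(labels == 1)
                & ~ndimage.binary_dilation(cur2)
            )

        out_sel = _pick(rng, _grow_until(out_fn, j), j, "foreground-shrink")
        in_sel = _pick(rng, _grow_until(in_fn, j), j, "foreground-grow")
        labels.ravel()[out_sel] = 0
        labels.ravel()[in_sel] = 1

    return LabelVolume(vol.case_id, labels, vol.spacing, vol.origin)


# -- cohorts --------------------------------------------------------------

def _grade_counts(n: int, weights: dict[ArcoGrade, float]) -> list[ArcoGrade]:
    """Deterministic largest-remainder apportionment of grades."""
    items = list(weights.items())
    total = sum(w for _, w in items)
    quotas = [(g, n * w / total) for g, w in items]
    counts = {g: int(q) for g, q in quotas}
    short = n - sum(counts.values())
    for g, q in sorted(quotas, key=lambda t: t[1] - int(t[1]), reverse=True)[:short]:
        counts[g] += 1
    out: list[ArcoGrade] = []
    for g, _ in items:
        out.extend([g] * counts[g])
    return out


#: within-group grade mix: 2 I : 4 II among early, 13 IIIA : 11 IIIB among advanced
EARLY_GRADE_WEIGHTS = {ArcoGrade.I: 2.0, ArcoGrade.II: 4.0}
ADVANCED_GRADE_WEIGHTS = {ArcoGrade.IIIA: 13.0, ArcoGrade.IIIB: 11.0}


def draw_cohort_specs(cohort: CohortSpec) -> list[tuple[str, ArcoGrade, PhantomSpec]]:
    """Draw per-case generative parameters for a cohort, deterministically.

    Half-angles are uniform within the group's range; the cut distance and
    neck radius scale with the head radius. Fully reproducible from
    ``cohort.seed``. Exposed separately so the same geometry can be
    voxelized on several grid dialects.
    """
    rng = np.random.default_rng(cohort.seed)
    grades = _grade_counts(cohort.n_early, EARLY_GRADE_WEIGHTS) + _grade_counts(
        cohort.n_advanced, ADVANCED_GRADE_WEIGHTS
    )
    theta_ranges = [cohort.theta_range_early] * cohort.n_early + [
        cohort.theta_range_advanced
    ] * cohort.n_advanced

    out: list[tuple[str, ArcoGrade, PhantomSpec]] = []
    for i, (grade, th_range) in enumerate(zip(grades, theta_ranges)):
        R = rng.uniform(*cohort.r_range)
        theta = rng.uniform(*th_range)
        spec = PhantomSpec(
            head_radius=R,
            wedge_half_angle_deg=theta,
            neck_radius=0.45 * R,
            cut_distance=0.6 * R,
            grid=cohort.grid,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append((f"case-{i + 1:03d}", grade, spec))
    return out


def generate_cohort(
    cohort: CohortSpec,
    source: Source = Source.MANUAL3D,
    trim_margin: float = 3.0,
) -> list[CohortCase]:
    """Voxelize a deterministic early/advanced phantom cohort."""
    cases: list[CohortCase] = []
    for case_id, grade, spec in draw_cohort_specs(cohort):
        volume, truth = generate_phantom(spec, case_id=case_id, trim_margin=trim_margin)
        record = CaseRecord(case_id=case_id, arco_grade=grade, source=source)
        cases.append(CohortCase(record, volume, truth))
    return cases
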