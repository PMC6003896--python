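"""Digital liver/lung torso phantom and synthetic patient cohorts.

The physical reference is a fillable liver/lung torso phantom (spine insert,
two lungs, liver with two embedded "lesions") filled with Tc-99m at
concentrations chosen to realize lung shunt fractions (LSF) of 0, 3.6 and
6.9 %.  The printed constraints are the compartment activity concentrations,
the total activity (195 MBq at the 3.6 % fill) and the LSF targets; compartment
volumes are recovered from those constraints by :func:`solve_phantom_volumes`.

Geometry is parametric (elliptic-cylinder body, ellipsoidal lungs and liver,
sphere + ellipsoid lesions, cylindrical spine): only volumes, densities and
activity concentrations are constrained, not shapes.  Voxel masks are
calibrated so each compartment's discretized volume matches its target to
within half a voxel.

Axis convention: arrays are indexed ``(x, y, z)``; x increases toward the
patient's left, y toward anterior, z toward superior.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter1d

from lungshunt import io

LUNG_DENSITY_G_ML = 0.3
SOFT_TISSUE_DENSITY_G_ML = 1.0
BONE_DENSITY_G_ML = 1.5
AIR_DENSITY_G_ML = 0.0012

#: fraction of total lung volume assigned to the left lung (right gets the rest)
LEFT_LUNG_FRACTION = 0.47
#: fraction of total lesion volume in the spherical lesion (rest: ellipsoid)
SPHERE_LESION_FRACTION = 0.40


class Compartment(IntEnum):
    AIR = 0
    SOFT_TISSUE = 1
    LEFT_LUNG = 2
    RIGHT_LUNG = 3
    NORMAL_LIVER = 4
    SPHERE_LESION = 5
    ELLIPSOID_LESION = 6
    SPINE = 7


_DENSITY_BY_LABEL = {
    Compartment.AIR: AIR_DENSITY_G_ML,
    Compartment.SOFT_TISSUE: SOFT_TISSUE_DENSITY_G_ML,
    Compartment.LEFT_LUNG: LUNG_DENSITY_G_ML,
    Compartment.RIGHT_LUNG: LUNG_DENSITY_G_ML,
    Compartment.NORMAL_LIVER: SOFT_TISSUE_DENSITY_G_ML,
    Compartment.SPHERE_LESION: SOFT_TISSUE_DENSITY_G_ML,
    Compartment.ELLIPSOID_LESION: SOFT_TISSUE_DENSITY_G_ML,
    Compartment.SPINE: BONE_DENSITY_G_ML,
}

LUNG_LABELS = (Compartment.LEFT_LUNG, Compartment.RIGHT_LUNG)
LIVER_LABELS = (
    Compartment.NORMAL_LIVER,
    Compartment.SPHERE_LESION,
    Compartment.ELLIPSOID_LESION,
)


def density_to_hu(density_g_ml: np.ndarray) -> np.ndarray:
    """Synthetic CT: HU = 1000 x (rho - rho_water) / rho_water.

    Lung (0.3 g/mL) maps to -700 HU, air to ~ -999 HU, bone (1.5) to +500 HU.
    """
    return 1000.0 * (np.asarray(density_g_ml, dtype=float) - 1.0)


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class PhantomSpec:
    """Compartment concentrations/volumes realizing one true LSF level.

    Concentrations are kBq/mL, volumes mL, total activity MBq.  ``lung_conc``
    applies to each lung (both lungs are filled identically).
    """

    lung_conc_kbq_ml: float
    normal_liver_conc_kbq_ml: float
    lesion_conc_kbq_ml: float
    lung_volume_ml: float
    normal_liver_volume_ml: float
    lesion_volumes_ml: tuple[float, float]  # (sphere, ellipsoid)
    total_activity_mbq: float
    true_lsf_percent: float

    def __post_init__(self):
        vals = [
            self.lung_conc_kbq_ml,
            self.normal_liver_conc_kbq_ml,
            self.lesion_conc_kbq_ml,
            self.lung_volume_ml,
            self.normal_liver_volume_ml,
            *self.lesion_volumes_ml,
        ]
        if any(v < 0 for v in vals):
            raise ValueError("concentrations and volumes must be >= 0")
        lung_kbq = self.lung_activity_kbq
        total_kbq = lung_kbq + self.liver_activity_kbq
        lsf = 0.0 if total_kbq == 0 else 100.0 * lung_kbq / total_kbq
        if abs(lsf - self.true_lsf_percent) > 0.05:
            raise ValueError(
                f"true_lsf_percent={self.true_lsf_percent} inconsistent with "
                f"field-derived LSF {lsf:.3f}"
            )
        if total_kbq > 0 and abs(total_kbq / 1000.0 - self.total_activity_mbq) > 0.01 * max(
            self.total_activity_mbq, 1.0
        ):
            raise ValueError(
                f"total_activity_mbq={self.total_activity_mbq} inconsistent with "
                f"field-derived total {total_kbq / 1000.0:.2f} MBq"
            )

    @property
    def lung_activity_kbq(self) -> float:
        return self.lung_conc_kbq_ml * self.lung_volume_ml

    @property
    def liver_activity_kbq(self) -> float:
        return (
            self.normal_liver_conc_kbq_ml * self.normal_liver_volume_ml
            + self.lesion_conc_kbq_ml * sum(self.lesion_volumes_ml)
        )

    @property
    def liver_volume_ml(self) -> float:
        """Whole liver (normal tissue + lesions)."""
        return self.normal_liver_volume_ml + sum(self.lesion_volumes_ml)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ConcentrationTable:
    """Injected activity concentrations (kBq/mL) at two non-zero LSF fills.

    Both fills share the same lung and lesion concentrations; only the normal
    liver concentration differs (it is raised to dilute the shunt).
    """

    lung: float = 3.0
    lesion: float = 390.0
    normal_liver_at_low_lsf: float = 140.0
    normal_liver_at_high_lsf: float = 65.0


def solve_phantom_volumes(
    concs: ConcentrationTable | None = None,
    lsf_targets: tuple[float, float] = (3.6, 6.9),
    total_activity_mbq: float = 195.0,
) -> dict[float, PhantomSpec]:
    """Recover compartment volumes from the printed fill constraints.

    Unknowns are the total lung volume L, normal-liver volume N and total
    lesion volume S.  Constraints: the two LSF equations (one per non-zero
    fill) and the total activity at the *low*-LSF fill (the maximum-activity
    configuration).  This is a 3x3 linear system; the solution is validated by
    substitution.

    Returns one :class:`PhantomSpec` per LSF level, including the 0 % fill
    (cold lungs, high-LSF liver concentration) at the same volumes.
    """
    concs = concs or ConcentrationTable()
    lo, hi = sorted(lsf_targets)
    f_lo, f_hi = lo / 100.0, hi / 100.0
    c_l, c_s = concs.lung, concs.lesion
    c_n_lo, c_n_hi = concs.normal_liver_at_low_lsf, concs.normal_liver_at_high_lsf
    if c_l <= 0:
        raise ValueError("constraint violated: lung concentration must be > 0 "
                         "to realize a non-zero LSF")
    # rows: LSF(lo) eq, LSF(hi) eq, total activity at the lo fill (kBq)
    a = np.array(
        [
            [c_l * (1 - f_lo), -f_lo * c_n_lo, -f_lo * c_s],
            [c_l * (1 - f_hi), -f_hi * c_n_hi, -f_hi * c_s],
            [c_l, c_n_lo, c_s],
        ]
    )
    b = np.array([0.0, 0.0, total_activity_mbq * 1000.0])
    if abs(np.linalg.det(a)) < 1e-9 * max(1.0, np.abs(a).max() ** 3):
        raise ValueError("constraint violated: singular system — the two LSF "
                         "targets and concentrations are not independent")
    vol_lung, vol_nliver, vol_lesion = np.linalg.solve(a, b)
    if min(vol_lung, vol_nliver, vol_lesion) <= 0:
        raise ValueError(
            "constraint violated: inconsistent constraints give a non-positive "
            f"volume (lung={vol_lung:.1f}, liver={vol_nliver:.1f}, "
            f"lesions={vol_lesion:.1f} mL)"
        )
    lesions = (
        SPHERE_LESION_FRACTION * vol_lesion,
        (1 - SPHERE_LESION_FRACTION) * vol_lesion,
    )

    def _spec(lung_c, liver_c, lsf):
        total = (lung_c * vol_lung + liver_c * vol_nliver + c_s * vol_lesion) / 1000.0
        return PhantomSpec(
            lung_conc_kbq_ml=lung_c,
            normal_liver_conc_kbq_ml=liver_c,
            lesion_conc_kbq_ml=c_s,
            lung_volume_ml=vol_lung,
            normal_liver_volume_ml=vol_nliver,
            lesion_volumes_ml=lesions,
            total_activity_mbq=total,
            true_lsf_percent=lsf,
        )

    return {
        0.0: _spec(0.0, c_n_hi, 0.0),
        lo: _spec(c_l, c_n_lo, lo),
        hi: _spec(c_l, c_n_hi, hi),
    }


# ---------------------------------------------------------------------------
# Voxelization


@dataclass(frozen=True)
class PhantomGeometry:
    """Parametric shape layout (all lengths mm, positions about grid center).

    Lungs sit superior to the diaphragm plane, the liver inferior to it, so
    the organs abut: superior-inferior blur then smears liver activity into
    the inferior lung, as respiratory motion does in free-breathing scans.
    Shape 'ratios' are semi-axis proportions; absolute scale comes from the
    target volumes.
    """

    body_semiaxes_mm: tuple[float, float] = (150.0, 105.0)
    z_diaphragm_mm: float = -25.0
    lung_axis_ratio: tuple[float, float, float] = (0.66, 0.78, 0.98)
    lung_centers_xy_mm: tuple[tuple[float, float], ...] = ((-56.0, -4.0), (56.0, -4.0))
    lung_center_z_axes: float = 0.85  # lung center sits this many z-semi-axes above the diaphragm
    midline_gap_mm: float = 10.0      # mediastinal separation between the lungs
    liver_axis_ratio: tuple[float, float, float] = (1.45, 0.98, 0.88)
    liver_center_xy_mm: tuple[float, float] = (-20.0, 12.0)
    liver_center_z_axes: float = 0.65  # below the diaphragm, in liver z-semi-axes
    sphere_lesion_offset_axes: tuple[float, float, float] = (-0.35, 0.10, 0.15)
    ellipsoid_lesion_ratio: tuple[float, float, float] = (1.4, 1.0, 0.8)
    ellipsoid_lesion_offset_axes: tuple[float, float, float] = (0.30, -0.15, -0.25)
    spine_radius_mm: float = 14.0
    spine_center_y_mm: float = -80.0


@dataclass
class DigitalPhantom:
    """Voxelized activity / density / compartment-label grids.

    ``activity_grid`` is kBq/mL, ``density_grid`` g/mL, ``label_grid`` holds
    :class:`Compartment` ids.  Third axis is superior-inferior (z up).
    """

    activity_grid: np.ndarray
    density_grid: np.ndarray
    label_grid: np.ndarray
    voxel_spacing_mm: np.ndarray
    spec: PhantomSpec | None = None

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_spacing_mm)) / 1000.0

    def total_activity_mbq(self) -> float:
        return float(self.activity_grid.sum()) * self.voxel_volume_ml / 1000.0

    def ct_hu(self) -> np.ndarray:
        return density_to_hu(self.density_grid)

    def compartment_volume_ml(self, *labels: Compartment) -> float:
        mask = np.isin(self.label_grid, labels)
        return float(mask.sum()) * self.voxel_volume_ml

    def lsf_from_labels(self) -> float:
        """Ground-truth LSF recounted from the (possibly blurred) activity grid."""
        lung = float(self.activity_grid[np.isin(self.label_grid, LUNG_LABELS)].sum())
        liver = float(self.activity_grid[np.isin(self.label_grid, LIVER_LABELS)].sum())
        if lung + liver == 0:
            return 0.0
        return 100.0 * lung / (lung + liver)

    def save(self, out_dir: str | Path, fmt: str = "nii.gz") -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "activity": io.save_volume(out / f"activity.{fmt}", self.activity_grid, self.voxel_spacing_mm),
            "ct": io.save_volume(out / f"ct.{fmt}", self.ct_hu().astype(np.float32), self.voxel_spacing_mm),
            "labels": io.save_volume(out / f"labels.{fmt}", self.label_grid.astype(np.uint8), self.voxel_spacing_mm),
        }
        if self.spec is not None:
            paths["spec"] = io.save_json(out / "phantom_spec.json", self.spec.as_dict())
        return paths


def _grid_coords(shape, spacing):
    axes = [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _calibrated_ellipsoid(r2_grid, allowed, target_ml, voxel_ml, name):
    """Pick the inclusion radius so the voxelized volume best matches target.

    ``r2_grid`` is the squared normalized ellipsoid coordinate (<= 1 at the
    nominal surface).  The threshold is chosen from the sorted voxel radii, so
    the volume error is at most half a voxel.
    """
    r2 = r2_grid[allowed]
    k = int(round(target_ml / voxel_ml))
    if k < 1:
        raise ValueError(f"{name}: target volume {target_ml:.2f} mL is below one voxel")
    if k > r2.size:
        raise ValueError(f"{name}: target volume {target_ml:.1f} mL does not fit the allowed region")
    thr = np.partition(r2, k - 1)[k - 1]
    if thr > 1.6:  # would require inflating the shape >25% past its nominal surface
        raise ValueError(f"{name}: shape cannot be calibrated to {target_ml:.1f} mL")
    mask = np.zeros(r2_grid.shape, dtype=bool)
    mask[allowed] = r2 <= thr
    return mask


def _ellipsoid_r2(coords, center, semiaxes):
    x, y, z = coords
    return (
        ((x - center[0]) / semiaxes[0]) ** 2
        + ((y - center[1]) / semiaxes[1]) ** 2
        + ((z - center[2]) / semiaxes[2]) ** 2
    )


def _scale_for_volume(axis_ratio, volume_ml):
    """Semi-axes (mm) of an ellipsoid with given axis proportions and volume."""
    volume_mm3 = volume_ml * 1000.0
    prod = axis_ratio[0] * axis_ratio[1] * axis_ratio[2]
    s = (volume_mm3 / (4.0 / 3.0 * np.pi * prod)) ** (1.0 / 3.0)
    return tuple(r * s for r in axis_ratio)


def build_phantom(
    spec: PhantomSpec,
    voxel_spacing_mm: float | tuple[float, float, float] = 4.0,
    grid_shape: tuple[int, int, int] = (128, 128, 96),
    geometry: PhantomGeometry | None = None,
) -> DigitalPhantom:
    """Voxelize a :class:`PhantomSpec` onto a regular grid.

    Raises if the voxel spacing is outside [2, 8] mm, if any compartment would
    cross the body outline, or if the lesions do not fit inside the liver.
    """
    geometry = geometry or PhantomGeometry()
    spacing = np.asarray(
        np.broadcast_to(np.asarray(voxel_spacing_mm, dtype=float), (3,)), dtype=float
    ).copy()
    if np.any(spacing < 2.0) or np.any(spacing > 8.0):
        raise ValueError("voxel spacing must be within [2, 8] mm")
    voxel_ml = float(np.prod(spacing)) / 1000.0
    coords = _grid_coords(grid_shape, spacing)
    x, y, z = coords

    bx, by = geometry.body_semiaxes_mm
    half_extent = [(n * s) / 2.0 for n, s in zip(grid_shape, spacing)]
    if bx > half_extent[0] or by > half_extent[1]:
        raise ValueError("body outline does not fit inside the grid")
    body = (x / bx) ** 2 + (y / by) ** 2 <= 1.0
    body = np.broadcast_to(body, grid_shape)

    labels = np.where(body, np.uint8(Compartment.SOFT_TISSUE), np.uint8(Compartment.AIR)).copy()
    # organs keep a soft-tissue rind against the body surface (and grid edges)
    interior = ndimage.binary_erosion(body, iterations=2)

    z_d = geometry.z_diaphragm_mm

    # lungs: left gets LEFT_LUNG_FRACTION of the total volume
    lung_targets = {
        Compartment.LEFT_LUNG: LEFT_LUNG_FRACTION * spec.lung_volume_ml,
        Compartment.RIGHT_LUNG: (1 - LEFT_LUNG_FRACTION) * spec.lung_volume_ml,
    }
    # patient left = +x; centers are listed (right, left) in -x, +x order
    lung_centers = {
        Compartment.RIGHT_LUNG: geometry.lung_centers_xy_mm[0],
        Compartment.LEFT_LUNG: geometry.lung_centers_xy_mm[1],
    }
    above_diaphragm = np.broadcast_to(z >= z_d, grid_shape)
    for label, target in lung_targets.items():
        semi = _scale_for_volume(geometry.lung_axis_ratio, target / 0.97)
        cx, cy = lung_centers[label]
        cz = z_d + geometry.lung_center_z_axes * semi[2]
        r2 = _ellipsoid_r2(coords, (cx, cy, cz), semi)
        # keep a mediastinal gap so large lungs never meet at the midline
        own_side = x >= geometry.midline_gap_mm / 2 if cx > 0 else x <= -geometry.midline_gap_mm / 2
        allowed = above_diaphragm & np.broadcast_to(own_side, grid_shape) & interior
        mask = _calibrated_ellipsoid(r2, allowed, target, voxel_ml, label.name)
        if np.any(mask & ~body):
            raise ValueError(f"{label.name} overlaps the body boundary")
        labels[mask] = label

    # liver below the diaphragm, lesions carved out of it
    liver_total = spec.liver_volume_ml
    liver_semi = _scale_for_volume(geometry.liver_axis_ratio, liver_total / 0.8)
    lcx, lcy = geometry.liver_center_xy_mm
    lcz = z_d - geometry.liver_center_z_axes * liver_semi[2]
    below_diaphragm = np.broadcast_to(z < z_d, grid_shape) & interior  # strict: lungs own the plane
    liver_r2 = _ellipsoid_r2(coords, (lcx, lcy, lcz), liver_semi)
    liver_mask = _calibrated_ellipsoid(liver_r2, below_diaphragm, liver_total, voxel_ml, "LIVER")
    if np.any(liver_mask & ~body):
        raise ValueError("LIVER overlaps the body boundary")
    if np.any(liver_mask & np.isin(labels, LUNG_LABELS)):
        raise ValueError("LIVER overlaps a lung compartment")
    labels[liver_mask] = Compartment.NORMAL_LIVER

    sphere_ml, ellipsoid_ml = spec.lesion_volumes_ml
    if sphere_ml + ellipsoid_ml >= liver_total:
        raise ValueError("lesions larger than the liver")
    lesion_defs = []
    if sphere_ml > 0:
        center = tuple(
            c + o * a for c, o, a in zip((lcx, lcy, lcz), geometry.sphere_lesion_offset_axes, liver_semi)
        )
        r = (sphere_ml * 1000.0 * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        lesion_defs.append((Compartment.SPHERE_LESION, center, (r * 1.1,) * 3, sphere_ml))
    if ellipsoid_ml > 0:
        center = tuple(
            c + o * a
            for c, o, a in zip((lcx, lcy, lcz), geometry.ellipsoid_lesion_offset_axes, liver_semi)
        )
        semi = _scale_for_volume(geometry.ellipsoid_lesion_ratio, ellipsoid_ml / 0.8)
        lesion_defs.append((Compartment.ELLIPSOID_LESION, center, semi, ellipsoid_ml))
    for label, center, semi, target in lesion_defs:
        r2 = _ellipsoid_r2(coords, center, semi)
        room = liver_mask & (labels == Compartment.NORMAL_LIVER)
        mask = _calibrated_ellipsoid(r2, room, target, voxel_ml, label.name)
        if np.any(mask & ~liver_mask):  # pragma: no cover - room is liver-restricted
            raise ValueError(f"{label.name} extends outside the liver")
        labels[mask] = label

    # spine: fixed-size cylinder, only where no organ was placed
    spine = (x**2 + (y - geometry.spine_center_y_mm) ** 2) <= geometry.spine_radius_mm**2
    spine = np.broadcast_to(spine, grid_shape) & (labels == Compartment.SOFT_TISSUE) & body
    labels[spine] = Compartment.SPINE

    conc = {
        Compartment.AIR: 0.0,
        Compartment.SOFT_TISSUE: 0.0,
        Compartment.SPINE: 0.0,
        Compartment.LEFT_LUNG: spec.lung_conc_kbq_ml,
        Compartment.RIGHT_LUNG: spec.lung_conc_kbq_ml,
        Compartment.NORMAL_LIVER: spec.normal_liver_conc_kbq_ml,
        Compartment.SPHERE_LESION: spec.lesion_conc_kbq_ml,
        Compartment.ELLIPSOID_LESION: spec.lesion_conc_kbq_ml,
    }
    activity = np.zeros(grid_shape, dtype=np.float64)
    density = np.empty(grid_shape, dtype=np.float64)
    for label in Compartment:
        sel = labels == label
        activity[sel] = conc[label]
        density[sel] = _DENSITY_BY_LABEL[label]

    phantom = DigitalPhantom(
        activity_grid=activity,
        density_grid=density,
        label_grid=labels,
        voxel_spacing_mm=spacing,
        spec=spec,
    )
    if spec.total_activity_mbq > 0:
        err = abs(phantom.total_activity_mbq() - spec.total_activity_mbq) / spec.total_activity_mbq
        if err > 0.01:
            raise ValueError(
                f"discretized total activity off by {100 * err:.2f}% — grid too coarse"
            )
    return phantom


def apply_breathing_blur(phantom: DigitalPhantom, sigma_mm: float) -> DigitalPhantom:
    """Smear activity along the superior-inferior axis (free-breathing motion).

    Only the activity grid is blurred; density and labels (the CT, acquired as
    a fast snapshot) are untouched.  Total activity is conserved exactly: the
    truncated-Gaussian edge loss is renormalized away.
    """
    if sigma_mm < 0:
        raise ValueError("blur sigma must be >= 0")
    if sigma_mm == 0:
        return dataclasses.replace(phantom, activity_grid=phantom.activity_grid.copy())
    sigma_vox = sigma_mm / float(phantom.voxel_spacing_mm[2])
    blurred = gaussian_filter1d(phantom.activity_grid, sigma_vox, axis=2, mode="constant")
    total_before = phantom.activity_grid.sum()
    total_after = blurred.sum()
    if total_after > 0:
        blurred *= total_before / total_after
    return dataclasses.replace(phantom, activity_grid=blurred)


# ---------------------------------------------------------------------------
# Synthetic patient cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Sampling distributions for a synthetic patient cohort.

    Defaults emulate the study population: SPECT-based LSFs centered near
    1.5 % (log-normal, clipped to 0.2-8 %), CT lung volumes averaging 2.9 L
    (0.87 kg at 0.3 kg/L, spanning 1.5-4.8 L), administered Tc-99m activity
    185-222 MBq, planned Y-90 activity averaging ~3.7 GBq (0.9-7.9), and
    free-breathing superior-inferior blur of a few mm to 15 mm.
    """

    n_patients: int = 40
    lsf_lognormal_median_percent: float = 1.3
    lsf_lognormal_sigma: float = 0.55
    lsf_clip_percent: tuple[float, float] = (0.2, 8.0)
    lung_volume_mean_l: float = 2.9
    lung_volume_sd_l: float = 0.7
    lung_volume_clip_l: tuple[float, float] = (1.5, 4.8)
    liver_volume_mean_l: float = 1.8
    liver_volume_sd_l: float = 0.35
    liver_volume_clip_l: tuple[float, float] = (1.2, 2.6)
    lesion_fraction_of_liver: float = 0.10
    lesion_to_liver_conc_ratio: float = 3.0
    breathing_sigma_mean_mm: float = 8.0
    breathing_sigma_sd_mm: float = 3.0
    breathing_sigma_clip_mm: tuple[float, float] = (0.0, 15.0)
    tc_activity_range_mbq: tuple[float, float] = (185.0, 222.0)
    y90_lognormal_median_gbq: float = 3.3
    y90_lognormal_sigma: float = 0.5
    y90_clip_gbq: tuple[float, float] = (0.9, 7.9)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("cohort must contain at least one patient")


@dataclass(frozen=True)
class PatientGroundTruth:
    patient_id: int
    true_lsf_percent: float
    lung_volume_ml: float
    lung_mass_kg: float
    liver_volume_ml: float
    tc_activity_mbq: float
    y90_activity_gbq: float
    breathing_sigma_mm: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def patient_spec(
    lsf_percent: float,
    lung_volume_ml: float,
    liver_volume_ml: float,
    tc_activity_mbq: float,
    lesion_fraction: float = 0.10,
    lesion_conc_ratio: float = 3.0,
) -> PhantomSpec:
    """Concentrations realizing a prescribed LSF in a patient-sized anatomy.

    The liver holds one 'lesion' pair at ``lesion_conc_ratio`` times the
    normal-liver concentration occupying ``lesion_fraction`` of liver volume.
    """
    total_kbq = tc_activity_mbq * 1000.0
    f = lsf_percent / 100.0
    lung_kbq = f * total_kbq
    liver_kbq = total_kbq - lung_kbq
    lesion_ml = lesion_fraction * liver_volume_ml
    normal_ml = liver_volume_ml - lesion_ml
    c_norm = liver_kbq / (normal_ml + lesion_conc_ratio * lesion_ml)
    return PhantomSpec(
        lung_conc_kbq_ml=lung_kbq / lung_volume_ml,
        normal_liver_conc_kbq_ml=c_norm,
        lesion_conc_kbq_ml=lesion_conc_ratio * c_norm,
        lung_volume_ml=lung_volume_ml,
        normal_liver_volume_ml=normal_ml,
        lesion_volumes_ml=(
            SPHERE_LESION_FRACTION * lesion_ml,
            (1 - SPHERE_LESION_FRACTION) * lesion_ml,
        ),
        total_activity_mbq=tc_activity_mbq,
        true_lsf_percent=lsf_percent,
    )


def synth_cohort(
    spec: CohortSpec,
    voxel_spacing_mm: float = 6.0,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    build: bool = True,
) -> list[tuple[DigitalPhantom | None, PatientGroundTruth]]:
    """Sample a reproducible cohort of digital patients.

    The ground-truth LSF is the administered shunt, recorded *before* the
    breathing blur is applied (the blur is an imaging artifact, not a change
    in where particles lodged).  With ``build=False`` only ground-truth
    records are generated (cheap, e.g. for statistical simulations).
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for pid in range(1, spec.n_patients + 1):
        lsf = float(
            np.clip(
                spec.lsf_lognormal_median_percent
                * np.exp(spec.lsf_lognormal_sigma * rng.standard_normal()),
                *spec.lsf_clip_percent,
            )
        )
        lung_l = float(
            np.clip(
                rng.normal(spec.lung_volume_mean_l, spec.lung_volume_sd_l),
                *spec.lung_volume_clip_l,
            )
        )
        liver_l = float(
            np.clip(
                rng.normal(spec.liver_volume_mean_l, spec.liver_volume_sd_l),
                *spec.liver_volume_clip_l,
            )
        )
        sigma = float(
            np.clip(
                rng.normal(spec.breathing_sigma_mean_mm, spec.breathing_sigma_sd_mm),
                *spec.breathing_sigma_clip_mm,
            )
        )
        tc_mbq = float(rng.uniform(*spec.tc_activity_range_mbq))
        y90 = float(
            np.clip(
                spec.y90_lognormal_median_gbq
                * np.exp(spec.y90_lognormal_sigma * rng.standard_normal()),
                *spec.y90_clip_gbq,
            )
        )
        truth = PatientGroundTruth(
            patient_id=pid,
            true_lsf_percent=lsf,
            lung_volume_ml=lung_l * 1000.0,
            lung_mass_kg=lung_l * LUNG_DENSITY_G_ML,
            liver_volume_ml=liver_l * 1000.0,
            tc_activity_mbq=tc_mbq,
            y90_activity_gbq=y90,
            breathing_sigma_mm=sigma,
        )
        phantom = None
        if build:
            pspec = patient_spec(
                lsf, lung_l * 1000.0, liver_l * 1000.0, tc_mbq,
                spec.lesion_fraction_of_liver, spec.lesion_to_liver_conc_ratio,
            )
            phantom = build_phantom(pspec, voxel_spacing_mm, grid_shape)
            phantom = apply_breathing_blur(phantom, sigma)
        out.append((phantom, truth))
    return out
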