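"""Semi-automatic liver/lung segmentation for volumetric LSF estimation.

The workflow mirrors a clinical auto-contouring chain: a whole-body VOI from
CT thresholding plus morphology; a lung VOI as the HU <= -150 voxels inside
the body, cleaned with a minimum-component-volume filter and split
left/right about the mid-sagittal plane; a motion-exclusion lung VOI with
the most inferior 2 cm of each lung removed (to suppress liver activity
smeared into the lung base by free breathing); and a liver VOI from
percent-of-maximum thresholding of the emission volume.  Total lung counts
are extrapolated from the count density in the (exclusion-corrected,
in-field-of-view) lung to the full CT lung volume.

All operations are deterministic: identical inputs give identical masks.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class SegmentationConfig:
    body_hu_threshold: float = -500.0
    lung_hu_lock: float = -150.0        # upper HU bound for lung voxels
    min_lung_component_ml: float = 50.0  # mediastinum/airway cleanup
    exclusion_margin_cm: float = 2.0
    liver_threshold_presets_percent: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0, 10.0)
    default_liver_preset_percent: float = 2.0  # the modal clinical choice

    def __post_init__(self):
        if list(self.liver_threshold_presets_percent) != sorted(self.liver_threshold_presets_percent):
            raise ValueError("liver presets must be sorted ascending")
        if self.exclusion_margin_cm < 0:
            raise ValueError("exclusion margin must be >= 0")


@dataclass
class SegmentationResult:
    body_mask: np.ndarray
    left_lung_mask: np.ndarray
    right_lung_mask: np.ndarray
    lung_mask_with_exclusion: np.ndarray
    liver_mask: np.ndarray
    lung_volume_l: float      # full lungs, from CT (pre-exclusion; used for mass)
    liver_volume_l: float
    chosen_liver_preset_percent: float
    exclusion_margin_mm: float
    voxel_spacing_mm: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0, 1.0]))

    @property
    def lung_mask(self) -> np.ndarray:
        return self.left_lung_mask | self.right_lung_mask

    def report(self) -> dict:
        return {
            "lung_volume_l": self.lung_volume_l,
            "liver_volume_l": self.liver_volume_l,
            "chosen_liver_preset_percent": self.chosen_liver_preset_percent,
            "exclusion_margin_mm": self.exclusion_margin_mm,
            "voxel_spacing_mm": list(map(float, self.voxel_spacing_mm)),
        }


def _voxel_ml(spacing) -> float:
    return float(np.prod(spacing)) / 1000.0


def whole_body_voi(ct_hu_grid: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Largest contiguous above-threshold region, closed and hole-filled."""
    config = config or SegmentationConfig()
    raw = ct_hu_grid > config.body_hu_threshold
    if not raw.any():
        raise ValueError("empty body: no voxels above the body threshold")
    closed = ndimage.binary_closing(raw, structure=np.ones((3, 3, 3), bool))
    closed |= raw  # closing with a border can only grow interior; keep original
    filled = ndimage.binary_fill_holes(closed)
    # also fill per axial slice: a bed cutting through the lungs leaves them
    # open at the axial face, where 3-D filling alone would leak
    filled |= ndimage.binary_fill_holes(closed, structure=np.ones((3, 3, 1), bool))
    labels, n = ndimage.label(filled)
    if n > 1:
        largest = np.argmax(ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))) + 1
        filled = labels == largest
    return filled


def lung_voi(
    ct_hu_grid: np.ndarray,
    body_mask: np.ndarray,
    config: SegmentationConfig | None = None,
    voxel_spacing_mm=(1.0, 1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Left/right lung masks from the HU lock inside the body VOI.

    Connected components smaller than ``min_lung_component_ml`` (air pockets,
    mediastinal/airway voxels) are discarded; survivors are assigned left or
    right by the sign of their centroid about the body's mid-sagittal plane
    (x is the left-right axis, +x patient-left).
    """
    config = config or SegmentationConfig()
    if not body_mask.any():
        raise ValueError("body mask is empty")
    spacing = np.broadcast_to(np.asarray(voxel_spacing_mm, float), (3,))
    cand = (ct_hu_grid <= config.lung_hu_lock) & body_mask
    if not cand.any():
        raise ValueError("no lung candidate voxels (no HU <= lock inside the body)")
    labels, n = ndimage.label(cand)
    sizes_ml = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1)) * _voxel_ml(spacing)
    keep = np.flatnonzero(sizes_ml >= config.min_lung_component_ml) + 1
    if keep.size == 0:
        raise ValueError("no lung component survives the minimum-volume filter")
    mid_x = ndimage.center_of_mass(body_mask)[0]
    left = np.zeros(ct_hu_grid.shape, bool)
    right = np.zeros(ct_hu_grid.shape, bool)
    for lab in keep:
        comp = labels == lab
        if ndimage.center_of_mass(comp)[0] >= mid_x:
            left |= comp
        else:
            right |= comp
    if not left.any() or not right.any():
        warnings.warn("single-lung segmentation: one side is empty", stacklevel=2)
    return left, right


def exclude_inferior(
    lung_masks: tuple[np.ndarray, np.ndarray],
    exclusion_margin_cm: float,
    voxel_spacing_mm=(1.0, 1.0, 1.0),
) -> tuple[np.ndarray, float]:
    """Remove the most inferior margin of each lung (per-lung, not a global plane).

    The margin is rounded to whole slices; the realized margin in mm is
    returned alongside the combined mask.  z (axis 2) runs inferior->superior.
    """
    spacing = np.broadcast_to(np.asarray(voxel_spacing_mm, float), (3,))
    dz = float(spacing[2])
    n_slices = int(round(exclusion_margin_cm * 10.0 / dz))
    combined = np.zeros(lung_masks[0].shape, bool)
    for mask in lung_masks:
        if not mask.any():
            continue
        z_idx = np.flatnonzero(mask.any(axis=(0, 1)))
        if n_slices >= z_idx.max() - z_idx.min() + 1:
            raise ValueError(
                f"exclusion margin ({exclusion_margin_cm} cm) exceeds the lung height"
            )
        kept = mask.copy()
        kept[:, :, : z_idx.min() + n_slices] = False
        combined |= kept
    return combined, n_slices * dz


def liver_voi(
    emission_volume: np.ndarray,
    config: SegmentationConfig | None = None,
    preset_override: float | None = None,
    ct_liver_volume_ml: float | None = None,
    voxel_spacing_mm=(1.0, 1.0, 1.0),
) -> tuple[np.ndarray, float]:
    """Liver mask by percent-of-maximum thresholding of the emission volume.

    Default preset is 2 % of the field-of-view maximum (the modal clinical
    choice); ``preset_override`` forces any threshold, and when a CT-derived
    liver volume estimate is supplied the preset whose mask volume agrees
    best is auto-selected.  The largest connected component is kept.
    """
    config = config or SegmentationConfig()
    emission = np.asarray(emission_volume, dtype=float)
    vmax = emission.max()
    if vmax <= 0:
        raise ValueError("emission volume is identically zero")
    spacing = np.broadcast_to(np.asarray(voxel_spacing_mm, float), (3,))

    def mask_at(preset):
        m = emission >= (preset / 100.0) * vmax
        labels, n = ndimage.label(m)
        if n > 1:
            largest = np.argmax(ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))) + 1
            m = labels == largest
        return m

    if preset_override is not None:
        preset = float(preset_override)
    elif ct_liver_volume_ml is not None:
        vox = _voxel_ml(spacing)
        errs = [
            (abs(mask_at(p).sum() * vox - ct_liver_volume_ml), p)
            for p in config.liver_threshold_presets_percent
        ]
        preset = min(errs)[1]
    else:
        preset = config.default_liver_preset_percent
    return mask_at(preset), preset


def estimate_lung_counts(
    emission_volume: np.ndarray,
    lung_mask_with_exclusion: np.ndarray,
    total_lung_volume_ml: float,
    in_fov_mask: np.ndarray | None = None,
    voxel_spacing_mm=(1.0, 1.0, 1.0),
) -> float:
    """Extrapolate total lung counts from the sampled lung count density.

    Density is measured over the exclusion-corrected lung restricted to the
    field of view, then multiplied by the full CT lung volume — this handles
    both the 2 cm exclusion and partial-lung FOV coverage.
    """
    sample = lung_mask_with_exclusion if in_fov_mask is None else (lung_mask_with_exclusion & in_fov_mask)
    n = int(sample.sum())
    if n == 0:
        raise ValueError("no lung in FOV: empty sampling region")
    vox_ml = _voxel_ml(np.broadcast_to(np.asarray(voxel_spacing_mm, float), (3,)))
    density_per_ml = float(np.asarray(emission_volume, float)[sample].sum()) / (n * vox_ml)
    return density_per_ml * float(total_lung_volume_ml)


def segment(
    ct_hu_grid: np.ndarray,
    emission_volume: np.ndarray,
    config: SegmentationConfig | None = None,
    voxel_spacing_mm=(1.0, 1.0, 1.0),
    liver_preset_override: float | None = None,
    ct_liver_volume_ml: float | None = None,
) -> SegmentationResult:
    """Run the full segmentation chain on one co-registered CT + emission pair.

    ``lung_volume_l`` is computed from the *full* lung masks; the exclusion
    affects count sampling only, never the volume used for lung mass.
    The liver mask is made disjoint from the (CT-authoritative) lung masks.
    """
    config = config or SegmentationConfig()
    spacing = np.asarray(np.broadcast_to(np.asarray(voxel_spacing_mm, float), (3,)), float)
    body = whole_body_voi(ct_hu_grid, config)
    left, right = lung_voi(ct_hu_grid, body, config, spacing)
    excl, margin_mm = exclude_inferior((left, right), config.exclusion_margin_cm, spacing)
    liver, preset = liver_voi(
        emission_volume, config, liver_preset_override, ct_liver_volume_ml, spacing
    )
    liver &= ~(left | right)
    vox_ml = _voxel_ml(spacing)
    return SegmentationResult(
        body_mask=body,
        left_lung_mask=left,
        right_lung_mask=right,
        lung_mask_with_exclusion=excl,
        liver_mask=liver,
        lung_volume_l=(left | right).sum() * vox_ml / 1000.0,
        liver_volume_l=liver.sum() * vox_ml / 1000.0,
        chosen_liver_preset_percent=preset,
        exclusion_margin_mm=margin_mm,
        voxel_spacing_mm=spacing,
    )
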