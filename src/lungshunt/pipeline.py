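"""Pipeline drivers: the phantom accuracy/precision experiment and the
patient LSF + dose workflow.

``run_phantom_experiment`` is the in-silico twin of a physical accuracy /
precision study: the torso phantom at true LSF 0 / 3.6 / 6.9 % is imaged by
planar and SPECT acquisition, reconstructed with and without AC/SC, and the
LSF estimated by all five methods over repeated noise realizations,
tabulating mean +/- SD per (level, method).

``run_patient_pipeline`` chains segmentation -> lung count extrapolation ->
volumetric LSF -> CT lung mass -> MIRD dose for one- or two-bed studies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from lungshunt import contour, io, quantify, scanner
from lungshunt import phantom as ph

PHANTOM_METHODS = ("planar_antpost", "planar_gm", "spect_noc", "spect_ac", "spect_acsc")


@dataclass(frozen=True)
class PipelineConfig:
    """Serializable bundle of all stage parameters plus seeds."""

    voxel_spacing_mm: float = 6.0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    lsf_levels: tuple[float, ...] = (0.0, 3.6, 6.9)
    n_realizations: int = 3
    noise: bool = True
    seed: int = 0
    acquisition: scanner.AcquisitionConfig = field(default_factory=scanner.AcquisitionConfig)
    segmentation: contour.SegmentationConfig = field(default_factory=contour.SegmentationConfig)
    dose: quantify.DoseParams = field(default_factory=quantify.DoseParams)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "acquisition" in d:
            d["acquisition"] = scanner.AcquisitionConfig(**d["acquisition"])
        if "segmentation" in d:
            seg = dict(d["segmentation"])
            if "liver_threshold_presets_percent" in seg:
                seg["liver_threshold_presets_percent"] = tuple(seg["liver_threshold_presets_percent"])
            d["segmentation"] = contour.SegmentationConfig(**seg)
        if "dose" in d:
            d["dose"] = quantify.DoseParams(**d["dose"])
        for key in ("grid_shape", "lsf_levels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def planar_organ_rois(phantom: ph.DigitalPhantom) -> tuple[np.ndarray, np.ndarray]:
    """2-D liver/lung ROIs from the ground-truth label footprints.

    Projected along the anterior-posterior axis onto the (x, z) detector
    grid; pixels claimed by the liver footprint are removed from the lung ROI
    so the two are disjoint, as manually drawn ROIs would be.
    """
    liver = np.isin(phantom.label_grid, ph.LIVER_LABELS).any(axis=1)
    lung = np.isin(phantom.label_grid, ph.LUNG_LABELS).any(axis=1)
    return liver, lung & ~liver


def _lsf_level_once(
    phantom: ph.DigitalPhantom,
    mu: scanner.AttenuationMap,
    lungs: tuple[np.ndarray, np.ndarray],
    lung_excl: np.ndarray,
    lung_volume_ml: float,
    liver_roi: np.ndarray,
    lung_roi: np.ndarray,
    config: PipelineConfig,
    rng: np.random.Generator | None,
) -> dict[str, float]:
    acq = config.acquisition
    noise = rng is not None
    planar = scanner.project_planar(phantom, mu, acq, noise=noise, rng=rng)
    out = {
        "planar_antpost": quantify.planar_lsf(planar, liver_roi, lung_roi, "ant_post").lsf_percent,
        "planar_gm": quantify.planar_lsf(planar, liver_roi, lung_roi, "geometric_mean").lsf_percent,
    }
    sinos = scanner.project_spect(phantom, mu, acq, noise=noise, rng=rng)
    recons = {
        "spect_noc": scanner.osem_reconstruct(sinos, mu, acq, ac=False, sc=False,
                                              voxel_spacing_mm=phantom.voxel_spacing_mm),
        "spect_ac": scanner.osem_reconstruct(sinos, mu, acq, ac=True, sc=False,
                                             voxel_spacing_mm=phantom.voxel_spacing_mm),
        "spect_acsc": scanner.osem_reconstruct(sinos, mu, acq, ac=True, sc=True,
                                               voxel_spacing_mm=phantom.voxel_spacing_mm),
    }
    # liver VOI on the corrected reconstruction (the displayed image in clinic)
    liver_mask, _ = contour.liver_voi(
        recons["spect_acsc"].value_grid, config.segmentation,
        preset_override=config.segmentation.default_liver_preset_percent,
        voxel_spacing_mm=phantom.voxel_spacing_mm,
    )
    liver_mask = liver_mask & ~(lungs[0] | lungs[1])
    for name, rec in recons.items():
        lung_counts = contour.estimate_lung_counts(
            rec.value_grid, lung_excl, lung_volume_ml,
            voxel_spacing_mm=phantom.voxel_spacing_mm,
        )
        out[name] = quantify.volumetric_lsf(rec.value_grid, liver_mask, lung_counts).lsf_percent
    return out


def run_phantom_experiment(config: PipelineConfig | None = None, out_dir=None) -> dict:
    """Accuracy/precision table: LSF mean +/- SD per true level and method."""
    config = config or PipelineConfig()
    specs = ph.solve_phantom_volumes()
    report: dict = {"config": config.as_dict(), "levels": {}}
    for li, level in enumerate(config.lsf_levels):
        if level not in specs:
            raise ValueError(f"phantom stage: no spec for LSF level {level}")
        spec = specs[level]
        phant = ph.build_phantom(spec, config.voxel_spacing_mm, config.grid_shape)
        mu = scanner.density_to_mu(phant.density_grid, phant.voxel_spacing_mm)
        seg_cfg = config.segmentation
        ct = phant.ct_hu()
        body = contour.whole_body_voi(ct, seg_cfg)
        lungs = contour.lung_voi(ct, body, seg_cfg, phant.voxel_spacing_mm)
        lung_excl, _ = contour.exclude_inferior(lungs, seg_cfg.exclusion_margin_cm,
                                                phant.voxel_spacing_mm)
        lung_volume_ml = (lungs[0] | lungs[1]).sum() * phant.voxel_volume_ml
        liver_roi, lung_roi = planar_organ_rois(phant)
        n_real = config.n_realizations if config.noise else 1
        values: dict[str, list[float]] = {m: [] for m in PHANTOM_METHODS}
        for r in range(n_real):
            rng = np.random.default_rng([config.seed, li, r]) if config.noise else None
            one = _lsf_level_once(phant, mu, lungs, lung_excl, lung_volume_ml,
                                  liver_roi, lung_roi, config, rng)
            for m in PHANTOM_METHODS:
                values[m].append(one[m])
        report["levels"][f"{level:g}"] = {
            "true_lsf_percent": level,
            "methods": {
                m: {
                    "mean": float(np.mean(v)),
                    "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                    "values": [float(x) for x in v],
                }
                for m, v in values.items()
            },
        }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.save_json(out / "phantom_experiment.json", report)
    return report


@dataclass
class BedStudy:
    """One co-registered CT + reconstructed emission volume (one SPECT bed)."""

    ct_hu: np.ndarray
    emission: np.ndarray
    voxel_spacing_mm: np.ndarray
    in_fov_mask: np.ndarray | None = None


def run_patient_pipeline(
    beds: BedStudy | list[BedStudy],
    config: PipelineConfig | None = None,
    activity_gbq: float | list[float] | None = None,
    out_dir=None,
) -> dict:
    """Segmentation -> lung-count extrapolation -> volumetric LSF -> dose.

    With two beds, the lung volume (and lung count density) comes from the
    bed encompassing the entire lungs and the liver counts from the bed
    encompassing the entire liver; counts are combined without
    renormalization (equal per-view time).  Raises when no bed fully covers
    the lungs.
    """
    config = config or PipelineConfig()
    if isinstance(beds, BedStudy):
        beds = [beds]
    if not beds:
        raise ValueError("segmentation stage: at least one bed is required")
    seg_cfg = config.segmentation
    segs = []
    for bed in beds:
        try:
            segs.append(contour.segment(bed.ct_hu, bed.emission, seg_cfg, bed.voxel_spacing_mm))
        except ValueError as err:
            raise ValueError(f"segmentation stage: {err}") from err

    def covered(bed, seg):
        fov = bed.in_fov_mask
        lung = seg.lung_mask
        if fov is not None and (lung & ~fov).any():
            return False
        z_any = lung.any(axis=(0, 1))
        return not (z_any[0] or z_any[-1])  # lungs must not touch the axial FOV edge

    lung_candidates = [i for i, (b, s) in enumerate(zip(beds, segs)) if covered(b, s)]
    if not lung_candidates:
        raise ValueError("lung stage: no bed encompasses the entire lungs")
    lung_bed = max(lung_candidates, key=lambda i: segs[i].lung_volume_l)
    liver_bed = max(
        range(len(beds)),
        key=lambda i: float(beds[i].emission[segs[i].liver_mask].sum()),
    )
    seg_lung, seg_liver = segs[lung_bed], segs[liver_bed]
    lung_counts = contour.estimate_lung_counts(
        beds[lung_bed].emission,
        seg_lung.lung_mask_with_exclusion,
        seg_lung.lung_volume_l * 1000.0,
        in_fov_mask=beds[lung_bed].in_fov_mask,
        voxel_spacing_mm=beds[lung_bed].voxel_spacing_mm,
    )
    lsf = quantify.volumetric_lsf(beds[liver_bed].emission, seg_liver.liver_mask, lung_counts)
    mass = quantify.lung_mass_from_ct(seg_lung.lung_volume_l, config.dose)
    report = {
        "config": config.as_dict(),
        "n_beds": len(beds),
        "lung_bed": lung_bed,
        "liver_bed": liver_bed,
        "segmentation": [s.report() for s in segs],
        "lsf": lsf.as_dict(),
        "lung_mass_kg": mass,
    }
    if activity_gbq is not None:
        dose = quantify.lung_dose(activity_gbq, mass, lsf.lsf_percent,
                                  lsf_unit="percent", params=config.dose)
        report["dose"] = dose.as_dict()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.save_json(out / "patient_report.json", report)
    return report
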