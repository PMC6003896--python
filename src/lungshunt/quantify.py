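"""Lung shunt fraction and MIRD lung absorbed dose.

LSF (percent) = 100 x lung counts / (lung counts + liver counts), computed
either from planar views (anterior-liver / posterior-lung, or per-organ
geometric mean of the conjugate views) or volumetrically (liver counts summed
over the SPECT liver VOI, lung counts extrapolated from the lung VOI count
density).

Lung absorbed dose follows the MIRD formalism for Y-90:
dose (Gy) = 49.38 x administered activity (GBq) / lung mass (kg) x LSF
with LSF as a *fraction*; the interface therefore requires an explicit unit
tag on the shunt value.  Planar dosimetry conventionally assumes a 1 kg
standard lung; volumetric dosimetry uses the CT-derived mass
(volume x 0.3 kg/L).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from lungshunt.scanner import PlanarPair

#: Y-90 MIRD dose constant, Gy . kg / GBq (total self-dose per unit uptake)
MIRD_CONSTANT_GY_KG_PER_GBQ = 49.38


@dataclass(frozen=True)
class DoseParams:
    mird_constant: float = MIRD_CONSTANT_GY_KG_PER_GBQ
    lung_density_kg_per_l: float = 0.3
    planar_standard_lung_mass_kg: float = 1.0


@dataclass(frozen=True)
class LSFResult:
    method: Literal["planar-antpost", "planar-GM", "volumetric"]
    lung_counts: float
    liver_counts: float
    lsf_percent: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class DoseResult:
    administered_activity_gbq: float
    lung_mass_kg: float
    lsf_fraction: float
    dose_gy: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def lsf_from_counts(lung_counts: float, liver_counts: float) -> float:
    if lung_counts < 0 or liver_counts < 0:
        raise ValueError("counts must be >= 0")
    total = lung_counts + liver_counts
    if total == 0:
        raise ValueError("no counts: lung and liver are both zero")
    return 100.0 * lung_counts / total


def planar_lsf(
    planar: PlanarPair,
    liver_roi: np.ndarray,
    lung_roi: np.ndarray,
    method: Literal["ant_post", "geometric_mean"] = "ant_post",
) -> LSFResult:
    """Planar LSF from 2-D organ ROIs.

    ``ant_post``: liver counts from the anterior view (liver lies anterior),
    lung counts from the posterior view (avoids the heart).
    ``geometric_mean``: per-organ geometric mean of the anterior and posterior
    ROI sums (conjugate-view method).
    Both views use raw photopeak counts — clinical planar acquisitions carry
    no scatter window.
    """
    liver_roi = np.asarray(liver_roi, bool)
    lung_roi = np.asarray(lung_roi, bool)
    if not liver_roi.any() or not lung_roi.any():
        raise ValueError("empty ROI")
    if (liver_roi & lung_roi).any():
        raise ValueError("liver and lung ROIs must be disjoint")
    ant = np.asarray(planar.anterior_counts, float)
    post = np.asarray(planar.posterior_counts, float)
    if method == "ant_post":
        liver = float(ant[liver_roi].sum())
        lung = float(post[lung_roi].sum())
        tag = "planar-antpost"
    elif method == "geometric_mean":
        liver = float(np.sqrt(ant[liver_roi].sum() * post[liver_roi].sum()))
        lung = float(np.sqrt(ant[lung_roi].sum() * post[lung_roi].sum()))
        tag = "planar-GM"
    else:
        raise ValueError(f"unknown planar method: {method!r}")
    return LSFResult(method=tag, lung_counts=lung, liver_counts=liver,
                     lsf_percent=lsf_from_counts(lung, liver))


def volumetric_lsf(
    emission_volume: np.ndarray,
    liver_mask: np.ndarray,
    estimated_lung_counts: float,
) -> LSFResult:
    """Volumetric LSF: VOI liver counts vs extrapolated total lung counts."""
    liver_mask = np.asarray(liver_mask, bool)
    if not liver_mask.any():
        raise ValueError("empty liver mask")
    liver = float(np.asarray(emission_volume, float)[liver_mask].sum())
    lung = float(estimated_lung_counts)
    return LSFResult(method="volumetric", lung_counts=lung, liver_counts=liver,
                     lsf_percent=lsf_from_counts(lung, liver))


def lung_mass_from_ct(lung_volume_l: float, params: DoseParams | None = None) -> float:
    """Lung mass (kg) = CT lung volume (L) x 0.3 kg/L."""
    params = params or DoseParams()
    if lung_volume_l <= 0:
        raise ValueError("lung volume must be > 0")
    return params.lung_density_kg_per_l * lung_volume_l


def lung_dose(
    activity_gbq: float | Iterable[float],
    lung_mass_kg: float,
    lsf: float,
    *,
    lsf_unit: Literal["percent", "fraction"],
    params: DoseParams | None = None,
) -> DoseResult:
    """MIRD lung absorbed dose; multi-administration activities are summed.

    The shunt value must carry an explicit unit tag; percent input is
    converted to a fraction internally.
    """
    params = params or DoseParams()
    activities = np.atleast_1d(np.asarray(activity_gbq, dtype=float))
    if np.any(activities <= 0):
        raise ValueError("administered activity must be > 0")
    if lung_mass_kg <= 0:
        raise ValueError("lung mass must be > 0")
    if lsf_unit == "percent":
        if not 0 <= lsf <= 100:
            raise ValueError("LSF percent must lie in [0, 100]")
        fraction = lsf / 100.0
    elif lsf_unit == "fraction":
        if not 0 <= lsf <= 1:
            raise ValueError("LSF fraction must lie in [0, 1]")
        fraction = float(lsf)
    else:
        raise ValueError(f"unknown lsf_unit: {lsf_unit!r}")
    total_activity = float(activities.sum())
    dose = params.mird_constant * total_activity / lung_mass_kg * fraction
    return DoseResult(
        administered_activity_gbq=total_activity,
        lung_mass_kg=float(lung_mass_kg),
        lsf_fraction=fraction,
        dose_gy=dose,
    )
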