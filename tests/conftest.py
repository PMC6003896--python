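"""Shared fixtures.

Heavy simulations (the full noisy phantom experiment, noise-free
reconstructions of the torso phantom) are session-scoped so several tests
can interrogate one run.  Small-scale configs (48^3 grid, 24 views) exercise
identical code paths at desk speed for structural tests.
"""

import numpy as np
import pytest

from lungshunt import contour, scanner
from lungshunt import phantom as ph
from lungshunt.pipeline import PipelineConfig, run_phantom_experiment


@pytest.fixture(scope="session")
def solved_specs():
    return ph.solve_phantom_volumes()


@pytest.fixture(scope="session")
def torso_phantom(solved_specs):
    """Torso phantom at true LSF 3.6 %, 64^3 at 6 mm."""
    return ph.build_phantom(solved_specs[3.6], 6.0, (64, 64, 64))


@pytest.fixture(scope="session")
def small_config():
    """Reduced acquisition for fast structural tests (same algorithms)."""
    acq = scanner.AcquisitionConfig(n_views=24, osem_subsets=4, matrix=48)
    return PipelineConfig(
        voxel_spacing_mm=7.0, grid_shape=(48, 48, 48), acquisition=acq
    )


@pytest.fixture(scope="session")
def phantom_experiment_report():
    """Full-scale noisy accuracy/precision study: 3 LSF levels x 5 methods x 3
    noise realizations at 64^3 / 60 views (the deep end-to-end simulation
    shared by the bias-ordering and precision tests)."""
    return run_phantom_experiment(PipelineConfig(noise=True, seed=7))


@pytest.fixture(scope="session")
def acsc_recon(torso_phantom):
    """Noise-free AC+SC reconstruction of the unblurred 3.6 % phantom."""
    mu = scanner.density_to_mu(torso_phantom.density_grid, torso_phantom.voxel_spacing_mm)
    acq = scanner.AcquisitionConfig()
    sinos = scanner.project_spect(torso_phantom, mu, acq, noise=False)
    return scanner.osem_reconstruct(sinos, mu, acq, ac=True, sc=True,
                                    voxel_spacing_mm=torso_phantom.voxel_spacing_mm)


@pytest.fixture(scope="session")
def blurred_recon():
    """Noise-free AC+SC reconstruction of the 3.6 % phantom under 15 mm
    breathing blur, with its CT-derived lung masks (for exclusion tests)."""
    specs = ph.solve_phantom_volumes()
    p = ph.build_phantom(specs[3.6], 6.0, (64, 64, 64))
    p = ph.apply_breathing_blur(p, 15.0)
    mu = scanner.density_to_mu(p.density_grid, p.voxel_spacing_mm)
    acq = scanner.AcquisitionConfig()
    sinos = scanner.project_spect(p, mu, acq, noise=False)
    rec = scanner.osem_reconstruct(sinos, mu, acq, ac=True, sc=True,
                                   voxel_spacing_mm=p.voxel_spacing_mm)
    ct = p.ct_hu()
    body = contour.whole_body_voi(ct)
    lungs = contour.lung_voi(ct, body, voxel_spacing_mm=p.voxel_spacing_mm)
    return {"phantom": p, "recon": rec, "lungs": lungs}
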