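# Methods

`lungshunt` simulates and quantifies hepatopulmonary shunting of
Tc-99m-MAA as imaged for Y-90 radioembolization planning. This note
documents the models, the parameters that matter, and the choices made
where the design was genuinely open.

## The quantity of interest

The lung shunt fraction is

    LSF (%) = 100 × C_lung / (C_lung + C_liver)

where `C_lung` and `C_liver` are image-derived counts attributed to lung and
liver. Because the ratio is scale-free, any global calibration factor
cancels; what biases the LSF is *differential* physics — lung tissue
(ρ ≈ 0.3 g/mL) attenuates far less than liver, scatter from the hot liver
spills into the cold lungs, and respiratory motion smears liver activity
across the diaphragm. The package quantifies how three estimators respond
to those biases:

* **planar anterior-liver / posterior-lung** — liver ROI summed on the
  anterior view, lung ROI on the posterior view (raw photopeak counts, no
  scatter window is acquired clinically for planar scans);
* **planar geometric mean** — per-organ √(anterior × posterior) conjugate
  counts;
* **volumetric (SPECT/CT or PET/CT)** — liver counts summed over a
  percent-of-maximum threshold VOI, lung counts extrapolated from the count
  density of a CT-derived lung VOI (with the inferior 2 cm excluded) times
  the full CT lung volume.

The lung absorbed dose follows the MIRD formalism for Y-90:

    D_lung (Gy) = 49.38 × A (GBq) / m_lung (kg) × LSF(fraction)

49.38 Gy·kg/GBq is the total self-dose constant for Y-90; the LSF must
enter as a fraction, so the API requires an explicit `lsf_unit` tag.
Planar dosimetry uses the conventional 1 kg standard lung; volumetric
dosimetry uses CT mass = volume × 0.3 kg/L. Doses from repeat
administrations add.

## Digital phantom

The torso phantom is parametric: an elliptic-cylinder body
(semi-axes 150 × 105 mm), two ellipsoidal lungs above a flat diaphragm
plane, an ellipsoidal liver below it carrying a spherical and an
ellipsoidal lesion, and a cylindrical bone-density spine. Only volumes,
densities and activity concentrations are constrained to the physical
reference; shapes are not anatomical (no airway tree, cardiac notch, or
diaphragm doming). Compartment masks are calibrated by choosing the
inclusion radius from the sorted voxel radii, so every discretized volume
matches its target to within half a voxel at any spacing in [2, 8] mm.

Compartment volumes are not free parameters: they are solved from the fill
constraints of the reference experiment — lung and lesion concentrations
shared by two fills (3 kBq/mL lung, 390 kBq/mL lesions), normal-liver
concentration 140 vs 65 kBq/mL, true shunts of 3.6 % and 6.9 %, and
195 MBq total at the 3.6 % fill. The resulting 3 × 3 linear system gives
2340 mL of lung, 1243.5 mL of normal liver and 35.6 mL of lesions; the
solver validates by substitution and refuses singular or negative-volume
systems. The left lung takes 47 % of lung volume, the sphere 40 % of
lesion volume; both splits are unconstrained by the reference and fixed for
reproducibility.

Synthetic CT is derived from density as HU = 1000 × (ρ − 1), giving
−700 HU lung, −999 HU air, +500 HU spine — adequate for threshold
segmentation, with none of the texture, beam hardening or dose-dependent
noise of real CT. A rind of soft tissue (two voxels) is enforced between
every organ and the body surface so lung cavities are always closed in CT.

**Breathing blur.** Free-breathing motion is modeled as a 1-D Gaussian
smear of the *activity* grid along the superior-inferior axis only
(density and labels — the fast CT snapshot — are untouched). Totals are
renormalized so activity is conserved. This reproduces the one artifact
the inferior-lung exclusion targets (liver counts pooling in the lung
base) but not hysteresis, out-of-plane motion, or CT-emission misregistration.

**Synthetic cohorts.** Patients are the same parametric anatomy with
sampled volumes and activities. Defaults emulate the study population:
log-normal LSF with median 1.3 % and σ_log 0.55 (mean ≈ 1.5 %, clipped to
0.2–8 %), lung volume N(2.9, 0.7) L clipped to 1.5–4.8 L (mass
0.45–1.43 kg at 0.3 kg/L), liver volume N(1.8, 0.35) L, Tc-99m activity
uniform in 185–222 MBq, planned Y-90 activity log-normal with median
3.3 GBq clipped to 0.9–7.9 GBq, breathing σ N(8, 3) mm clipped to 0–15 mm.
The ground-truth LSF is recorded *before* the blur: the blur is an imaging
artifact, not a change in where particles lodged. A seed fully determines
a cohort.

## Scanner model

The projector is rotation-based parallel-beam. Each view resamples the
volume into the detector frame with a sparse bilinear rotation matrix.
The scatter (mass-preserving) convention is used — each source voxel
distributes its counts with the bilinear weights of the inverse rotation —
so a centered point source projects identical totals at every angle, and
the backprojector is the exact matrix transpose (adjointness holds to
machine precision, tested at 1e-6 relative). Along each ray the model
applies:

* **attenuation** — μ = 0.154 cm⁻¹ × ρ, capped at 0.25 cm⁻¹ for bone;
  per-voxel survival factors toward the detector computed by cumulative
  sums (half-voxel self-attenuation);
* **collimator response** — depth-dependent Gaussian with
  FWHM = 4 mm + 0.05 × depth (LEHR-like; the reference gives no numbers),
  quantized into 6 contiguous depth slabs so each slab is one separable,
  self-adjoint convolution;
* **scatter** — the primary projection convolved with a σ = 40 mm Gaussian,
  scaled by a scatter fraction of 0.3, added to the photopeak. The
  adjacent low-energy window records that scatter divided by the
  dual-energy-window factor k = 0.5, so k × window is an unbiased scatter
  estimate before Poisson noise. A convolution model has no object
  dependence beyond the primary image; it stands in for, and is simpler
  than, the energy-window behavior of a real camera.

Counts are scaled to clinical levels (500 k anterior planar counts, 6 M
SPECT counts) and Poisson-sampled with a seeded generator; every
acquisition offers a noise-free mode. The default matrix is 64 with 60
views over 360° (a desk-scale stand-in for the clinical 128 matrix,
60 views/head; the algorithms are identical and the matrix is
config-exposed), and the orbit is circular rather than body-contoured —
orbit shape is immaterial to the corrections under test.

**OSEM.** 8 iterations × 4 subsets. Attenuation correction (AC) toggles
the μ factors inside the system model; scatter correction (SC) adds the
scaled scatter-window estimate to the forward projection — additive rather
than pre-subtracted, which preserves non-negativity. An 8.4 mm FWHM
Gaussian post-filter is applied last. With μ = 0 and no blur, total
reconstructed counts match the per-view sinogram counts to 1 %.

## Auto-contouring

The segmentation chain is deterministic:

1. **whole-body VOI** — CT > −500 HU, 3-D morphological closing, hole
   filling (3-D plus per-axial-slice, the latter so a bed cutting through
   the lungs still closes them), largest connected component;
2. **lung VOI** — HU ≤ −150 inside the body; connected components smaller
   than 50 mL discarded (the mediastinum/airway cleanup; the reference
   does not print its threshold, so it is config-exposed); left/right
   assignment by component centroid about the body's mid-sagittal plane;
3. **exclusion VOI** — the most inferior 2 cm of *each* lung removed,
   measured per lung from its own most inferior voxel and rounded to whole
   slices (the realized margin in mm is recorded);
4. **liver VOI** — voxels above a preset percentage (0.5/1/2/5/10) of the
   emission maximum, largest component. The default preset is 2 % (the
   modal clinical choice); an auto-selection mode picks the preset whose
   volume best matches a CT-derived liver estimate, mirroring the clinical
   procedure of choosing the threshold by agreement with the liver outline
   on fused CT. On this simulator the fixed 2 % preset over-segments the
   phantom liver (the threshold is referenced to the hot lesion maximum
   and picks up the resolution halo); the auto-selected preset recovers
   the liver volume within 10 %.

Lung *counts* are extrapolated as mean count density over the
(exclusion-corrected, in-FOV) lung times the full CT lung volume — one
mechanism that serves both the 2 cm exclusion and partial-FOV PET
coverage. Lung *volume* (hence mass) always comes from the full
pre-exclusion masks. For two-bed studies the lung bed is the one whose
lung mask is fully inside the axial FOV, the liver bed the one with the
most liver counts; counts combine without renormalization (equal per-view
time).

## Cohort statistics

The packaged fixture is a checksummed transcription of the 40-patient LSF
table (8 method columns; 20 patients carry post-therapy PET values). One
printed AC entry (patient 23, 0.3 below its AC+SC 0.7) is a suspected
typographical inversion; it is transcribed as printed and no statistic in
scope depends on it. Summaries are arithmetic mean and range (reported to
1 dp); the paired t statistic is computed from its definition (mean
difference over standard error, df = n − 1) and cross-checked against a
sign-flip permutation test; the planar:SPECT ratio is the mean of
per-patient ratios (4.3), with the ratio of means (3.6) reported
separately because the two differ materially. The squared Pearson
correlation between planar and SPECT LSFs computed from the 1-dp table is
0.425; the published scatter-plot value (0.46) evidently used
full-precision clinic values, a gap input rounding alone cannot close —
tests therefore accept 0.46 ± 0.05.

## Problem sizes and numerical choices

Simulation-backed checks run at a 64³ grid (6 mm voxels), 60 views, 8 × 4
OSEM, three noise realizations per phantom fill — about two minutes of
projector/reconstruction work per study on one core; unit tests exercise
the same code at 48³/24 views. Degenerate inputs are errors, not silent
results: empty bodies, absent lung candidates, margins exceeding lung
height, all-zero emission volumes, zero-count LSFs, non-positive masses.
Ratios guard division (0/0 → 0 inside OSEM; explicit errors elsewhere).
Ties in the left/right lung split cannot occur (a 10 mm mediastinal gap is
built into the phantom); single-lung segmentations warn rather than fail.

## What passing tests do and do not show

The simulator reproduces the *mechanisms* of LSF bias — attenuation
asymmetry, scatter spill-in, motion smear — and the tests verify the
clinically observed pattern: uncorrected SPECT > AC > AC+SC, planar
geometric mean > planar ant/post, all planar estimates above truth, AC+SC
within 15 % of truth, near-zero residual at zero shunt, and sub-percent
repeatability across noise realizations. The *numerical* LSF values of a
physical camera depend on collimator, energy resolution, septal
penetration and vendor reconstruction details that are not modeled, so
simulated magnitudes are comparable in kind, not digit-for-digit, with
measured phantom tables. Patient-table statistics, by contrast, are exact
recomputations from the fixture. Known limitations: no Monte Carlo photon
transport, no septal penetration or dead time, no Y-90 bremsstrahlung/PET
physics (post-therapy volumes enter as generic reconstructed inputs), no
deformable registration between beds, and parametric rather than
anthropomorphic anatomy.
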