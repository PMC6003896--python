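# lungshunt

Quantification of the **lung shunt fraction (LSF)** for Y-90
radioembolization planning — and a digital testbed for asking how much the
answer depends on how you image it.

Before trans-arterial radioembolization (TARE) of liver tumors, Tc-99m-MAA
is injected into the hepatic artery and imaged to estimate the fraction of
particles shunting to the lungs,

&nbsp;&nbsp;&nbsp;&nbsp;LSF (%) = 100 · C_lung / (C_lung + C_liver),

which caps the prescribed activity through the MIRD lung dose

&nbsp;&nbsp;&nbsp;&nbsp;D_lung (Gy) = 49.38 · A (GBq) / m_lung (kg) · LSF.

Planar scintigraphy — still the standard — overestimates the LSF because
lung attenuates far less than liver and because 2-D views cannot exclude
liver activity smeared into the lung base by breathing. Quantitative
SPECT/CT with attenuation correction (AC), energy-window scatter
correction (SC), CT-based lung/liver contouring and a 2 cm inferior-lung
exclusion largely removes these biases. This package implements the whole
chain:

* **`lungshunt.phantom`** — a voxelized liver/lung torso phantom whose
  compartment volumes are solved from published fill constraints (true
  LSF 0 / 3.6 / 6.9 %, 195 MBq), breathing blur, and seeded synthetic
  patient cohorts;
* **`lungshunt.scanner`** — planar and SPECT projection with attenuation,
  depth-dependent collimator blur and window-based scatter, plus OSEM
  reconstruction (8 it × 4 subsets, 8.4 mm post-filter) with AC and SC
  independently toggleable; the projector/backprojector pair is exactly
  adjoint;
* **`lungshunt.contour`** — the auto-contouring workflow: whole-body VOI,
  HU ≤ −150 lung lock with left/right split and volume cleanup, per-lung
  2 cm inferior exclusion, percent-of-max liver VOI, and count-density
  extrapolation to the full CT lung volume (also used for partial-FOV PET);
* **`lungshunt.quantify`** — LSF by planar ant/post, planar geometric-mean
  and volumetric methods; CT lung mass (0.3 kg/L); MIRD dose with an
  explicit percent/fraction unit tag;
* **`lungshunt.cohort`** — a checksummed 40-patient LSF table (planar,
  SPECT variants, post-therapy PET for 20 patients) and the statistics
  over it: means/ranges, paired t tests, Pearson correlation, per-patient
  ratios, threshold-exceedance counts;
* **`lungshunt.pipeline` / CLI** — drivers for the phantom
  accuracy/precision experiment and the patient LSF + dose workflow.

## Worked example

Simulate the torso phantom study (three true shunt levels, three noise
realizations each, five estimators):

```
$ lungshunt run-phantom-experiment --seed 1 --out out/
LSF 0%  planar_antpost   2.98 (0.02)
LSF 0%  planar_gm        4.33 (0.02)
LSF 0%  spect_noc        1.38 (0.01)
LSF 0%  spect_ac         0.67 (0.00)
LSF 0%  spect_acsc       0.07 (0.00)
LSF 3.6%  planar_antpost   8.07 (0.07)
LSF 3.6%  planar_gm       10.06 (0.03)
LSF 3.6%  spect_noc        7.07 (0.02)
LSF 3.6%  spect_ac         3.86 (0.01)
LSF 3.6%  spect_acsc       3.19 (0.01)
LSF 6.9%  planar_antpost  12.49 (0.02)
LSF 6.9%  planar_gm       14.87 (0.01)
LSF 6.9%  spect_noc       12.44 (0.01)
LSF 6.9%  spect_ac         6.96 (0.01)
LSF 6.9%  spect_acsc       6.31 (0.02)
```

Each row is the mean (SD) LSF over the noise realizations. The pattern is
the clinically observed one: planar methods overestimate (geometric mean
worst), uncorrected SPECT overestimates, AC removes most of the bias and
AC+SC lands within 15 % of truth (3.19 vs 3.6; 6.31 vs 6.9) with a
near-zero residual (0.07 %) when nothing shunts.

Dose impact of the planar overestimate for one patient
(4.377 GBq, standard 1 kg lung, planar LSF 13.6 %):

```
$ lungshunt dose -a 4.377 --lsf-percent 13.6 --lung-mass-kg 1.0
{
  "administered_activity_gbq": 4.377,
  "lung_mass_kg": 1.0,
  "lsf_fraction": 0.136,
  "dose_gy": 29.39...
}
```

— close to the 30 Gy eligibility limit, while the same patient's SPECT/CT
estimate (LSF 2.5 %, CT mass) gives ~6.5 Gy.

Cohort statistics from the packaged patient table:

```
$ lungshunt cohort-stats
{
  ...
  "planar_all":     {"method": "planar",     "n": 40, "mean": 5.435, "min": 1.2, "max": 15.7},
  "spect_acsc_all": {"method": "spect_acsc", "n": 40, "mean": 1.51,  "min": 0.4, "max": 6.0},
  "planar_vs_pet":     {"max_abs_diff": 12.3, "n_exceeding_5_points": 3, "p": 8.37e-05},
  "spect_acsc_vs_pet": {"max_abs_diff": 1.6,  "n_exceeding_5_points": 0, "p": 0.951},
  "planar_to_spect_acsc_mean_ratio": 4.34,
  "planar_vs_spect_acsc_r2": 0.425
}
```

Planar imaging runs ~4× higher than corrected SPECT/CT patient-by-patient,
while SPECT/CT agrees with post-therapy Y-90 PET/CT to within 1.6 points.

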