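# bone4d

Longitudinal in vivo micro-CT 4D bone (re)modeling analysis for the mouse
tibial-loading study design: Sost knockout (KO) vs littermate control (LC)
mice, young (10 wk) and skeletally mature (26 wk), one tibia cyclically
loaded to a strain-matched +900 µε peak while the contralateral limb serves
as internal control.

The package implements the full analysis chain for that design:

* **Synthetic scans with ground truth** — tapered, crested elliptical-tube
  cortical phantoms at 10.5 µm isotropic voxels, with analytic surface
  formation/resorption between time points, rigid misalignment, scanner PSF
  and noise (`bone4d.synthetic`). No raw scans are distributed with the
  study, so every downstream step is validated against these generators.
* **Imaging** — grey-value rigid registration (mean squares,
  multi-resolution, optional second pass that masks out remodeled voxels),
  global thresholding at 4626 HU (809.6 mg HA/cm³), cortex extraction and
  mid-diaphyseal VOI selection (5 % of tibial length) (`bone4d.imaging`).
* **Static morphometry** — Ct.Ar, T.Ar, Ct.Ar/T.Ar, Ct.Th
  (largest-inscribed-sphere local thickness), Imax/Imin, Ct.vTMD
  (`bone4d.morpho_static`).
* **Dynamic 4D morphometry** — quiescent/formed/resorbed voxel labeling
  between registered day-0/day-15 masks and the normalized parameters
  MV/BV, EV/BV, MS/BS, ES/BS (`bone4d.morpho_dynamic`).
* **Dynamic histomorphometry** — sLS/BS, dLS/BS, MS/BS = 0.5·sLS/BS +
  dLS/BS, MAR over the 9-day labeling interval, BFR/BS = MAR·MS/BS/100,
  with the "no data" rule for sections without double labels
  (`bone4d.histomorphometry`).
* **Assays** — strain-gauge load calibration (per-animal OLS of load on
  strain; load at +900 µε) and qPCR ΔCt relative expression against B2m
  with paired/independent tests on ΔCt (`bone4d.assays`).
* **Statistics** — interlimb differences, %Δ = (loaded − control)/control ×
  100, paired/independent t-tests, and the split-plot repeated-measures
  ANOVA with loading within-subject and genotype × age between-subject,
  plus the separate between-subjects ANOVA on interlimb differences
  (`bone4d.stats`).

## Worked example

Strain-matched loading requires a per-group calibration of the load–strain
relation. With the published group regression slopes the package computes
the load producing +900 µε at the gauge site:

```python
>>> from bone4d.assays import load_for_target_strain
>>> load_for_target_strain(-0.0143, 900.0)   # young Sost KO slope, N/µε
-12.9
>>> load_for_target_strain(-0.0161, 900.0)   # adult Sost KO
-14.5
```

So a young KO tibia needs −12.9 N and an adult KO tibia −14.5 N of axial
compression to reach the same +900 µε peak strain that −7 N produces in LC
mice — the KO cortex is roughly twice as stiff at the gauge site.

The histomorphometry arithmetic on the young-LC loaded endocortical surface:

```python
>>> from bone4d.histomorphometry import bone_formation_rate
>>> 0.5 * 11.9 + 68.2            # MS/BS from single/double label fractions
74.15
>>> bone_formation_rate(74.2, 1.5)   # BFR/BS from MS/BS and MAR, µm³/µm²/day
1.113
```

Both values round to the published group cells (74.2 % and 1.11).

The numbered drivers under `analysis/` run the full chain on synthetic
cohorts — `01_strain_calibration.py`, `02_remodeling_recovery.py`,
`03_static_morphometry.py`, `04_histomorphometry.py`, `05_qpcr.py`,
`06_statistics.py` — each printing what it found and writing its tables
under `results/`. A thin CLI (`bone4d simulate|register|segment|static|
dynamic|histo|strain-fit|qpcr|stats|run`) wraps the same library calls for
shell use.

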