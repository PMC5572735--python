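# Methods

## Study design and what the package computes

The analysis targets a two-week mouse tibial-loading experiment: the left
tibia of Sost knockout (KO) and littermate control (LC) mice, at 10 and 26
weeks of age, receives cyclic axial compression calibrated per group to a
+900 µε peak strain at a mid-diaphyseal gauge site; the right tibia is the
within-animal control. In vivo micro-CT at days 0 and 15 (10.5 µm isotropic)
yields static cortical morphometry and, after rigid registration of the
day-15 scan onto day 0, a voxel-level 4D analysis of where bone was formed
and resorbed. Fluorochrome double labeling (days 3 and 12, a 9-day interval)
yields conventional dynamic histomorphometry, and qPCR at 3/8/24 h after a
single loading bout yields Wnt-pathway relative expression. The raw scans
were never deposited, so the package pairs every computation with a
synthetic generator whose ground truth is exact by construction.

## Coordinate and unit conventions

Volumes are `grid[i, j, k]` with the bone's long axis on the third index;
voxel `(i, j, k)` has its centre at `((i+0.5)s, (j+0.5)s, (k+0.5)s)` µm.
Crops are half-open, indices 0-based. Grey values are HU; the default
calibration is proportional with 4626 HU ↔ 809.6 mg HA/cm³ (the only pair
the protocol fixes), overridable. Components use 26-connectivity, exposed
surfaces 6-connectivity faces. Thresholding is inclusive (≥), so
thresholding in HU at 4626 and in density at 809.6 select identical voxels.

## Synthetic phantoms

The cortical phantom is an elliptical tube (outer/inner semi-axes in µm)
rasterized by the centre-sampling rule: a voxel is bone iff its centre lies
inside the outer boundary and not strictly inside the inner ellipse. This
rule makes brute-force per-voxel oracles exact. Optional structure, all
analytic and used consistently by the remodeling generator:

* **taper** — linear radius change along the axis (a diaphysis is conical);
* **crests** — Gaussian angular ridges on the periosteal boundary (the
  tibial-crest analogue);
* **axial ripple** — a small sinusoidal radius modulation along the axis;
* **grid offset** — shifts the anatomy relative to the acquisition grid,
  emulating a second scan (and, at sub-voxel size, residual
  misregistration) without any interpolation;
* **PSF and noise** — Gaussian blur (σ in µm) and additive HU noise applied
  identically to every acquisition of a pair.

The structural options are not decoration: an axially uniform smooth tube
leaves the axial position (and, for near-circular sections, the axial
rotation) unobservable to any intensity metric, and a *monotone* taper lets
a rigid axial drift "explain" periosteal growth — we measured the
mean-squares metric to be genuinely lower at a drifted pose than at the true
alignment. Crests pin the rotation; the ripple pins the axial coordinate.
Real cortices carry this structure intrinsically.

Remodeling is applied analytically: per-angular-sector apposition depths on
the periosteal/endocortical boundary and ball-shaped resorption pits with a
radial depth limit and a perforation guard. Ground-truth counts are measured
on the emitted voxel sets, never assumed. Default generator conditions
follow the study scale: n = 7/age/genotype limbs, formation depths of
10.5–31.5 µm over part of the circumference (MV/BV ≈ 0.05–0.1 over 15 days),
one small endocortical pit (EV/BV a few × 10⁻³, the young-control scale),
noise 120–150 HU and PSF σ = 8 µm in the demo pipeline (the protocol does
not report scan noise or PSF; these are declared assumptions).

## Registration

Grey-value rigid registration (SimpleITK): mean-squares metric — both scans
share one calibration — linear interpolation, gradient descent with line
search (step capped at 2 voxels), scales from physical shift, initialized
at the moments centroid. The pyramid is two-level (shrink 2, 1): diaphyseal
VOIs have few axial slices and a deeper pyramid can leave too little axial
structure at the coarsest level, which we observed to throw the optimizer
into a distant basin. The metric excludes a 4-slice axial margin of the
fixed image (a repositioned scan has no valid data beyond its field of
view; the fill value otherwise biases the axial alignment). An optional
second pass re-runs the registration with all voxels masked out that still
disagree by >40 % of the grey range after the first pass (dilated by one
voxel): between time points the remodeled bone is exactly such a change,
and leaving it in the metric drags the pose (measured improvement
0.46 → 0.19 voxel on a remodeled pair). Measured recovery on structured
phantoms: 0.02–0.2 voxel and <0.25°, and ≥95 % success at 0.25 voxel/0.5°
under 10 %-of-contrast acquisition noise (50 seeded trials).

## Static morphometry

Ct.Ar and T.Ar are per-slice pixel counts (T.Ar after 2D hole filling of
the periosteal envelope), averaged over VOI slices; the VOI covers 5 % of
the bone length centred at the mid-shaft (82 slices for a 17.3 mm tibia at
10.5 µm). Imax/Imin are per-slice second-moment tensors about the slice
centroid, eigen-decomposed and averaged. Ct.vTMD is the calibrated mean
density over bone voxels.

Ct.Th uses the largest-inscribed-sphere (distance-transform) definition,
computed by morphological opening over descending sphere radii on a 2×
supersampled grid. Supersampling lets sphere centres fall between original
voxel centres, removing the one-voxel parity bias of centre-restricted
sphere fitting; the mask is edge-padded so VOI cut faces are treated as
continuing bone. Radii are quantized to 0.25 upsampled voxels so the
discretization scales with resolution; the opening loop stops once ≤2 % of
the foreground is uncovered and fills the residue from the nearest covered
voxel (a bounded overestimate on <2 % of voxels). Accuracy on a 150–200 µm
annular wall: 1–2 µm at 10.5 µm voxels. The estimator's error is dominated
by rasterization-alignment fluctuation below ~21 µm voxels (measured 5.9 µm
@42 µm, 1.3 @21, 2.0 @10.5, 1.6 @5.25 on a 150 µm wall): convergence checks
therefore use the 42→21 µm pair, where discretization dominates, while the
accuracy bound (2 %) is checked at 10.5 µm.

## Dynamic 4D morphometry

With masks on a common grid: quiescent = day0 ∩ day15, formed =
day15 ∖ day0, resorbed = day0 ∖ day15. Formed/resorbed 26-connected
clusters below `min_cluster` voxels (default 2) are reassigned to
background/quiescent as interpolation speckle. MV/BV and EV/BV normalize
formed/resorbed counts to the day-0 bone volume; MS/BS and ES/BS count
day-0 exposed 6-faces whose exterior neighbour became formed (MS) or whose
bone voxel was resorbed (ES), normalized to the day-0 surface. Both
envelopes are combined, and axial faces on the first/last slice are
excluded as VOI crop artifacts. At `min_cluster` 1 on a lossless pair the
pipeline inverts the generator exactly (counts equal; |day15| = |day0|(1 +
MV/BV − EV/BV) as a set identity).

Ordering: the day-15 grey volume is registered, resampled (linear), then
thresholded — the alternative (threshold in the native grid, carry the mask
with nearest-neighbour) was measured and retained as an option;
on the demo it gave +10 % MV/BV vs −6.7 % for the grey ordering.

**Known limitation.** On a noisy, rotated scan pair the voxel-level
difference carries a thin (≈1 voxel) boundary jitter shell. For formation
at the study scale this is a ±10 % effect, but when true resorption is very
small (young-control scale, EV/BV ~10⁻³) the shell can dominate EV/BV. The
cluster-size filter cannot remove it (the shell is connected), and a 2×2×2
morphological opening that removes it also destroys genuine 1–2-voxel
formation shells (measured). The demo therefore treats sub-voxel-scale
EV/BV as qualitative; exact recovery is demonstrated on lossless and
offset-grid pairs. Passing tests show the algorithmic chain is correct;
they do not certify EV/BV precision on real noisy scans at the smallest
published effect sizes.

## Histomorphometry

sLS/BS and dLS/BS are label perimeters over the total surface length per
envelope; MS/BS = 0.5·sLS/BS + dLS/BS; MAR = mean double-label distance /
9 days; BFR/BS = MAR · MS/BS / 100 (the product reproduces the published
group cells, e.g. 1.5 × 74.2/100 = 1.11). A section with dLS/BS = 0 carries
no MAR/BFR ("no data") and is excluded listwise from group statistics.
Sections are averaged per animal before group mean ± SD. The MS/BS identity
holds for all eight published endocortical group cells within one unit in
the last digit; the periosteal group cells are not derivable from their
printed sLS/dLS means (per-animal exclusions in the original aggregation),
so tests assert the identity on Ec and internal consistency on Ps.

## Assays

Strain calibration regresses load (N) on strain (µε) per animal (OLS);
group slope = mean ± SD over animals; the strain-matched load is slope ×
900 µε, reported half-away-from-zero at the printed precision (0.1 N for
KO, integer for LC). qPCR uses ΔCt = Ct_gene − Ct_B2m per (animal, limb)
block; fold change between conditions is 2^−ΔΔCt on group-mean ΔCt
(geometric-mean convention), with paired t-tests on ΔCt for loaded-vs-
control and independent t-tests for genotype/age contrasts. Undetected
genes propagate as missing.

## Statistics

Loading is within-subject (2 levels), genotype and age between-subject
(2 × 2). With a 2-level within factor the classical split-plot
decomposition is exact and sphericity trivial: the between stratum is a
two-way ANOVA on each animal's limb mean, the within stratum an ANOVA
(including the intercept test, which is the loading main effect) on each
animal's half-difference. Type III sums of squares via Wald tests on the
sum-coded full-factorial model — with 2-level factors each term is one
coefficient, so F = (β/SE)². On the single-cell reduction the loading F
equals the squared paired-t statistic to machine precision, and on the
one-between reduction the F values match pingouin's mixed ANOVA. A separate
between-subjects ANOVA on Δ_interlimb = loaded − control serves the
relative-value analysis. Independent t-tests default to the pooled-variance
form (switchable); no multiple-testing correction is applied across
outcomes; α = 0.05. Degenerate zero-variance inputs: all-zero differences
give t = 0, p = 1; constant nonzero differences give |t| = ∞, p = 0.

Null calibration: 2,000 replicates of the full design at n = 7/cell give
every term a rejection rate within 0.05 ± 0.015.

## Problem sizes

Test and acceptance runs use phantoms of roughly 60–110 voxels across and
16–30 slices, 150–200 µm walls, chosen so the whole suite exercises every
code path at full fidelity; simulation-based calibrations use 200–10,000
replicates depending on the Monte-Carlo error the assertion needs.

## What the generators do not emulate

Beam hardening, ring artifacts, scatter, woven-bone microstructure,
trabecular bone, osteocyte lacunae, and anatomically realistic cross-section
shapes. Tests passing on phantoms demonstrate correctness of the
computational chain and its behaviour under controlled noise, misalignment
and remodeling — not performance on real scans, where PSF, motion artifacts
and biological variability add error sources the generators do not model.
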