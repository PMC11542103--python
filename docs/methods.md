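# Methods

This note documents the models, conventions, numerical choices and known
limitations of `retvasc`. Everything stated here is computed by the test
suite or the examples; nothing is quoted from external results.

## Conventions

Pixel grids are 0-based `(row, col)` with the origin at the top-left and y
increasing downward. Angles are degrees in image coordinates; "elevation"
is the angle above the horizontal through the optic-disc (OD) centre.
Skeletons use 8-connectivity. All serialized coordinates are 0-based; all
thresholds live in `PipelineConfig` with their defaults.

## Vessel graph extraction

1. **Skeletonization.** `skimage.morphology.skeletonize` thins the binary
   class mask to a 1-px, topology-preserving skeleton.
2. **Nodes.** Skeleton pixels with ≠ 2 eight-neighbours are node pixels;
   node pixels within Chebyshev distance 2 collapse to one node at their
   centroid (thinning emits clusters at branch points). Maximal degree-2
   chains between nodes become ordered centerline segments; pure cycles are
   kept as loops anchored at an arbitrary pixel.
3. **Spur pruning** (default 10 px). Terminal segments shorter than the
   threshold are artifacts of thinning and are removed; junctions reduced
   to degree 2 are dissolved by concatenating their two segments. The
   operation is idempotent.
4. **Junction consolidation** (default 10 px). Thinning a wide junction
   often produces a short parallel-path loop or two branch points a few
   pixels apart where the anatomy has one bifurcation. Internal segments
   shorter than the threshold joining two degree-≥3 nodes are contracted.
   Without this, bifurcation counts on wide-vessel trees are systematically
   inflated/deflated by junction artifacts. Two genuinely distinct
   bifurcations closer than the threshold would merge into a degree-4 node
   (tagged as a crossing candidate) — an accepted ambiguity at typical
   fundus resolution.
5. **Centerline smoothing.** Integer pixel chains overestimate arc length
   through staircase zigzag (up to ~8% at 22.5° orientations). A window-3
   moving average applied twice (endpoints fixed) recovers sub-pixel
   centerlines; measured distance-factor tortuosity then matches analytic
   arc/chord on straight, half-circle and sinusoidal fixtures to well
   within 2%.
6. **Diameters.** Per-point diameter
   `= 2 × ridge-corrected EDT − 1 px`, where the Euclidean distance
   transform is sampled bilinearly at the point and at ±0.5 px along the
   local normal, taking `max(EDT + |offset|)`. Rationale: the EDT reaches
   to the first *background pixel centre* (~half a pixel past the true
   boundary on each side), and on even-width strokes the skeleton sits half
   a pixel off the true medial ridge. The correction restores both the
   absolute calibration (a width-5 bar reads ~5) and scale equivariance
   (2× upscaling doubles readings within 10%). Residual error is dominated
   by half-pixel quantization: ±10% at 5 px width, shrinking with caliber.

Degree-3 nodes are bifurcations; degree-≥4 nodes are crossing candidates
(e.g. one vessel passing over another of the same class) and are excluded
from the bifurcation count, which is summed over the two per-class graphs.

## Phenotype definitions and thresholds

- **Tortuosity** is the distance factor `arc/chord` per segment, median
  over segments with chord ≥ 10 px (`min_chord_px`; shorter chords make
  the ratio numerically unstable). Curvature-integral variants are out of
  scope.
- **Diameter stats** (median, population std) pool all per-point diameters
  of a class; fewer than 50 samples (`min_points`) yields missing values
  rather than noisy ones.
- **Central retinal equivalents** use zone B, the annulus 0.5–1.0 disc
  diameters from the disc margin (radii `2r_OD` to `3r_OD`), the
  conventional region for CRAE/CRVE. Each segment contributes its mean
  in-zone diameter; the six widest are paired iteratively (sorted, widest
  with narrowest, odd middle carried) with coefficients 0.88/0.95. With
  fewer than six eligible vessels the value is computed on what is
  available and flagged (`n_vessels=k` in the QC flags); with none it is
  missing.
- **Temporal angle**: diameter-weighted mean unit position vectors (from
  the OD centre) over centerline points in the annulus 1.0–2.5 OD radii,
  temporal half-plane only, split into superior/inferior by elevation with
  a ±5° dead band (an undulating horizontal trunk must not read as two
  arcades); the angle between the two mean directions. The temporal side
  is inferred from the OD's offset from the image midline and can be
  overridden with a laterality hint. The exact operationalization of this
  angle varies across the literature; this one is validated against the
  generator's ground truth (recovery within ±5° across the acceptance
  batch).
- **Vascular density** = vessel ∧ ROI pixels / ROI pixels. Default ROI:
  the disk inscribed in the frame minus the OD disk.
- **Ratios** are artery/vein throughout. Missing inputs propagate to
  missing outputs — never silent zeros; an empty class mask marks the
  whole class (and the joint bifurcation count) unmeasurable.

## Synthetic vasculature (the test oracle)

Each class is a complete binary tree: a trunk enters from the nasal side
and splits exactly at the OD centre into superior/inferior temporal arcades
(elevations `arcade_sup`/`arcade_inf`); deeper levels split symmetrically
about the parent with geometrically decaying lengths (×0.7/level), split
half-angles (×0.7) and Murray-law calibers (`child = parent·2^(−1/3)` by
default, exponent configurable). Centerlines are sinusoids with analytic
arc length (quadrature oracle for tortuosity). The vein tree is the same
construction rigidly rotated 4° about the OD (leaving `sup+inf` — the true
temporal angle — invariant) with calibers ×1.1 and independent jitter, so
the class rasters are distinct and artery–vein crossings arise naturally.
Strokes are unions of disks along the densified centerline; truth records
bifurcation counts (`2^depth − 1` per class), per-segment
diameter/tortuosity/arc length, arcade angle sums and exact pixel counts.

Default study conditions (a 576² canvas, OD radius 40 px, root calibers
10–16 px, segment lengths 85–110 px, arcade elevations 45–65°, tortuosity
amplitudes 0–4 px, depths 1–4) emulate disc-anchored arcade geometry at
roughly UK-Biobank-like vessel widths. They deliberately do **not** emulate
intensity profiles, segmentation noise, broken vessels, optic-disc
appearance or pathology — so passing recovery tests demonstrates the
correctness of the measurement chain on clean geometry, not robustness to
segmentation failure modes.

## QC, aggregation and preparation

- Images below the 25th percentile of the quality score fail QC
  (linear-interpolation percentile; ties at the threshold pass; fewer than
  4 scores: all pass with a warning). With no external score, total
  vascular density serves as the proxy. Note a consequence of linear
  interpolation: for n not divisible by 4 the retained count is
  `floor(0.75n)`–`ceil(0.75n)`, exactly 75% when divisible.
- Per subject, only the earliest visit with a passing eye is used; the two
  eyes are averaged field-wise over non-missing values, otherwise the
  single passing eye is taken.
- Rank-based inverse normal transformation uses the Blom offset (3/8), the
  GWAS convention; ties share average ranks; all-identical input maps to 0
  with a warning.
- Residualization is OLS with an intercept; categorical covariates expand
  to drop-one indicators; rank-deficient designs fall back to least
  squares on the column space with a logged warning. Residuals are
  orthogonal to every covariate column to numerical precision. The
  covariate battery (age, sex, age², sex×age, sex×age², spherical and
  cylindrical powers and their squares, centre/batch indicators, genomic
  PCs) is assembled from base columns; the spherical equivalent is
  `spherical + cylindrical/2` diopters.
- A known quality–age correlation in real cohorts is deliberately **not**
  corrected for.

## Statistics

- Correlation matrices are pairwise-complete Pearson with a minimum of 3
  complete pairs per cell.
- The genetic-vs-phenotypic comparison runs over the upper-triangle pairs:
  Cohen's `d = (mean(r_g) − mean(r_p)) / sqrt((SD_g² + SD_p²)/2)` (pooled
  SD; a difference-of-variances denominator is available behind
  `denominator="printed"` for auditability but is undefined whenever
  `SD_p > SD_g`), a two-sided paired *t* with `df = n_pairs − 1`, and the
  Pearson correlation between the two vectors with a permutation *p* from
  10⁴ random re-pairings of the entries (seeded, reported as
  `(1 + #{|r*| ≥ |r|}) / (n_perm + 1)`, so it is bounded below by
  `1/(n_perm+1)`).
- The association battery fits one single-regressor model per
  (phenotype, trait) pair — OLS on z-scored variables for continuous
  traits, logit on the z-scored phenotype for binary ones (effects as odds
  ratios per SD) — with Bonferroni tiers at `0.05/N` and `0.001/N`,
  `N = N_IDPs × N_traits`. Degenerate traits (a single class) and
  non-converging fits yield missing results with warnings. Cox
  proportional-hazards models are out of scope.

## Problem sizes used in the tests

The acceptance suite measures parameter recovery on 200 generated images
(depths 1–4, seeded), statistical calibration on 500 null replicates of a
17×20 battery (n = 250), and effect recovery at n = 2000; the full suite
runs in a few minutes on one CPU. Determinism is asserted byte-for-byte on
pipeline CSV outputs under a fixed seed.

## Known limitations

- The pipeline starts at segmentation masks; it never touches raw fundus
  photographs, and segmentation/OD-detection quality bounds everything
  downstream.
- Diameter readings below ~3 px are dominated by quantization; tortuosity
  of segments shorter than the chord threshold is not measured.
- Degree-≥4 junctions are ambiguous between crossings and closely spaced
  bifurcations; they are excluded from bifurcation counts.
- The temporal-angle estimator assumes arcades radiate from near the OD
  centre within 1.0–2.5 OD radii; unusual disc-centred geometries (e.g.
  disc-centred images with strong cyclotorsion) may need the annulus
  retuned.
- Fractal dimension, branching angles, artery–vein crossing phenotypes and
  extended phenotype sets are out of scope.
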