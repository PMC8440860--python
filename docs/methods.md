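# Methods

`famhci` re-creates, end to end, a high-content morphometric profiling
workflow for alveolar macrophage activation states and foamy (vacuolated,
lipid-laden) phenotypes: a synthetic multi-channel field generator with
exact ground truth, the image-analysis protocol (nucleus-seeded cell
segmentation, negative-stain vacuole detection), per-cell morphometrics,
flow-cytometry-style percent-positive gating, colorimetric assay
computations, and the statistical layer (one-way ANOVA with Bonferroni
post-hoc on experiment-level means). This note documents the models, the
parameters that matter, and the design choices that were genuinely open.

## The measurement model

Each imaged field carries four channels: a nuclear stain, a whole-cell
cytoplasm stain in which vacuoles appear as *negative-stain holes*, a
phospholipid-selective stain and a neutral-lipid stain. The analysis
protocol is:

1. **Nuclei** — Gaussian smoothing (σ = 1 px), Otsu threshold, hole
   filling, watershed on the Euclidean distance transform to split
   touching nuclei, removal of components below `min_nucleus_area_um2`
   (default 20 µm²).
2. **Cells** — the cytoplasm channel is thresholded (Otsu) after a light
   0.5 px blur, interior holes are filled (vacuoles belong to the cell
   body), and a marker-based watershed seeded by the nucleus labels
   partitions touching cells along equidistant lines. Foreground without a
   nucleus is discarded; border-touching cells are excluded by default so
   area statistics are unbiased; each retained cell carries the label of
   its single seed nucleus.
3. **Vacuoles** — within each cell, connected regions (8-connectivity)
   below `vacuole_relative_threshold` (default 0.5) × the cell's median
   cytoplasm intensity. The enclosure reference is the cell mask after a
   radius-2 closing and hole filling: a vacuole hugging the membrane can
   pinch the thresholded cytoplasm strip apart, and the closing restores
   its enclosure, while genuine boundary notches (open by more than ~4 px)
   stay open and are rejected. Components overlapping the nucleus, below
   0.5 µm², or above half the cell area are rejected. The vacuole
   threshold runs on the *raw* channel: vacuoles are small high-contrast
   holes and even mild smoothing erodes their measured area by tens of
   percent at 2–3 px radii.
4. **Features** — per cell: nuclear and cellular area (pixel counts ×
   `pixel_size_um²`), vacuole count, mean and total vacuole area, percent
   of the cell occupied by vacuoles, and background-corrected integrated
   lipid intensities (Σ(channel − median outside all cells) over the cell
   mask, clipped at 0). A vacuole-free cell reports a mean vacuole area of
   0 (not missing) so population averages stay defined; exclusion is a
   config switch.

All thresholds are relative, so segmentation is invariant to a global
positive gain on the intensities.

## The synthetic-data generator

The generator emulates four-channel fields of NR8383-like macrophage
populations. Cells are ellipses (axis ratio ≤ 1.2) with a low-frequency
radial perturbation (amplitude ≤ 8%, 3–5 lobes), rescaled so the enclosed
area is exact; they are placed on a jittered 11×11 grid in a 1024² field
(0.325 µm/px, 16-bit) so outlines never overlap or touch the border and a
9-field well yields ~1100 measurable cells, matching the 1000–2000 cells
per well of the real assay design. The published protocol states neither
pixel size nor field geometry; these are explicit, plausible defaults for
a 40x high-content imager and are carried in metadata, never hard-coded
downstream.

Per-cell draws: cell and nuclear areas are truncated normals (±2.5 SD,
symmetric, hence unbiased; CV 12% and 10%); vacuole counts are negative
binomial (dispersion 30 — over-dispersed counts are biologically typical)
with the *mean proportional to the cell's sampled area*, so the population
mean of total-vacuole-area/cell-area equals `count_mean × area_mean /
cell_area_mean` exactly; single-vacuole areas are lognormal (σ_log 0.35).
Vacuole disks are placed by rejection sampling (largest first, with an
exhaustive polar-grid fallback) subject to: ≥ 1.6 px clearance from the
outline (> √2, so a cytoplasm strip pixel always separates hole from
background), ≥ 1.2 px from the nucleus ellipse, and ≥ 1.6 px between
disks (two rasterized disks can only merge under 8-connectivity if their
gap is below √2). Placement failures are confined to genuinely saturated
cells and bias delivered counts by well under 1%.

Rendering deposits a uniform cytoplasm amplitude over the cell (holes stay
at background), a nuclear amplitude over the nucleus, 70% of the cell's
phospholipid flux in 2 px rings around its vacuoles (30% diffuse), and 85%
of the neutral-lipid flux in Gaussian droplets renormalized over the
in-cell pixel set (15% diffuse). Per-cell lipid flux is conserved exactly,
so integrated intensity is an unbiased readout and fold changes transfer
through the pipeline. Noise is Poisson photon noise plus additive Gaussian
read noise (default 2% of the 16-bit range); ground-truth masks are fixed
before noise injection and are independent of the seed.

Adhesion is modeled by dropping non-adherent cells before rendering
("washed off"), which makes the adherent fraction observable as a cell
count ratio between matched wells.

### Phenotype presets and calibration

Preset population means are calibrated to published anchors for this
system: non-activated cells at 226 µm² cell / 75 µm² nuclear area,
2.16 µm² single vacuoles totalling 20 µm² (⇒ 9.26 vacuoles/cell); the
LPS/IFN-γ-activated state at 290 / 65 µm², 2.4 µm² vacuoles, 45% adherence
relative to control, phagocytic fractions 51% → 41%, and lipid fold
factors 1.5× (phospholipid) / 2.7× (neutral lipid), with amiodarone
challenge raising phospholipid to 1.5× on the resting background and 3.8×
on the activated background. The activated state's printed vacuolation
anchors are mutually inconsistent (40 µm² at 2.4 µm²/vacuole implies 16.7
vacuoles against a printed count excess of +6; 40/290 = 13.8% against a
printed 11.7%). The activated count mean of 15.3 is the analytic
compromise that equalizes the relative deviation from the total-area and
percent anchors (~8% each) while keeping the count excess at +6.0; it was
derived from the preset algebra, not fitted to pipeline output. The
IL-4 preset coincides with the resting preset (that stimulation does not
measurably polarize this cell line); staurosporine on the activated
background enlarges single-vacuole area by 20% (direction chosen — the
source reports significance but no magnitude). Nitrite and arginase preset
levels are plausible working values with no published numeric anchor; they
feed no calibration target.

### What the generator does *not* emulate

No optical PSF or z-structure, no illumination gradients or vignetting, no
photobleaching, no cell contact or overlap, no debris/artifacts in the
image channels, no texture inside nuclei or cytoplasm. Passing tests
therefore demonstrate that the analysis chain is correct and unbiased on
geometry it can fully observe — not that it would be robust to focus
drift, clumped cells or staining artifacts in real micrographs.

## Cytometry and assays

Events are (forward scatter, side scatter, green fluorescence) with debris
simulated at low scatter; the debris gate retains events above nominal
scatter minima (2000/1200 AU). Percent-positive gating thresholds at the
control's 0.99 quantile, taken as an order statistic so the result is
invariant under monotone transforms of the fluorescence axis; the published
protocol says only "comparison with untreated control", so the quantile
rule is this package's explicit substitute and the quantile is
configurable. Bead counts are zero-inflated Poisson tied to the preset's
positive fraction; bead fluorescence sits far above autofluorescence, so
percent positive ≈ the positive fraction plus the 1% false-positive rate
of the gate. Default event counts: 5000 (beads), 10000 (receptor mode).

The nitrite computation fits an ordinary least-squares line to the
sodium-nitrite standards (the Griess response is linear over the assay
range; a 4PL adds nothing here) and inverts it, clipping negative values
at zero with a warning and flagging extrapolation beyond the standard
span. Arginase activity converts a urea absorbance difference through a
single-point urea standard and the 1 U = 1 µmol/min definition, normalized
by reaction time and sample volume; the kit's volume-normalization
constants are parameters with documented defaults, not hard-coded.

Note on single-plate recovery: the refitted standard curve contributes a
shared error (~0.6 µM at 0.005 AU noise) to every well on a plate, so
recovery is unbiased *across* plates, not within one; the tests average
over 40 simulated plates.

## Statistics

ANOVA is computed from explicit between/within sums of squares; the
post-hoc is the classical Bonferroni multiple-comparison test (pairwise t
on the pooled ANOVA mean square with N−k degrees of freedom, adjusted
p = min(1, m·p), stars at 0.05/0.01/0.001), with Welch p-values reported
alongside for transparency. Group statistics operate on experiment-level
means — the experiment, not the cell, is the unit of replication; per-cell
testing would pseudoreplicate. The Shapiro–Wilk test is delegated to
scipy's implementation of the Royston approximation. The population
response profile (percent of treated cells above/below the control mean ±
k·SD band, default k = 2) is this package's explicit rule for
increased/decreased-feature heatmaps; the corresponding rule in the source
material is not published, so no parity is claimed.

## Problem sizes and numerical choices

The simulated study design is 3 independent experiments × 3 wells × 9
fields per condition (~1100 cells/well seeded), the size the assay design
describes; a full three-condition run takes a few minutes on one CPU.
Determinism: every stochastic step draws from `numpy` Generators spawned
from a single `SeedSequence`, so a fixed seed reproduces populations,
images and tables bit-for-bit. Watershed ties are resolved
deterministically by the library's fixed processing order. Degenerate
inputs (constant images, empty populations, vacuole-free cells, single
experiments) return well-defined values or explicit errors, as exercised
by the test suite.

## Known limitations

- The preset calibration tension described above is irreducible given the
  inconsistent anchors; the compromise leaves total vacuole area ~8% below
  and percent-vacuolated ~8% above their anchors by construction.
- Vacuoles below ~1.5 px radius (≈0.7 µm²) are neither generated in
  meaningful numbers nor reliably detectable at the default pixel size.
- Segmentation parity is with the stated operator definitions
  (nucleus-seeded cells, negative-stain vacuoles), not with any commercial
  implementation of them.
- The response-profile band rule and the cytometry quantile gate are
  documented substitutes for unpublished rules.
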