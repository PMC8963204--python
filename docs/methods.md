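# Methods

## The measurement

All quantification is per islet and area-based.  Within one islet ROI
and for one ordered marker pair (A, B):

* **background area** — pixels below threshold in both A and B;
* **foreground area** — ROI area − background area (signal in at least
  one of the two channels);
* **colocalization area** — pixels at/above threshold in both;
* **colocalization rate** — `100 · coloc / foreground`, in percent.

This is a Manders-style binary area overlap, not an intensity
correlation: the quantity of interest is *how much of the fluorescent
area is doubly positive*, which is robust to per-channel gain and
matches how islet immunofluorescence is normally reported.  Areas are
integer pixel counts; the single division happens last, so the
background + foreground = ROI partition is exact by construction.  An
islet whose pair foreground is empty (e.g. an insulin-deficient islet
with no MDA5 signal, measured against insulin) has an *undefined* rate;
it is flagged and excluded from summaries instead of being coerced to 0,
which would bias IDI-containing groups downward.

Two readings of the foreground are defensible: per-pair (union of the
two channels, the default) or a single reference channel.  The per-pair
union is used because the rate itself is defined per pair; the
segmentation module accepts any ROI mask, so a reference-channel
workflow can be composed if preferred.  To keep the vocabulary
unambiguous: the colocalization area is an area (a pixel count), and
the rate is the only ratio in the definition.

## ROI segmentation

An islet is a connected region of chromogranin-A (CHGA, pan-endocrine)
signal.  The CHGA channel is thresholded; the binary foreground is
morphologically closed (disk radius 3 px) **only to decide
connectivity** — each ROI's pixel mask is the raw CHGA foreground inside
its closed component.  This matters for validation: ground-truth ROI
labels are the pre-blur cell footprints, which have sub-cell-diameter
gaps between packed cells, and restricting ROIs to true foreground
makes noiseless segmentation exactly reproduce the truth (per-islet
IoU = 1).  Components smaller than `min_islet_area` (default three cell
footprints, 207 px at the default 5 px cell radius) are scattered
single endocrine cells, not islets, and are excluded from islet
statistics.  Connectivity is 8-neighbor; labels are ordered by
descending area with centroid tie-breaks; coordinates are 0-based
row-major.

**Thresholds.**  Default is Otsu's method per channel on the full
frame.  Two deliberate details:

* *Plateau-midpoint tie-breaking.*  When the histogram has an empty gap
  between background and signal modes (exactly the noise-free case),
  Otsu's between-class variance is flat across the gap and the
  conventional argmax collapses to the lowest bin.  The implementation
  takes the midpoint of the optimal plateau, which places the threshold
  centrally between the modes and makes noiseless thresholding exact.
* *Global, not per-ROI.*  Per-ROI Otsu on a marker-negative islet's
  bounding box would split the noise distribution and declare half the
  ROI positive.  With a tight background mode and well-separated signal
  (true for the phantoms and for reasonably exposed IF images), global
  Otsu is stable even when a channel's positive fraction is ~1%.

Quantile and fixed thresholding are provided for sensitivity analysis
(`isletcoloc sweep` sweeps classifier cutoffs; threshold method is a
config field).  A constant channel raises an explicit degenerate-input
error under Otsu.

## Five-way classification

Each detected structure receives exactly one category.  With
per-channel positive-area fractions of the ROI:

* insulin status: ICI iff INS fraction ≥ `ins_min_frac` (default 0.01);
* MDA5 status: positive iff MDA5 fraction ≥ `mda5_min_frac` (0.01);
* hormone-negative islet-like cluster iff CHGA ≥ `chga_min_frac` (0.5),
  MDA5-positive, and INS, GCG, SST each < `hormone_max_frac` (0.01).

No published numeric cutoffs exist for these calls; the defaults are
explicit, configurable, and sweepable.  They are deliberately
permissive (1% of ROI area ≈ a fraction of one cell at typical islet
sizes) because the biology is cell-wise: a single positive cell should
make an islet positive.  Cluster candidates additionally pass a size
gate — estimated cell count (ROI area / default cell footprint,
rounded) must be ≥ `min_cluster_cells` (5) — dropping speckle that
happens to phenotype like a cluster.  δ-cells (SST) are rendered and
thresholded but enter the scheme only through the cluster
hormone-negativity test.

Hormone-negative clusters are *not* islets: they are tabulated in the
distribution table but excluded from rate contrasts.

## Statistics

Rates are summarized as median with IQR (quartiles by the inclusive
linear-interpolation convention, i.e. `numpy.percentile` defaults) plus
mean/SD.  Two-sample contrasts use the two-sided Mann–Whitney U test:
an exact permutation null (full enumeration of label assignments, ties
handled by the ½-count convention) when both samples have ≤ 8
observations, otherwise the tie-corrected normal approximation with
continuity correction.  Multi-group comparisons use the tie-corrected
Kruskal–Wallis H followed by Dunn pairwise z-tests with Holm adjustment
(Bonferroni optional); the Dunn test is implemented in-package and the
Holm step uses statsmodels.  Vendor statistics packages often label this
whole nonparametric workflow loosely (sometimes even as an "ANOVA");
what is implemented here is the standard reading: a Kruskal–Wallis
omnibus followed by Dunn's pairwise rank tests.

Islets are treated as independent observations, as per-islet dot plots
do.  This understates donor-level correlation in real cohorts; a
donor-level clustered bootstrap (`stats.clustered_bootstrap_p`) is
provided as a robustness check but is not the default.

## The synthetic tissue generator

**Geometry.**  Cells are non-overlapping disks (default radius 5 px at
0.5 µm/px, i.e. 5 µm cell radius).  An islet is 8–40 cells placed by
sequential attachment (each new cell 2–2.5 radii from an existing one),
giving a compact connected cluster; hormone-negative clusters are 5–15
cells.  Islets are placed by rejection sampling, largest first, with a
12 px separation margin; an unplaceable layout raises a capacity error.
Scattered single CHGA+/mostly-GCG+/often-MDA5+ cells and plain exocrine
(DAPI-only) cells fill the parenchyma.

**Composition.**  ICI islets draw cell types at (β 0.55, α 0.35, δ 0.08,
other 0.02) with at least one β and one α guaranteed; IDI islets at
(α 0.75, δ 0.20, other 0.05) with no β; clusters are entirely
other-endocrine, all MDA5-positive, INS=GCG=SST=0, CHGA+.

**MDA5 calibration.**  Cohort presets store (mean, sd) of a truncated
normal on [0, 1] for the per-islet MDA5–glucagon and MDA5–insulin
*measured rates* — the scale on which cohort results are reported
(ND 20.5 ± 12.5 / 14.4 ± 10.6; T1D-RO 28.5 ± 17 / 20.6 ± 13.5; T1D-LS
26.1 ± 17.1 / 11.9 ± 10.8, percent).  For each islet the generator draws
target rates (r_a, r_b) and inverts the pair-foreground relation

```
r_a = x / (A_α + y),   r_b = y / (A_β + x)
```

(x, y = MDA5-positive α/β area) — linear in (x, y) — for the
per-cell-type positive fractions, then marks `round(f · n)` cells of
each type positive.  Two consequences are intentional: the simulated
rate distribution carries the published mean *and* sd (an extra
Bernoulli thinning per cell would roughly double the islet-level sd at
5–15 cells per type and mis-calibrate the spread), and islet-level
MDA5-negative islets arise naturally from the low tail once rounding
yields zero positive cells — a minor proportion, as observed in T1D
tissue.  An explicit `mda5_neg_islet_fraction` knob (default 0) can
force more all-negative islets for classification stress tests.
Category-level draws (cluster, IDI) are Bernoulli per structure.
Cluster fraction defaults to 0.10 in the recent-onset preset
(observed range 3.2–15.9% across donors); ND and AAB_POS presets have
no IDIs and no clusters by contract.  MDA5 is confined to endocrine
cells; in non-cluster islets only α- and β-cells can be positive;
cluster cells render MDA5 brighter (0.75–0.95 vs 0.6–0.9 relative
intensity) than α/β cells.

**Rendering.**  Marker levels are drawn per cell from U(0.6, 0.9);
channels are rasterized as filled disks, blurred with a Gaussian PSF
(σ = 1 px), offset by a constant background (0.05), degraded with
additive Gaussian noise (σ = 0.02) in a jitted single-pass kernel, and
quantized to uint16.  Defaults keep the background far below the
dimmest marker so thresholding is well-posed — the point of the phantom
is a correct oracle, not photon physics.  Ground truth (ROI labels,
categories, MDA5-within-GCG/INS area fractions) is computed from
pre-blur footprints and pre-noise masks, so degradation affects
intensities only, never the truth.

**Determinism.**  One master seed; per-islet, layout, scatter, and
noise streams are split via `numpy.random.SeedSequence`, so identical
(preset, shape, seed) reproduce bit-identical images and tables.

**What the phantom does not emulate** — and hence what passing tests do
not show about real tissue: graded per-cell expression (positivity is
binary per cell), cell shape and crowding (disks, no overlap), optical
realism (no depth, shading, bleed-through, or autofluorescence),
staining artifacts, immune infiltrate, and donor-level random effects
(islets are i.i.d. given the preset).  Validation on phantoms
demonstrates that the *pipeline arithmetic and decision logic* are
correct and well-calibrated, not that any specific biological claim
transfers.

## Validation design and problem sizes

The test suite validates: exact agreement of the rate computation with
a brute-force per-pixel counter on 1000 random 64×64 mask pairs; the
exact ROI partition across simulated cohorts; recovery of constructed
MDA5⊂GCG fractions f ∈ {0.1, 0.25, 0.5, 0.75, 1.0} to within one
percentage point noiselessly and monotonically under default noise;
segmentation IoU = 1 noiseless and mean IoU ≥ 0.9 under noise;
five-way classification accuracy of 100% noiseless and ≥ 95% under
noise over ten seeds (60-structure mixed phantoms); preset contracts
(ND cohorts yield no IDI and no cluster records; a 0.10 cluster
fraction is recovered within the exact binomial 95% CI at 200
structures); exact Mann–Whitney agreement with full enumeration for all
group sizes ≤ 8 and the closed-form Kruskal–Wallis H = 7.2 on ranks
1..9; and byte-identical reruns.

Pipeline-level calibration runs 200 null replicates (two cohorts from
the identical preset, 30 islets/group; rejection frequency must lie in
[0.02, 0.09] at α = 0.05) and 200 power replicates (ND vs T1D_RO preset
means 20.5 vs 28.5, 100 islets/group; rejection frequency ≥ 0.9).
These replicates run at a coarser raster — cell radius 3 px at
0.83 µm/px, the same 8–9 µm biology — which is the package's chosen
simulation scale for replicate-heavy experiments; area-fraction
statistics are scale-free to first order, and the coarser raster only
slightly increases edge-digitization jitter.

## Known limitations

* The ICI/IDI and MDA5-positivity cutoffs are area-fraction heuristics;
  on real tissue they should be checked with the sweep mode.
* Global Otsu assumes a dominant, tight background mode; heavily
  vignetted or low-contrast slides would need the quantile or fixed
  modes (or per-tile thresholds, not implemented).
* Undefined-rate exclusion means MDA5–INS comparisons in IDI-rich
  groups rest on few islets; the report tables carry n per cell so this
  is visible.
* The donor-level clustered bootstrap is a check, not a substitute for
  mixed-effects modeling, which is out of scope.
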