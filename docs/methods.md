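# Methods

`cardioquant` re-implements, as a tested library, the quantification
machinery used in comparative cardiac-injury studies of the spiny mouse
(*Acomys cahirinus*) and the laboratory mouse (C57BL/6) after ligation of
the left anterior descending coronary artery: ECG QRS metrics,
echocardiographic output formulas, histological scar and fiber
morphometry, fluorescence cell-counting recipes, and transcriptomic
maturation scoring. Every stage is paired with a seeded synthetic-data
generator that carries exact ground truth, so the whole pipeline is
testable without any imaging or sequencing data.

## ECG QRS quantification (`cardioquant.ecg`)

Per beat, the Q (negative), R (positive) and S (negative) deflections are
measured as signed amplitudes relative to the isoelectric baseline and as
onset-to-offset durations. The baseline is the median of the trace: QRS
complexes occupy a small fraction of the murine cardiac cycle, making the
median a robust isoelectric estimate that is exactly equivariant under
voltage offsets. Onset and offset of a wave are the outermost samples at
which the waveform still reaches 5% of that wave's peak amplitude above
baseline (`onset_fraction`, default 0.05); the crossing is snapped to the
suprathreshold sample nearer the peak.

R detection is a derivative-energy detector in the Pan–Tompkins
tradition, exposed as a replaceable strategy in `QRSDetectionParams`:

* detrend by subtracting a running median (window 200 ms, default) —
  this absorbs respiratory-scale baseline wander;
* Gaussian-derivative filtering at 1 ms scale (matched to murine QRS
  deflections of a few milliseconds), squared, integrated over 6 ms;
* adaptive threshold at 0.30 x the 99.9th percentile of the integrated
  energy, peak picking with a 40 ms refractory period, then refinement of
  each energy peak to the local voltage maximum.

Q and S are the most negative extrema in ±50 ms windows around R. Beats
whose windows cross the trace boundary are skipped with a warning.

The synthetic generator renders each wave as a Gaussian (closed-form
amplitude/width truth), snaps wave centers to the sample grid so the true
peak value equals the specified amplitude exactly, and computes truth
onsets/offsets on the clean composite trace with the *same* 5% criterion
the analysis uses — at murine widths the Q/R/S tails overlap enough to
shift the 5% crossing by a sample, so per-wave analytic bounds would
disagree with any consistent measurement. Noise is additive white
Gaussian; `snr_db` specifies the conventional power signal-to-noise ratio
against the clean-trace RMS. Defaults (1 kHz sampling, 480 bpm, 1 mV R,
−0.2/−0.3 mV Q/S, 10 ms QRS footprint) reflect murine ECG.

## Echocardiographic output (`cardioquant.echo`)

FS(%) = (LVID;d − LVID;s)/LVID;d × 100 and
EF(%) = (LVID;d³ − LVID;s³)/LVID;d³ × 100 from M-mode internal
diameters. Replicates (five by convention) are averaged parameter-wise
*before* the formulas are applied; the alternative order changes results
for heterogeneous replicates and is deliberately not offered.
LVID;s > LVID;d (possible in dyskinesia) yields negative values plus a
quality flag rather than an error.

## Raster primitives (`cardioquant.imageops`)

All color gates use the 8-bit HSB convention (hue, saturation,
brightness each 0–255, inclusive bounds), matching how such gates are
reported for ImageJ's color thresholder; hue wraps circularly only when
`hue_min > hue_max`. Area = pixel count × pixel_size².

Automatic thresholds are computed directly on the 256-bin histogram so
each method realizes its published criterion exactly (the test suite
checks all four against exhaustive 256-candidate searches):

* `default_isodata` — iterative intermeans (the historical meaning of
  ImageJ's "Default");
* `yen` — maximum-correlation criterion;
* `triangle` — maximal distance between histogram and the peak-to-tail
  line, on the longer tail side;
* `moments` — Tsai's moment-preserving p0-tile (absent from
  scikit-image, hence implemented here).

Foreground is the bright side (`value > t`) unless requested otherwise.
Note that on sharply bimodal histograms Yen/triangle/moments typically
sit near the *base* of one mode rather than midway between modes; they
still separate the populations, but mask boundaries on smooth-edged
objects land near that mode's intensity level (see heart size below).

Rolling-ball background subtraction uses `skimage.restoration.
rolling_ball` (a true ball): smooth backgrounds, including structures
wider than the ball in both directions, are flattened; structures
narrower than the ball diameter in at least one direction are preserved.
The radius is in pixels ("size" in the recipes). The unsharp mask is
`(image − w·G_r(image))/(1 − w)` in float without clipping, so the
closed-form composition holds; despeckle is a radius-1 median.

Skeleton topology uses 8-connectivity: a junction is a skeleton pixel
with ≥3 skeleton neighbors (adjacent junction pixels merge into one
junction); branches are the connected components of the skeleton after
junction removal.

## Scar morphometry (`cardioquant.scar`)

Scar fraction per trichrome section: scar gate H 140–200 / S 10–255 /
B 0–255 versus whole-tissue gate H 60–255; fraction = scar px / tissue
px. Stacks of serial levels (six from ligation point to apex by
convention) are averaged unweighted; a tissue-area-weighted mean is
available behind a flag since the unweighted choice is a convention, not
a law.

Heart size: green channel → Gaussian blur (σ, default 50 px) → triangle
threshold (dark foreground: stained tissue absorbs green on a bright
background) → particle analysis excluding border-touching components and
filling holes → largest component area. Because the triangle threshold
sits near the background peak, the measured boundary lies one to three
blur widths outside the half-height contour; the blur must therefore be
small relative to the section radius for unbiased areas. The recipe's
σ = 50 presumes sections thousands of pixels across; the test suite
demonstrates the ≤2% contract with σ small relative to a synthetic disk.

Wall thickness: five rays from the tissue centroid at equally spaced
angles *within* the scar's angular extent (wraparound-aware; interior
placement so every ray crosses scar territory); thickness is the summed
tissue intersection along the ray, sampled at 0.25 px.

Dye-perfusion (Evans-blue-style) infarct area replaces manual tracing
with two explicit hue gates (perfused/dye H 140–200; dye-excluded
H 201–255), both overridable; ischemic fraction = excluded/(excluded +
perfused), averaged over a four-level stack.

Birefringence hue profiles: after subtracting a scalar background value,
ROI pixels are binned by the four classic picrosirius gates (red 1–13,
orange 14–25, yellow 26–52, green 53–110; S 10–255, B 20–255). Bins are
inclusive; hue 0 and hue >110 carry no birefringent signal and are
excluded from the total, which is normalized to 100%.

## Fiber architecture (`cardioquant.fibers`)

Waviness W = polyline arc length / endpoint chord length (≥1, =1 iff
straight). Batch statistics are per-frame means then the grand mean;
frames with fewer than 10 fibers or batches with fewer than 6 frames
warn but are retained.

Anisotropy: Scharr-filtered intensity gradients (chosen for their
near-optimal rotational invariance; plain central differences bias the
orientation by >1° on period-8 patterns) are accumulated over the ROI
into a 2×2 structure tensor; score = (λ₁−λ₂)/(λ₁+λ₂), orientation = the
dominant fiber axis (perpendicular to the dominant gradient) in [0,180)
counterclockwise.

Box counting: box sizes default to powers of 2 from 2 px to 45% of the
shorter side; each size is scanned with `grid_offsets` grid origins (the
anchored grid plus diagonally slipped ones). The dimension fit uses the
*tightened* count per size — the minimum over origins, i.e. the best
covering found. This is the deliberate reading of a slipping+tightening
grid scan: averaging raw slipped-grid counts systematically flattens the
slope (a slipped grid needs ⌈L/ε⌉+1 boxes per axis for a frame-spanning
set, which drags a filled square's D to ≈1.93). Lacunarity
Λ(ε, origin) = (σ/μ)²+1 over occupied-box masses, averaged over sizes
and origins. Scans whose mean sampled density falls below
`min_density` (default 0.40) of the across-scan mean are flagged and
excluded — the density filter is configurable because its exact
upstream semantics are ambiguous.

The fractal preprocessing chain is fixed in order: rolling ball (75) →
unsharp (2, 0.60) → median (1) → isodata threshold (bright foreground)
→ despeckle.

The fiber-field generator renders sinusoidally crimped polylines; the
crimp amplitude is solved by bisection *on the discretized polyline* so
every returned trace has the target waviness to solver precision.
Orientations follow an axial von Mises law (κ=0 uniform on [0,π)).
Straight targets (W=1) are rendered as two-vertex segments so W is
exactly 1 without accumulated rounding.

## Cell counting recipes (`cardioquant.cells`)

Recipes mirror declarative ImageJ macros and record their parameters in
result provenance:

* nuclei: rolling-ball(50) → median(1) → threshold (isodata for
  Hoechst, Yen for EdU) → particles, edges excluded, holes included;
* scar ROI from WGA: rolling-ball(50) → median(20) → Yen;
* marker positivity: a nucleus is positive iff its component overlaps
  the thresholded marker mask by ≥1 px; only nuclei whose centroid lies
  in the ROI count;
* dividing cardiomyocytes: MLC-2v segment (rolling-ball 50, median 1,
  isodata) minus the capillary segment (isolectin B4: rolling-ball 5,
  median 20, isodata); positives must overlap the marker and not the
  capillary mask;
* arteries: α-SMA components inside the WGA scar ROI, filtered to
  ring/tube shapes (solidity ≤ 0.85 or elongation ≥ 2.5, both
  configurable), measured by maximum Feret diameter and gated at
  ≥10 µm to exclude α-SMA+ mesenchyme; density is per scar mm²;
* coverage (PDGFRβ, isolectin): rolling-ball(50) → threshold (moments)
  → stained area / ROI area;
* cardiomyocyte surface area = width × length (µm²).

Blank (constant) channels count as zero nuclei / zero coverage; a blank
WGA channel is an error because no ROI can be derived.

The multichannel generator's geometry is co-designed with the recipes'
filter chains so noiseless truth is recovered exactly: stain *regions*
are solid bands narrower than the rolling ball (≤95 px for radius 50),
the cardiomyocyte region is a dense tube pack (width 8, gap 2) that
passes the radius-50 ball, and the capillary region is a coarser pack
(width 8, gap 7) whose elements pass the radius-5 ball while the pack is
locally dense enough for the radius-20 median to close it into a solid
strip. Capillary nuclei stay ≥24 px from the image border, where the
wide median shrinks its mask. Real tissue differs in texture, staining
gradients and nucleus overlap, so exact-recovery results certify the
recipe logic (segmentation order, exclusion masking, gates), not
robustness to histological variability.

## Maturation transcriptomics (`cardioquant.transcriptomics`)

All computations run on the log2(x+1) scale (the transform is a
package choice; FPKM inputs are kept raw on disk). Variable genes:
log-scale variance > 0.5 and expression > 1 FPKM in more than two
samples. PCA runs on the gene-centered matrix; loadings are gene-side
singular vectors scaled by their singular value and normalized to unit
maximum per component, so the 0.2 threshold acts on a comparable scale
across components; per PC the threshold-passing genes are ranked by
|loading| (ties broken by gene ID) and capped at 50; the union of PCs
1–5 is at most 250 genes, and actual counts are reported. The sample
network connects samples whose Pearson correlation over the selected
genes exceeds the threshold (default 0.6; 0.4 is the common
visualization alternative — both are exposed because the two appear in
practice). Layout is seeded Fruchterman–Reingold. The cumulative
category score is the per-sample sum of per-gene z-scores over a named
set (raw sums would let highly expressed genes swamp the set; z-scores
weight genes equally); constant genes are dropped with a warning.
Maturation ratios are Tnni3/Tnni1 and Myl2/Myl7 per sample, linear and
log2, NaN-flagged on zero denominators.

The expression generator is additive in log2 space: per-gene baseline
U(2,8), per-species offsets N(0, sd) on a subset of "species genes"
(optionally bounded away from zero via `species_effect_min`, emulating
genuinely divergent genes), adult-vs-neonate log2 fold-changes on named
maturation sets per species, and Gaussian sample noise. It does not
emulate count overdispersion, library-size variation, or correlated
gene modules beyond the planted blocks; conclusions about those require
real data.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale problems chosen
to keep the full run in a few minutes on one CPU: 512-px section and
pattern rasters (the Sierpinski oracle at depth 7 on a 128 grid),
384–512-px multichannel frames with 100–150 nuclei, 60 s ECG at 1 kHz
and 480 bpm, and 16-sample expression matrices with 400–2000 genes —
the group design (2 species × 2 ages × 4 replicates) mirrors the bulk
ventricle design. Degenerate inputs raise informative errors (constant
histograms, empty masks/ROIs, coincident fiber endpoints,
rank-deficient PCA inputs); warnings, not errors, cover recoverable
protocol deviations (wrong stack depth, sparse fiber frames, boundary
beats). Random draws always flow from explicit integer seeds via
`numpy.random.default_rng`; equal seeds give bit-identical outputs.

## Known limitations

* The R-peak detector is not a reimplementation of any specific
  published murine algorithm; it is a documented, replaceable strategy.
* Rolling-ball behavior follows scikit-image's true-ball kernel; ImageJ
  variants (paraboloid, shrink factors) can differ near wide, tall
  structures.
* Heart-size areas carry a threshold-halo bias of order the blur width
  (see above).
* Hue-binned birefringence assumes the polarized-light background is
  removable by a scalar subtraction.
* FracLac-style density filtering is implemented as a per-scan outlier
  filter; other readings of that filter exist and the parameter is
  exposed.
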