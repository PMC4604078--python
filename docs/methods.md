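# Methods

`dystromorph` re-implements, as one tested pipeline, the quantitative
measurement procedures used in preclinical Duchenne muscular dystrophy (DMD
/ *mdx* mouse) studies: muscle-fiber morphometry from immunofluorescence
sections, immunopositive-cell and area-fraction quantification, micro-CT
trabecular bone morphometry, qPCR/RNA-Seq expression summarization, scalar
assay metrics, and the group-comparison decision procedure that produces
the study's p values. Because the micrographs, CT volumes and qPCR plates
of any given study are rarely redistributable, each stage is paired with a
seeded synthetic generator whose ground truth is exact by construction, so
the whole pipeline is verifiable on any machine.

## Fiber morphometry

The membrane (collagen-IV) channel is processed the way the classic ImageJ
macro does: white-tophat background subtraction (rolling-ball analogue,
default radius 15 px), a band-pass threshold (defaulting to Otsu on the
background-subtracted channel, because published macros carry image-specific
thresholds that do not transfer), dilation with a disk of radius 2 px to
bridge staining gaps, and skeletonization into a 1-px border mask. Enclosed
regions are labeled 4-connected; regions outside a 50–10,000 µm² area window
(configurable) are discarded as non-fiber particles, and regions touching
the image edge are censored — their geometry is incomplete — with removal
counts logged.

The minimum Feret diameter is the smallest caliper (projection) width over
all orientations, the standard section-angle-robust fiber-size metric. It
is computed exactly by rotating calipers on the convex hull: the minimum
width of a convex polygon is attained with one jaw flush against a hull
edge, so the answer is the minimum over hull edges of the farthest
vertex-to-edge distance. Pixels are treated as unit squares (each pixel
contributes its four corners to the hull), so a region 30 px across
measures exactly 30 px. The independent check is a dense rotation sweep of
projection widths with golden-section refinement around the grid minimum;
the refinement is needed because the width function has a V-shaped minimum
at the optimal orientation and a bare grid converges only linearly in the
step.

A fiber is centrally nucleated (C/N) when at least one nucleus object
(threshold-then-label of the nuclei channel) has its centroid at depth
≥ `central_margin_fraction` × equivalent-circle radius inside the fiber
(default 0.1; the value is echoed in the summary output so its influence is
auditable). C/N fraction, per-class mean minimum Feret, fiber density per
mm² and a binned Feret histogram form the summary.

## Synthetic fiber fields

Fields are jittered-grid Voronoi tessellations: fibers are convex-ish cells
that tile the plane, with a sacrificial ring of cells absorbing the image
boundary so the `n_fibers` truth-bearing cells are never edge-censored. Cell
polygons are known exactly; truth areas come from the shoelace formula and
truth Feret diameters from the calipers kernel, cross-checked against the
rotation-sweep oracle at generation time. Planted central nuclei sit at
least 25 % of the equivalent radius from the border (falling back to the
polygon's pole of inaccessibility when the centroid is too shallow);
peripheral nuclei have centroids within ~1 px of the border. The gap
between the two keeps truth labels far from the classifier's 10 % margin.
Membrane borders are drawn ~3 px wide, blurred (σ = 1 px) and corrupted
with Gaussian noise (σ = 4 counts by default). The generator emulates
geometry and photometric noise only — no staining variability, montage
seams, or out-of-focus blur — so passing recovery tests demonstrates the
correctness of the measurement chain, not robustness to pathological image
quality.

## Region quantification

Cell counting is threshold → 8-connected labeling → object-size window
(default 20–500 µm²) → count per mm², with five-field-of-view averaging as
an arithmetic mean of densities. Area fractions are percent of tissue
area, either from a threshold or from replayed manual ROI polygons (CSV
vertex lists), supporting historical manually-delineated IgG workflows.
Trichrome (collagen) positivity uses a blue-dominance rule, B > R + 20 and
B > G + 20 on 8-bit channels, over non-near-white tissue pixels
(luminance < 235 excludes slide background). Revertant (dystrophin-positive)
fibers are counted as 8-connected components per mm²; a cluster of touching
positive fibers therefore counts once, a deliberate and documented
convention since published cluster handling is ambiguous. The
area-fraction generator paints positive patches and then individual pixels
until the painted count equals `round(fraction × n_pixels)` exactly, so
recovery tolerances test the classifier, not the fixture.

## Bone morphometry

Segmentation is seeded region growing with criterion |voxel − region mean|
≤ tolerance under 6-connectivity. Growth proceeds in whole-frontier
sweeps — every admissible unvisited neighbour joins at once and the mean is
updated — which is deterministic, invariant to the choice of seed within a
connected component, and fast enough for full-resolution volumes where
single-voxel FIFO growth is not. Two guards reject degenerate runs: region
overflow beyond half the volume (tolerance spanning background), and a
grown region darker than the volume's Otsu foreground class (seed planted
in background).

BV/TV is the bone-voxel fraction of the slice-range ROI. Tb.Th is
Hildebrand-style local thickness: the volume-weighted mean diameter of
maximal inscribed spheres, computed from the Euclidean distance transform
by a descending radius ladder (half-voxel quantization; a voxel at EDT
value r carries a ball covering voxels strictly closer than r, diameter
2r − 1 voxel pitches). The convention is exact for odd plate/rod widths
and at most one voxel low for even ones. The mask is padded with
background first, so structures cut by the volume boundary are measured at
the cut face instead of being inflated. The ladder stops once under 0.1 %
of voxels remain unassigned, which bounds the error on the mean by roughly
0.1 % and keeps a 250×256×256 volume under ~1.5 min on one core. Tb.Sp is
the same measure on the complement within the ROI. Tb.N uses the plate
model, BV/TV / Tb.Th per mm; the plate-model thickness
(BV/TV / (1 − BV/TV) × Tb.Sp) is reported alongside the sphere-fitting
value because both conventions are common in scanner software and
published methods rarely say which was used.

Phantoms: parallel plates (BV/TV = t/(t+s) exactly; axis-0 extent must
hold whole periods), rods on a square lattice, spheres on a cubic lattice;
truth for rods/spheres is the realized voxel fraction. Voxels are sharp
(foreground 200, background 50) plus optional Gaussian noise — no partial
volume effect, which real scans have.

## Expression

geNorm stability: with expression ∝ 2^−Ct, the log₂ ratio of genes j,k in
a sample is Ct_k − Ct_j; M(j) is the mean over other candidates of the SD
across samples of that ratio, and the ranking comes from iteratively
excluding the highest-M gene until two remain (which is why ≥ 3 candidates
are required). M is invariant to per-gene constant Ct offsets.

2^−ΔΔCt: ΔCt = Ct_target − mean(Ct of references) per sample; ΔΔCt =
group mean ΔCt − calibrator mean ΔCt; fold = 2^−ΔΔCt, so the calibrator
group is 1 by construction and a whole-sample Ct offset cancels. The
group-level convention is the mean of per-sample ΔCt; averaging per-sample
folds instead is available behind `per_sample_folds` because both exist in
the wild and they differ under noise (Jensen's inequality).

Heatmap stage: rows with missing values are removed, FPKM is transformed
as log₂(x + 1) (base and pseudocount configurable; sources that say only
"log-transformed" leave this open), rows are z-scored with sample SD
(ddof = 1, zero-variance rows dropped), and clustering is Ward on
Euclidean distance — the Ward.D2 variant, i.e. squared distances inside
the criterion, matching `scipy.cluster.hierarchy.linkage(method="ward")`.
The test oracle is an independent O(n³) Lance–Williams agglomeration.
Dendrograms serialize to Newick with merge heights as branch lengths.

## Assay metrics

Discrimination index = 100 × novel / (novel + familiar); 50 is chance.
Grip strength is the mean of the two trial maxima (trial count
configurable, enforced). Twitch/tetanic specific force is the tallest
baseline-corrected peak across each stimulus kind's repeated traces,
divided by muscle wet weight (N/g); the baseline is the median of the
pre-stimulus window (default first 50 ms), and a stimulus kind with no
traces is reported absent rather than zero. Wheel distance and rotarod
latency are externally measured scalars and are ingested, not recomputed.

## Statistics

Two groups: unpaired pooled-variance t test. Three or more: one-way ANOVA
with Tukey HSD (Tukey–Kramer SE for unbalanced groups, studentized-range
distribution). When ANOVA is significant at α = 0.05, the pipeline runs an
Anderson–Darling normality check on pooled residuals (case 3, mean and
variance estimated: A² with the (1 + 0.75/n + 2.25/n²) correction and the
standard piecewise-exponential p bands; skipped with a logged note below
n = 8) and a raw-label permutation ANOVA with p = (1 + #{F* ≥ F})/(B + 1),
B = 9,999 by default with a mandatory seed. The parametric p remains
primary; the companions are reported alongside and the ordered decision
path is recorded. Variables flagged non-normal up front route to
Mann–Whitney U / Kruskal–Wallis H instead.

Mann–Whitney reports W as the rank sum of the first sample — the only
convention under which published W values with unequal n reproduce — with
exact enumeration when n₁+n₂ ≤ 12 and no ties, else a tie-corrected normal
approximation with continuity correction on by default (toggleable, since
the originating software's convention is usually unstated). Kruskal–Wallis
uses tie-corrected H with the χ² tail on k − 1 df; for df = 2 the closed
form exp(−H/2) is a test invariant. Star annotations follow the
{0.05, 0.005, 0.001} scheme (note the unusual middle threshold of 0.005
rather than 0.01); the thresholds are configurable.

No multiplicity correction is applied across separate per-gene tests;
panels in this literature are reported per-gene without a stated
panel-wide correction, and the pipeline reproduces that convention as-is.

## Problem sizes and calibration checks

The validation suite uses: 200 random convex polygons (4–30 vertices)
against the 0.05°-sweep Feret oracle; a 100-fiber 512² field with 30 %
planted central nucleation (recovery tolerances: count ±2 %, %C/N ±3
points, per-fiber Feret within border width + 2 px for ≥ 95 % of fibers);
a 250×256×256 plate phantom at 8 µm/voxel, t = 40 µm, s = 160 µm (BV/TV
±0.01, Tb.Th/Tb.Sp ±2 voxel pitches); area-fraction fixtures at ±1
percentage point; 10⁴ three-group normal-null replicates for the decision
pipeline's type-I error (accepted band 0.04–0.06; the permutation stage
runs at B = 199 there because B does not affect the primary rejection
decision); and Ct/FPKM fixtures with planted unstable references and a
planted two-cluster sample split. `scripts/acceptance.py` recomputes all
of these from scratch from a single seed.

## Known limitations

* Measurements are 2-D (sections) and 3-D (volumes) as stated; no montage
  stitching, stain deconvolution, fiber typing, or cortical-bone geometry.
* The local-thickness convention is one voxel low for even-width
  structures; at realistic pitches this is well inside reported
  uncertainty, but comparisons across software should use one convention.
* The synthetic generators produce convex-ish fibers and ideal geometric
  phantoms; real dystrophic sections contain concave, split and necrotic
  fibers that the recovery tests do not exercise.
* Exact Mann–Whitney p values are enumeration-based only for n₁+n₂ ≤ 12
  without ties; ties always use the asymptotic path.
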