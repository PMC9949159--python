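# Methods

This note documents the models and numerical choices behind `axonmap`, the
defaults that matter, what the synthetic data generator does and does not
emulate, and the package's known limitations.

## Coordinate conventions

All physical positions are in μm in a right-handed frame: x mediolateral
(midline at `SimConfig.midline_x`, ipsilateral = larger x), y dorsoventral
(increasing ventrally), z anteroposterior. Tissue is sectioned along z at
`section_thickness` (default 20 μm); section indices are explicit
everywhere. Pixel coordinates are 0-based with subpixel fractions, at
`pixel_size` = 0.55 μm/pixel. Dot tables carry pixel coordinates in the
section frame; cell records carry μm.

## Spot detection

Rolonies are 3–7 px blobs whose z-profile is continuous, while fixed-pattern
noise is not. The floor-subtracted projection (per pixel: max over z minus
the 3rd-lowest plane, clipped at 0) exploits this to remove background
without flattening blob peaks; it needs ≥ 3 z-planes by construction.

Channel intensities are standardized by the mean/SD of local-maxima samples
(z-scores), which removes channel- and batch-scale differences. When a
channel yields fewer than `min_maxima_for_correction` (50) maxima, or the
sample is degenerate (zero SD, as in noiseless renders), the correction
falls back to identity with a warning and thresholds operate on raw
intensities. Optional bleed-through unmixing estimates a 4×4 mixing matrix
from maxima whose off-channel ratio is below a purity threshold (0.5) and
inverts it before standardization.

A local maximum (circular 5-px suppression footprint, ties broken by (y, x)
order) becomes a dot only if (1) its brightest z-plane neighbours the 2nd
or 3rd brightest (`neighbor_mode="both"` requires both), (2) its channel is
the brightest of the four both before and after correction, (3) the
channel-purity ratio 2nd-max/max is strictly below 0.95, and (4) the
corrected intensity passes the threshold. The default threshold is −3.0:
after z-scoring, genuine maxima sit near N(0, 1), so the gate excludes
implausibly dim peaks three SDs below the typical maximum rather than
demanding three SDs above it. Subpixel positions come from independent
per-axis parabolic interpolation of the 3×3 neighbourhood, clipped to
±0.5 px.

## Registration

Alignment is strictly linear (translation/affine/projective). Point clouds
are rasterized at 1 px bins and coarsely aligned by the normalized
cross-power spectrum with parabolic subpixel peak refinement; for point
input, confidence is the fraction of dots that land within 2 bins of a
partner after the shift (low confidence below 0.5). Refinement iterates
nearest-neighbour pairing within a 5 px gate and least-squares fitting
until the RMS residual changes by < 0.01 px (max 20 iterations); the
projective model is used only with ≥ 50 supporting pairs, otherwise affine.
Cycles are registered directly to a mid-sequencing reference cycle (tissue
distortion grows with cycle number, so a mid reference halves worst-case
drift); a failing cycle keeps its phase-correlation prealignment, flagged.
Tiles are placed in descending rolony-count order, each refined against the
union of already-placed dots by phase correlation plus a gated mean-offset
polish (3 iterations), which brings duplicate dots in 15%-overlap regions
to well under 1 px. Fitting of non-linear displacement fields is out of
scope; `apply_displacement_field` only applies a user-supplied sampled
field by linear interpolation.

## Base-calling

Dots are matched one-to-one between cycle pairs (t−d, t) for d = 1..3
within a 5 px gate, greedily by ascending distance with deterministic
dot-id tie-breaks. Matches merge in ascending interval order at each cycle
boundary; a skipped cycle inside a bridged interval becomes N. Up to two
consecutive lost cycles are therefore recoverable; three are not, and the
resulting fragments die by the N-run > 3 rule (leading and trailing runs
count). A match that disagrees with an occupied slot duplicates the read's
full prefix (fork); both forks persist until codebook matching condenses
them, and lineages exceeding 4 forks are dropped. The read position is the
reference-cycle dot when present, else the chain centroid.

Perisomatic reads (within 20 μm of ≥ 35 soma pixels in more than 2 cycles)
are excluded — base-calling is unreliable in the dense injection core.
Somata are base-called per pixel; the phasing correction subtracts the
previous cycle's intensity channel-wise (50% for the previously dominant
channel, 100% for the rest, clipped at 0) before taking the argmax; an
all-zero pixel is N.

## Codebook and matching

Candidate barcodes are aggregated by permissive-N-collapsed identity:
distinct read strings are grouped greedily in descending count order; a
group is seeded by the most-supported unmerged string and collects all
unmerged strings compatible with it (zero mismatches with N matching
anything, all positions); the representative is the member with the most
base-called positions (ties: higher count, then lexicographic), and only
members compatible with the representative merge. This matters: a true
barcode whose fully-called form was never read still surfaces as a
candidate with one or two N — which the composition limits explicitly
allow — instead of being impersonated by a substituted variant.

Candidates are accepted greedily by support: support ≥ 3, composition
limits (< 14 identical nucleotides over called positions including the
fixed ones; ≥ 13 of 15 variable positions called; N-run ≤ 3), and no
accepted entry within Hamming distance 1 under the default convention
(N permissive, fixed positions 9–10 excluded). A candidate rejected only
for a 1-Hamming neighbour donates its support to that neighbour
(`absorbed_support`), keeping counts interpretable.

Lookup uses the strict convention with *all* positions included: with m
mismatches at doubly-called positions and k positions where either string
has N (a both-N position counts once), the distance is m if m = 0, else
m + k. Queries match the nearest entry if unique at distance ≤ 2; ties at
the minimum are ambiguous and discarded. Condensation then blanks dots
claimed by more than one matched barcode, re-applies the N-run limit, and
collapses reads whose dot sets have Jaccard ≥ 0.8 to the most-base-called
read (the 0.8 threshold is a package choice; nothing in the source method
pins it).

## QC filters

Applied in order, each stage reporting in/kept/removed so the chain
telescopes: error-prone barcodes (> 6-run homopolymer; > 14 calls in
channel pair G/T or A/C; more 1–2-mismatch than 0-mismatch support);
count gates (some region ≥ 10 rolonies after zeroing counts below the
per-region minimums — 5 for cortex and thalamus, 3 for striatum and
midbrain; axonal total in [3, 1000]; soma counts ≤ 7000); secondary
infection (Hamming ball of radius 4, permissive convention, around
supplied contaminant barcodes); cross-field duplicates (same barcode,
different fields, < 25 μm; connected components over cross-field proximity
edges, lowest-index representative — same-field pairs never merge); soma
identification (section with highest summed soma-pixel intensity,
brightest pixel, valid with ≥ 80 same-barcode counts within 100 μm);
floating rolonies; non-neural cells (< 3 rolonies ≥ 200 μm from the soma
or rolony centroid).

The floating-rolony detector marks as candidates the rolonies with no
tangential neighbour within 140 μm on any section more than 1 away
(floaters are section-local; axons are not). Tangential (in-plane)
distance is used since sections are being compared. A (section, area) pair
qualifies when its candidates form ≥ 3 single-linkage clusters at a 50 μm
cut; evaluation is per scanned area because a bounding box pooled across
areas — or hemispheres — measures nothing. Among qualifying sections the
widest tangential bounding-box diagonal wins. Exclusion then removes
scanned-area rolonies within 2 sections (configurable to 3) of the anchor
(soma section when known, else the flagged section).

## Cortical flatmap

Boundaries are voxels of the outer (layer-1) and inner (layer-6) labels
6-adjacent to the configured outside labels; array edges are cut faces,
not surfaces, and never count as boundary. One column runs from each outer
voxel to its nearest inner voxel; every cortical voxel joins its nearest
column (columns sampled at 5 points for the lookup) and gets depth% from
its scalar projection onto the column, clipped to [0, 100].

The reference plate is the column midpoints (50% depth). Per hemisphere
(processed independently), PCA on the plate defines PC1 = AP and PC2 = ML.
The plate graph connects points within 3 voxel-sizes (Euclidean edge
weights); residual components — column snapping leaves occasional gaps —
are bridged through their closest point pairs so geodesics are defined
everywhere. AP is the signed multi-source geodesic distance to the
median-AP contour band (±0.75 voxel); ML likewise, on a graph whose edge
weights add `ap_penalty` (2.0) × |ΔAP| to honour "minimum AP change along
the plate" (an iso-AP slicing mode is exposed as an alternative). Each
hemisphere's minimum on both axes is shifted to 1. Voxel LUTs are smoothed
with a 3-voxel NaN-aware averaging filter; point conversion extends values
outward by a 50 μm nonzero-average fill before trilinear interpolation,
and extracortical points return NaN.

On the analytic half-cylinder shell (outer radius 1000 μm, inner 500 μm,
length 2000 μm, 25 μm voxels) the median per-voxel depth error is ≈ 1.5
percentage points and the median mid-plate pairwise-distance error ≈ 1.5%
of the true geodesic. Distortion at cut edges and folded regions is not
corrected.

## Cell typing

CF cells have thalamic or midbrain counts at or above the per-region
minimums; remaining cells are ITc with ≥ 5 contralateral-cortex rolonies,
else ITi. ET/CT starts from the y-median split of rolonies inside the
fiber ROI (defaults x 8250–9000, y 3500–5000, z 6750–7500 μm; top = CT),
then alternates (a) each in-scope rolony takes the most frequent label of
its 10 nearest labeled neighbours (3-D Euclidean, self excluded) and
(b) each cell takes the mode of its rolonies, which they inherit, until no
label changes (cap 100 iterations, logged when reached). Scope stays
inside the ROI during iteration. kNN ties keep the previous label, CT when
none — seed-order independent. A final pass labels all thalamic rolonies
from the pool of step-1-labeled cells' thalamic rolonies and takes the
per-cell mode; cells without thalamic rolonies are unassigned.

## Projection statistics

Laminar profiles are 1%-bin depth histograms/CDFs. The permutation KS test
computes max |CDF_A − CDF_B| on the 100-bin grid and a null from 1000
within-cell shuffles of the pooled depths; p is the plain fraction of
shuffled statistics ≥ the observed one (a +1-corrected estimator is
switchable), and patterns differ iff p ≤ 0.05. The shuffle RNG is seeded
per cell for reproducibility. Group fractions of "different" cells carry
percentile-bootstrap 95% CIs (2000 resamples). Cortical preparation drops
rolonies deeper than 95% and inside the injection disk (radius = 95th
percentile of soma distances to the median soma; a mirrored contralateral
control disk is optional).

Focal projection distance: per rolony, the mean of its shortest
⌈0.33 × (n−1)⌉ pairwise ML–AP distances (self excluded); per cell, the
mean over rolonies; cells with < 55 rolonies are excluded, following the
subsampling-error analysis implemented in `subsampling_error_curve`
(100 resamples per size, median relative error). Simulated retrograde
tracing selects IT cells with a known soma and ≥ 10 rolonies within a
300 μm flatmap patch; contralateral specificity requires patch/CtxC
count ratio ≥ 0.75. Reconstruction links each point to its nearest
neighbour, then repeatedly merges the closest cluster pair via their
closest points; no edge exceeds 1000 μm, so distant clusters remain
separate components. Under distinct distances this greedy equals the
Euclidean minimum spanning tree restricted to the cap, which the tests
assert.

Soma depth groups: ≤ 35% upper, (35, 60]% middle, > 60% deep; cells
without a soma are excluded.

## The synthetic data generator

The generator is the package's study-condition definition, not a fixture.
Defaults: 17 cycles, barcode length 17 with positions 9–10 fixed to "GG"
(the design says fixed; the letters are a package constant and
configurable), 0.55 μm pixels, 20 μm sections, class mixture
CT/ET/ITi/ITc = 0.12/0.08/0.45/0.35, 40 rolonies per neuron, 10%/cycle
dropout, 1% substitution per base-call, 0.5 px jitter, 12 floating
rolonies per soma scattered within 800 μm of the soma on the soma section
± 1 (mostly the soma section), and 3 secondary-infection barcodes emitted
as compact glial-like clusters (σ 30 μm) in target regions. Noise rates
are chosen to stress the pipeline; the source experiments do not report
their true rates.

Geometry: somata scatter (σ 200 μm) around an auditory-cortex injection
center, soma depth by class (CT 0.90 ± 0.04, ET 0.60 ± 0.05, IT upper).
Cortical target arbors are compact (tangential σ 120 or 400 μm — focal vs
diffuse cells — and σ 75 μm along the sectioning axis, locus drawn inside
the target area); subcortical arbors are single compact clusters. CT and
ET axons traverse the fiber ROI as two Gaussian fascicles centered at the
ROI's y quarter-points, with the bundle SD set so the ±2σ envelopes
overlap by `fiber_bundle_overlap` (10%) of their extent, and terminate in
dorsally vs ventrally biased thalamic clusters. ITc cells always carry
≥ 5 contralateral rolonies.

What the generator does **not** emulate: realistic axon morphology beyond
class-level statistics (rolonies are point clouds, not fibres), optical
aberrations, tissue distortion fields, chromatic misregistration,
section-to-section registration error, region-assignment error (labels
come from axis-aligned boxes), or density-dependent base-calling failure
outside the perisomatic rule. Passing tests therefore demonstrate the
algorithms' correctness and noise tolerance under the stated statistical
structure — not performance on real images, where registration and
segmentation errors dominate.

## Validation problem sizes

The acceptance script and end-to-end tests use desk-scale versions of the
study conditions: 100 neurons × 30 rolonies for codebook recovery (clean
and noisy), 150 neurons for the floating-rolony detector, 300 neurons
(CT/ET only) for the kNN grouping, 1000 null cells × 1000 shuffles for KS
calibration, 100 cells (n ≤ 200) for the focal-distance oracle, and the
analytic shell above for the flatmap. These sizes give the binomial
margins the checks need while keeping a full run around 15 s.

## Known limitations

- Greedy cycle-pair matching is order-dependent in pathologically dense
  fields; the perisomatic exclusion is the intended guard, and the
  per-pair candidate list is truncated at 8 nearest neighbours.
- Codebook construction is greedy by support; the tests include a
  brute-force oracle at small n, but no global optimality is claimed.
- The flatmap's plate graph bridges disconnected components with straight
  chords; for strongly folded geometries the iso-AP mode or a finer voxel
  grid is preferable.
- `reconstruct` recomputes cluster distances exhaustively (O(n²) per
  merge); adequate for per-cell point counts (tens to hundreds), not for
  whole-dataset pooling.
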