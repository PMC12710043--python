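# Methods

`phyllo3d` measures phyllotaxy — the azimuthal arrangement of successive
leaves around the stem — from calibrated multi-view binary silhouettes of
single sorghum-like shoots, and carries the resulting per-plant deviation
phenotypes through a quantitative-genetics analysis.  This note records the
models, parameter choices, and numerical decisions behind each stage, and
what the synthetic test bed does and does not establish about real data.

## Imaging model

A plant on a turntable photographed by a fixed side camera is equivalent to a
static plant viewed from a ring of azimuths.  The default rig uses five side
views at equidistant turntable angles (0°, 72°, 144°, 216°, 288°) plus one
top-down view.  Views are orthographic by default: at typical
camera-to-plant distances the perspective correction across a juvenile plant
is small, and the orthographic operator makes the carving geometry exactly
analyzable.  A pinhole model (finite camera distance, focal length sized so
the working volume fits the image) is available through
`CameraRig(projection="pinhole")`.

The world volume is a cube of side `world_extent` (default 1000 mm) resting
on the ground plane; the pixel pitch is chosen so the cube's diagonal fits
inside every image, which guarantees that any object inside the volume
projects fully inside all views.

## Synthetic plants

Plants are unions of capsules (segments swept by a sphere): a vertical stem
and, at each node, a leaf that leaves the stem at its insertion inclination
and droops along a planar arc at a fixed azimuth.  Because each leaf arc is
planar, the leaf's true azimuth is a single number independent of droop, and
the ground-truth phyllotaxy series φᵢ = (ϕᵢ₊₁ − ϕᵢ) mod 360 is exact.

Default dimensions describe a juvenile sorghum plant around seven weeks
after planting: internodes 70–110 mm, leaves 220–320 mm long inserted 20–60°
from vertical, stem radius 12 mm, leaf capsule radius 10 mm (a compromise
between midrib thickness and the rolled blade base; the blade's full width
is not modeled).  The stem continues 120 mm past the top leaf node,
standing in for the culm and the whorl of uncollared leaves above the last
measured one.  The plant base is offset a few millimetres from the
turntable axis (`base_offset`), as real pots always are; this also avoids a
degenerate symmetry noted under *Skeletonization*.  `PlantSpec.random`
draws azimuths as 180° alternation perturbed by ±60° per step, so true
deviations Φᵢ lie in [0°, 60°].

Silhouettes are rendered analytically: an orthographic projection of a
capsule is a 2-D stadium, and a pixel is foreground iff its centre lies in
the union of projected stadiums.  Rendering is deterministic and exact at
pixel-centre sampling.  Total projected area is stable under pixel-size
halving to well under 2 %; individual views of near-edge-on leaves converge
more slowly because sub-pixel-wide features alias.

## Voxel carving and reconstruction scoring

A voxel survives carving iff its centre projects to a foreground pixel
(nearest-pixel sampling) in every view — the discrete visual hull.  The
hull is a superset of the true plant up to a sampling margin of half a voxel
diagonal plus half a pixel diagonal; the test suite asserts this on spheres
and on plant centrelines.  An empty intersection produces an empty grid with
a warning rather than an error.

Reconstruction accuracy is the Dice overlap between each input silhouette
and the hull's reprojection into that view, averaged over views (pixel
pooling is available as an option).  The default reprojection marks, for
each occupied voxel, the pixel nearest its projected centre — the exact
adjoint of the carving membership test — so the reprojection is a subset of
every input mask and the score measures information lost by carving rather
than raster mismatch.  A `footprint` mode that dilates by the projected
voxel footprint is available for visualization.  Because the adjoint score
compares rasters, it is meaningful when image and grid sampling are
commensurate; `CameraRig.voxel_matched(resolution)` sizes the images so one
pixel covers one voxel, and the end-to-end driver uses it by default.
Reconstructions with an aggregate score below 0.70 (inclusive boundary: 0.70
itself survives) or without tree topology are flagged as rejected.

## Skeletonization

The hull is thinned to a one-voxel-wide skeleton by 3-D topology-preserving
thinning (scikit-image's medial-axis thinning), then converted to a graph
over skeleton voxels with 26-connectivity edges; node radii are sampled from
the Euclidean distance transform of the hull.

One caveat discovered during development: thinning annihilates solids with
an exactly even-symmetric cross-section (for example a 6×6-voxel column
centred on a lattice plane), because no centre voxel exists.  Real
reconstructions never present this measure-zero symmetry, but a synthetic
plant placed exactly on the grid axis does; the generator's off-centre
`base_offset` reflects reality and avoids the degeneracy.

Gap joining bridges disconnected fragments whose closest node pair is within
`max_bridge` (default 15 mm ≈ 4–5 voxels at working resolutions), iterating
until no two components are that close; bridge edges are flagged.
Fragments that remain disconnected afterwards are phantom hull volume far
from the plant and are dropped in favour of the largest component.

Terminal branches are then pruned by a classifier over five branch features
(length, mean local radius, straightness, attachment and tip height
fractions).  The default rule is deterministic: a branch is spurious if it
is shorter than 30 mm or thinner than ~1.5 voxels in mean radius.  The
radius floor is the discriminating feature for *ghost branches* — phantom
intersections of the viewing cones that mimic organs.  In carved synthetic
plants real organs carry radii near their capsule radius (8–11 mm) while
ghosts are about one voxel thin, so the scale-aware floor (capped at 80 % of
the skeleton's median radius so it stays neutral on coarse grids) removes
them without touching organs.  A trainable linear margin classifier over the
same features is provided as a functional stand-in for a pre-trained
organ/noise classifier whose training data is not available; the rule-based
mode is the default for reproducibility.  Pruning removes one branch per
pass (shortest first) and re-evaluates, never severs the branch containing
the root, and raises on degenerate input whose only branch is itself
classified spurious.

If cycles persist after pruning (phantom volume can fuse neighbouring
organs), the measurement driver extracts a minimum spanning tree by edge
length and prunes once more.  The topology verdict reported — and used for
the accept/reject flag — is that of the unmodified skeleton, so
cycle-breaking recovers angles without hiding the defect.

## Organ segmentation

For the rooted tree skeleton (root = the lowest degree-1 node, the pot end),
the unique path from the root to every tip is counted per node; nodes on
more than two such paths are stem.  On trees this is equivalent to "more
than two tips in the node's subtree", which is how it is computed (the
literal path-counting formulation is kept as an independent oracle in the
tests).  Remaining nodes form connected leaf segments, each attached to one
stem junction (ties to the lower junction); within a segment the leaf path
runs from the attachment to the geodesically farthest tip.  Leaves are
ranked bottom-up by attachment height, ties broken by azimuth around the
junction and then path length.

Two structural consequences of the path-counting rule are worth noting.
Above the second-highest junction the rule runs out of paths, so the top
leaf, the stem tip, and the stem section between them merge into a single
"leaf" whose azimuth is unreliable — one reason the analysis downstream is
restricted to the lower canopy.  And for plants with at most two tips the
literal rule labels nothing as stem; a relaxed at-least-two-paths rule is
applied and the record flagged (one-leaf plants are excluded from
phyllotaxy anyway, since an angle needs two leaves).

## Angles, filtering, and side alignment

The stem frame is the principal-axis frame of the stem nodes: e₁ the first
principal axis oriented upward, e₂ the second with a non-negative x
component (collinear stems take e₂ as x̂ projected orthogonal to e₁), e₃ =
e₁ × e₂.  Each leaf's direction is the first principal axis of its first 20
path nodes from the junction — about 6–8 cm at working resolutions, long
enough to average voxel noise and short enough to reflect the insertion
tangent rather than the chord to the drooping tip — signed to point away
from the junction.  Inclination θ is measured from e₁ and azimuth ϕ =
atan2(a·e₃, a·e₂), both on [0, 360) with ϕ half-open so 0 and 360 are one
value.

Phyllotaxic angles are successive azimuth differences normalized to
[0, 360); deviations are Φᵢ = |φᵢ − 180|, the departure from perfect
alternation.  Angles outside [90°, 270°] (equivalently Φ > 90°, and the two
formulations are asserted to agree) are flagged as removed: a healthy
sorghum plant rarely sets successive leaves less than a right angle apart,
so such values usually mean a missed or mis-ordered leaf.

Because the side of the plant on which measurement begins is arbitrary, a
series and its elementwise conjugate 360 − φ describe the same plant.  Two
measurement series of one plant are aligned by the sign of their Pearson
correlation over shared retained angles; a negative sign conjugates the
second series.  Alignment restores a conjugated series exactly up to
floating-point round-off (~10⁻¹⁴ degrees; bit-identity is not attainable in
IEEE arithmetic because 360 − x rounds).  Pooled repeatability R² is the
squared Pearson correlation over per-plant-aligned, range-filtered pairs.
Note that per-plant sign alignment is a selection step: under a null of
independent measurements it inflates pooled R² to roughly the squared
expected magnitude of a length-k sample correlation — about 0.10 for
five-angle plants — so `repeatability_r2(..., align=False)` is provided as
the unbiased null reference.

## Quantitative genetics

Per-plant summaries of the lower-canopy deviations (angle indices 1–4) are
a configurable menu — pooled median/mean/max/min across angles and
timepoints, per-angle-index medians and means, per-timepoint medians — with
the pooled median as the headline metric.  Plants with values outside 1.5
interquartile ranges of the quartiles can be flagged for review.

Broad-sense heritability comes from the one-way random-effects model
Y = μ + δᵢ + εᵢⱼ with genotype variance σ²G and residual σ²R, as
H = σ²G / (σ²G + σ²R / n) with n = 2 by default (the minimum replicate
count in a partially replicated panel; n is a configuration constant, not
the harmonic mean).  Balanced designs use the closed-form estimator
(identical to restricted maximum likelihood off the boundary, negative
genotype variance truncated to zero); unbalanced designs use REML via
statsmodels with a method-of-moments fallback.  A `max_reps` option caps
any genotype's contribution to a seeded random subsample so a heavily
replicated check line does not dominate.  At the H = 0 boundary the
truncation makes the estimator's mean positive (≈ 0.05 at 200 genotypes ×
2 replicates) even though its median is 0 — an intrinsic property of any
non-negative variance-component estimator, visible in the validation suite.

Marker quality control keeps biallelic SNPs with missingness < 30 %
(over all individuals), heterozygosity < 10 % and minor allele frequency
≥ 5 % (both over non-missing calls); the filters are independent
predicates, hence order-free.  Significance uses α/Mₑ over an externally
supplied effective marker count Mₑ, and the iterative-engine entry
threshold α·M/Mₑ.

The association engine is deliberately simple: a per-marker linear
regression of phenotype on dosage with optional covariates, exactly
calibrated against the t distribution (validated to machine precision
against `scipy.stats.linregress`, and in the tail by permutation).
Multi-locus engines that condition on detected pseudo-QTNs can be plugged
in through the same `engine(dosages, phenotype) -> p-values` contract.  The
resampling procedure masks 10 % of phenotype records per iteration
(plant-level masking, seeded), rescans, counts markers exceeding the
threshold, and reports RMIP = exceedances / iterations; markers at RMIP
≥ 0.1 are called, with a looser reporting threshold available.  Because a
marginal scan does not condition on detected signal, a dataset-level chance
false positive (expected in ≈ α·M/Mₑ of datasets at the Bonferroni
threshold) persists across resampling iterations and shows up as a non-null
RMIP; this is a property of single-marker scans, not of the resampling
wrapper.

Linkage disequilibrium r² is the squared dosage correlation over shared
non-missing individuals, undefined (NaN) for monomorphic pairs or fewer
than three shared calls.

## Population simulator

Genotypes are drawn at uniform minor allele frequencies in [0.05, 0.5]
under Hardy–Weinberg proportions with inbreeding coefficient F = 0.95 by
default — a predominantly selfing panel, where heterozygous calls are rare
(F = 0 recovers an outbred population).  Phenotypes are genotypic value
plus i.i.d. residual with total variance 1; `h2_target` sets the plot-level
genotypic fraction σ²G/(σ²G + σ²R), and causal markers contribute stated
fractions of total variance carved out of the genotypic share, the
remainder being polygenic.  Realized variance components are recorded so
estimator recovery is checked against known truth; `h2_for_target_H`
converts a desired broad-sense H at n replicates into the plot-level
fraction.

## Validation scales and what they show

The validation suite reconstructs at 64³–128³ for unit tests and 256³ for
the twenty-plant recovery study (the imaging protocol's native 512³ is
supported but reserved for parity runs); at 256³ over seeds 1–20 leaf
counts are exact in 20/20 plants and the pooled median absolute error of
the lower four phyllotaxic angles after side alignment is below 2°.  These
numbers certify the geometry and graph pipeline on clean, known-truth
input.  They deliberately do not emulate real-image segmentation noise,
leaf blades (vs. capsule midribs), tillers, canopy occlusion, or plant
movement between views — the factors that dominate error on real plants —
so passing tests bound the algorithmic error of the pipeline, not the
accuracy of field phenotyping.  Tiller geometry can be switched on in the
generator to study its failure mode, and noise blobs can be injected into
hulls to exercise the pruning stage.
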