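# Methods

## Working conventions

Arrays are (z, y, x), 0-based, with z the sectioning axis; a voxel's centre
sits at `(i + 0.5) × extent` along each axis. Voxel extents are in
nanometres, object volumes in µm³. Labelled (DAB/osmiophilic) structures are
**high** intensity in the working representation; stain-dark raw data can be
flagged for inversion at read time (`v → 2^bits − 1 − v`). The working
intensity domain is 8-bit by default (16-bit supported). Volumes carry an
append-only provenance list recording every operation and its parameters.

## Phantom model

Real labelled specimens are not publicly deposited, so validation runs on
synthetic phantoms whose ground truth is known exactly. Three geometry
presets mirror the acquisition classes the procedures were used on:

| preset | voxel (z, y, x) nm | emulates |
|---|---|---|
| `mito-sbem` | 50 × 18.9 × 18.9 | SBEM, after the 3×3×1 in-plane binning of 6.3 nm pixels |
| `neurite-sbem` | 25 × 10.5 × 10.5 | SBEM, cytosol-labelled projection neurons |
| `fibsem` | 10 × 10 × 10 | near-isotropic FIB-SEM |

The mitochondria preset is deliberately the *binned* working geometry — the
substrate the size cutoff (10 voxels ↔ 0.0002 µm³) is consistent at — while
the raw 6.3 nm geometry remains available through `PhantomSpec` directly.

**Intensity model.** Background is `mean + band-limited texture + Gaussian
noise`, defaults 100 ± 10 with texture amplitude 8 at 150 nm granularity,
clipped to the bit domain and rounded to integers (as acquired data would
be). Labelled voxels are drawn from a Gaussian (default 200 ± 5) truncated
at ±2σ. Truncation is what makes the *separability guarantee* hold by
construction: the closed interval `[label_mean − 2·label_sd, domain max]`
(the "separating range", default [190, 255]) contains every labelled voxel,
while the background mean lies 9 noise standard deviations below its lower
bound, so ≤ 0.1% (in practice ≈ 0%) of background voxels enter it. The
guarantee is asserted per-phantom in tests, not assumed. No quantitative
label-to-background contrast is published for the real volumes; these
defaults were chosen once for testability and are not tuned thereafter.

**Object placement** is uniform rejection sampling in physical coordinates
with a hard attempt cap (default 1000; exceeding it raises a `PlacementError`
naming the class). Accepted objects are recorded with a one-voxel
26-dilation, so all generated objects are separated by at least one
background voxel and threshold to distinct connected components.

**Mitochondria** are randomly oriented solid ellipsoids, each semi-axis
uniform in 100–400 nm, spanning roughly the 0.004–0.3 µm³ volume range
observed in labelled specimens. At the default geometry the smallest
ellipsoid still occupies ≥ 10 voxels after a further 3×3×1 binning, so the
size cutoff separates it from **speckle** — random-walk blobs of 1–9 voxels
at label intensity emulating non-specific signal — by construction.

**Membrane fragments** are thin slabs (≈ 45 nm, normal mostly in-plane)
whose voxels alternate between background draws (odd `z+y+x` sublattice) and
label-range values (even sublattice, alternating between the separating
range's lower bound and the domain maximum). Two properties are engineered:
the even sublattice is diagonally connected inside the slab, so a fragment
thresholds to a single object large enough to survive the size filter; and
its in-mask intensities span the label range, giving a population variance
of ≈ 1000 against ≤ 25 for truncated-Gaussian labelled structures. A naive
fragment alternating label/background values only would threshold to a
near-constant voxel set that no variance filter computed over the segmented
mask could reject; the design keeps the stated bimodality while preserving
the filter's discriminating power.

**Neurite phantoms** render a primary cell — soma sphere plus a recursive
tubular tree (default depth 3, two children per node, branch angles 25–55°,
segment length 600–1000 nm, root radius 150 nm tapering ×0.75) — rasterised
as capsules in physical space. Geometry escaping the grid is clipped and
counted in the truth record. Signal drop-off multiplies the label contrast
above background by `1 − d` inside spheres of 2.5× the local radius around
branch nodes (a sphere that wide severs the tube's in-range voxels, so at
`d = 0.3` region growing at the separating range provably terminates at the
first branch point) and along segments whose radius exceeds a calibre
threshold. **Crossover cells** are independent labelled cells clustered
around the primary soma with a guaranteed one-voxel gap, each joined to the
primary trunk by a bridge rendered 4 intensity units *below* the separating
range: tight ranges segment the cells as distinct traces, permissive ranges
merge them — reproducing both the distinct multi-seed traces and the
crossover incorporation seen in exploratory trial series. The **trachiole**
is a tube abutting the trunk at a constant intensity 2 units below the
separating bound, so the trial at which it joins the ROI is exactly
predictable from the step arithmetic (see below).

What the phantoms do *not* emulate: electron-optics noise statistics,
charging/curtaining artefacts, section-to-section misalignment, membrane
ultrastructure (vesicles, synaptic densities), partial-volume gradients at
label boundaries, or staining heterogeneity beyond the drop-off model.
Passing parameter recovery on phantoms therefore demonstrates correctness
of the *procedures* under their stated assumptions — a separable intensity
range and resolvable gaps between objects — not segmentation accuracy on
arbitrary real data, where ranges and filter thresholds must be chosen per
dataset.

## Pre-processing

Non-local means uses fixed patch size 3³ and search window 7³ (recorded in
provenance); `h = 0.8σ`. Binning reduces by the block **mean**, not sum, so
intensity ranges remain comparable across binning levels; trailing voxels
that do not complete a block are dropped and the voxel size is multiplied by
the factors. Gaussian smoothing takes a physical σ in nm, converted per axis
to voxel units, boundary mode reflect (conserves total intensity). Unsharp
masking is exposed but not part of the segmentation pipeline. The default
composition is NLM first, then binning (configurable; the original order is
not documented). The **true range** is the observed min–max of the working
volume — ranges were read off the data with pixel probes, not assumed
nominal — with a `nominal=True` escape hatch.

## Bulk segmentation

Both threshold bounds are inclusive. Default connectivity is 26
(corner-adjacent voxels connected), matching typical 3D visualisation
software; 6 and 18 are flags. Components are labelled in raster-scan order
of their first voxel so numbering is deterministic. The filter order follows
the procedure narrative — size first, then variance — and each filter logs
the removed ids (in the raw post-threshold numbering, so removal sets are
disjoint across records), parameters and reason. The variance filter uses
the **population** variance (÷N) of the object's voxel intensities on the
working volume and removes objects *above* the cutoff. No numeric variance
cutoff was published; the default used on phantoms is `(4·label_sd)²` (= 400
at the default spec) and the parameter must be chosen explicitly for real
data. The minimum-size cutoffs are strict (`< 10` voxels removed, exactly 10
kept); at the binned SBEM voxel (1.786 × 10⁻⁵ µm³) the 0.0002 µm³ criterion
removes objects of ≤ 11 voxels.

## Seed segmentation

Region growing is flood fill on the thresholded mask (scikit-image's
C implementation); it is tested equivalent to the bulk route
(threshold → components → seed's component) on random volumes at all three
connectivities. A seed whose intensity falls outside the range is an error
for a single grow, but within a trial series such a trial is recorded as
empty-with-error and the series continues. The series holds `hi` at the
common maximum and lowers `lo`: trial k uses
`[max(0, lo_start − (k−1)·step), hi]` with
`step = step_fraction × true-range width`, computed once per series on the
working volume; the symmetric mode (raising `hi`) is not implemented, as the
procedure never used it. Defaults: `step_fraction = 0.003` (the middle of
the 0.002–0.004 range used originally), 12 trials. Nesting
(`ROI_k ⊆ ROI_{k+1}`) and monotone voxel counts follow from range inclusion
and are asserted per series. For a structure of constant intensity `t₀`
touching the grown region, the first incorporating trial is
`k* = 1 + ⌈(lo_start − t₀)/step⌉`, which the trachiole test checks against
the observed series. Multi-seed tracing grows each seed independently at a
shared range; seeds landing in one component share an object id and the
merge is reported; only seeded components are labelled.

## Object analysis

Axis lengths are `2·√(5λᵢ)` for eigenvalues λᵢ of the second central moment
tensor of the voxel-centre cloud (unweighted by intensity;
intensity-weighted moments are deliberately not implemented since the
original features list intensities and geometry separately). For a
continuous solid ellipsoid this recovers the full axes exactly; on
rasterised ellipsoids of ≥ 10⁴ voxels the calibration tests show < 0.1%
error, well inside the 5% acceptance band. Aspect ratio is major/minor.
Degenerate directions (single voxels, collinear/coplanar objects) have their
eigenvalues floored so the reported extent along a flat direction equals the
smallest voxel extent; a single voxel reports its voxel extents as axes. The
orientation is the major-axis eigenvector with its largest-magnitude
component made positive (eigenvectors are sign-ambiguous). Physical volume
is voxel count × voxel volume — voxel-count-based, not mesh-based — so
volume additivity over objects is exact. The volume index maps volumes
affinely to [0, 1] (single object → 0; ties share an index).

Evaluation matches predicted to truth objects one-to-one, greedily by
descending IoU (ties broken by ids), counting pairs with IoU ≥ threshold;
precision = matched/predicted, recall = matched/truth, plus voxel-level
rates and per-match relative volume error. An empty prediction has
precision 1 by convention (no false positives) and is flagged as such.

## I/O and reproducibility

TIFF stacks (z = page) carry a JSON sidecar; HDF5 carries attributes; label
volumes, truth classes and trial masks are HDF5 integer datasets written
with `track_times=False` and fixed compression so identical inputs produce
identical bytes. Values are stored as unsigned integers at the working bit
depth. Declared z-slice counts are validated against
`round(depth_µm × 1000 / z_step_nm)`: off-by-one discrepancies warn (printed
acquisition tables contain such bookkeeping slips, e.g. 541 sections where
13.5 µm / 25 nm gives 540), larger ones fail. The full CLI pipeline under a
fixed seed is byte-identical across runs, which the test suite asserts
file-by-file.

## Problem sizes

Unit tests run phantoms at 64³–96³; the recovery benchmark uses the default
256³ mitochondria phantom (50 ellipsoids, 200 speckles, 20 fragments) and
the default 120×256×256 neurite phantom; oracle equivalence uses 10⁴ random
3×3×3 masks per connectivity and ~100 random 8³ volumes. These sizes were
chosen so the full validation cycle completes in minutes on a laptop while
every guarantee is exercised at the geometry it is stated for.
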