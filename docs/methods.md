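# Methods

## The quantification model

`regionquant` estimates cell numbers and densities for atlas-defined brain
regions from 2D section images that have already been (a) segmented into
binary cell masks and (b) registered to a reference atlas, so that each
section comes with a pixel-aligned label map of region ids. Segmentation
and registration are upstream of this package; their outputs are its
inputs.

The chain from mask to estimate is:

1. **Object extraction.** Maximal connected foreground components of the
   mask (8-connectivity by default, so diagonal pixel chains merge into
   one object) become detected objects; components below `min_size_px`
   (default 4 px) are treated as noise and dropped. Both settings are
   exposed because real pipelines tune them to magnification and marker.
2. **Region assignment.** Each object goes to exactly one region: the
   atlas label covering the majority of its pixels, with label 0 ("outside
   atlas") eligible only when no region overlaps at all, and ties broken
   toward the lowest region id. One-region assignment prevents cells
   straddling a boundary from being counted in two regions; the majority
   rule is the natural deterministic reading of that requirement, and the
   fixed tie-break makes runs reproducible. Objects assigned to label 0
   are reported as "unassigned", never added to any region, so counts are
   conserved. Hemisphere assignment, when a hemisphere mask is present,
   uses the same majority rule.
3. **Manual exclusion.** Segmentation occasionally passes non-cell
   structures (clustered neuropil and similar clutter). An exclusion
   registry — reference points or a mask — flags such objects; they stay
   in the object table but never enter counts. Point references resolve to
   the object containing the point, falling back to the nearest object
   centroid within 5 px; unresolvable references produce warnings, not
   errors, because a stale registry should not abort a run.
4. **Correction and extrapolation.** Sectioning splits a cell of mean
   diameter D across sections of thickness T, so profile counts overcount
   cells by (T+D)/T on average. Abercrombie's correction N = n·T/(T+D)
   removes this bias. Raw profile counts are summed over all sampled
   sections first, then corrected, then multiplied by the sampling
   interval k, then rounded half-up once. Correcting before summing would
   be equivalent; rounding per section would not, and the chosen order
   keeps rounding error from accumulating. Defaults T = 40 µm, D = 15 µm,
   k = 6 describe a typical 1-in-6 series of 40 µm sections with a mid-size
   neuronal soma; all three are configuration parameters, and D is a
   single scalar per run because one mean diameter applies per stain.
5. **Density.** ρ = total / V with V the region volume from the 3D
   reference atlas, which is far less affected by histological shrinkage
   than section-derived areas. Section areas are used only for
   per-section densities in gradient profiling, where only the ordering
   matters. Regions flagged oversaturated (staining too dense to resolve
   single cells) are reported with status "not reported (oversaturated)"
   and no numbers; the flag propagates from a node to all its descendant
   leaves.

Known, uncorrected biases: "lost caps" (cell fragments at section faces
that escape detection) and z-axis occlusion in thick sections. Both
require information a 2D section image cannot provide, and both are left
uncorrected deliberately; estimates should be read with that in mind.

## Downstream statistics

- **Validity**: percent difference of automated vs manual counts per
  group, 100·(test − ref)/ref with the manual count as denominator,
  displayed as a half-up rounded integer, plus an "ALL" row over summed
  counts.
- **Reliability**: absolute percent differences of each rater's counts
  against a reference rater, per group. Because a min–max "range" can be
  taken over raters, over groups, or over both, the summary reports all
  three granularities.
- **Cross-species**: region totals and volumes are pooled over the source
  regions mapped to a shared target region, and densities recomputed as
  Σ totals / Σ volumes — volume-weighted, not an average of densities,
  which would overweight small regions. The comparison is therefore
  invariant to a uniform rescaling of both atlases' volumes.
- **Cell-type ratio**: a/(a+b) per region for two-marker composition
  charts.
- **Gradients**: per-section density = profiles / (region pixel area ×
  pixel-size² × T), Spearman-rank-correlated against dorsoventral section
  order. |ρ| ≥ 0.5 with at least 4 usable sections classifies a trend
  (decreasing/increasing); fewer sections yield "insufficient data".
  Rank correlation makes the classification invariant to any strictly
  monotone transform of the densities; the threshold and minimum are
  declared parameters, since a qualitative "decreases dorsoventrally"
  claim needs some operationalization. Sections serve as the dorsoventral
  bins. Constant density sequences are assigned ρ = 0.

## Synthetic data: what it emulates and what it does not

The generator produces atlas series (equal-width bands or Voronoi
partitions of the image among leaf regions), binary masks with planted
circular cell profiles, and irregular clutter blobs, all recorded in an
exact registry. Per-(section, region) counts are Poisson with a mean set
by a per-region areal density, the simplest count model consistent with a
density specification; a fixed-count mode exists for exact tests. Discs
lie entirely inside one region and at least `min_gap_px` (default 2) from
region boundaries and from each other, so the assignment ground truth is
unambiguous and planted counts are recovered exactly — real tissue offers
no such guarantee, and passing these tests shows the counting machinery
is correct, not that segmentation of real images would be. A packing
pre-check rejects requests where discs would exceed 40% of a region's
area, since random sequential placement jams well below full coverage.
No staining texture, intensity variation, or light/dark cell classes are
modeled; those are segmentation-stage concerns.

The sectioning simulator reduces spherical cells to intervals on the
depth axis: centers uniform over the tissue depth, a cell of diameter D
appearing in every slab of thickness T its open interval intersects, with
every k-th slab sampled. This reproduces exactly the statistical
structure Abercrombie's formula assumes — expected profiles per cell
(T+D)/T — and nothing else (no lost caps, no shrinkage). Centers falling
exactly on a slab boundary belong to the lower slab, which makes the
D = 0 limit an exact identity (every point-cell counted once). Edge
effects at the tissue top and bottom are not corrected; at the default
depths used in tests (≥ 400 slabs) they are orders of magnitude below
sampling noise.

## Numerical and format choices

- Half-up rounding (2.5 → 3, symmetric for negatives) everywhere a
  user-facing integer or rounded percentage is produced, chosen over
  banker's rounding for predictability in reports.
- Label images are stored as unsigned 32-bit little-endian row-major flat
  binary with a JSON sidecar header (width, height, pixel size, thickness,
  section index, axis coordinate) — the flat-file convention of
  atlas-registration toolchains, made self-describing. Pixel id 0 is
  reserved for "outside atlas". Coordinates are row-major, origin
  top-left, 0-based.
- Ontologies, groupings, cross-atlas mappings, object tables and reports
  are all TSV with fixed column orders (see `docs/formats.md`); reports
  print integers plain and densities/percentages with 2 decimals.
- The pipeline writes a manifest (config snapshot, input checksums,
  per-stage row counts, warnings) and asserts count conservation
  (region + unassigned + excluded = extracted) on every run; reruns on
  identical inputs are byte-identical.

## Problem sizes used in the test suite

Property tests run on synthetic series of 4–20 sections at 48–96 px
square with 1–5 regions and a few hundred planted cells, 100 random
64×64 masks for the flood-fill cross-check, 200 replicates of the
sectioning simulator at 1,000 cells, and 20 seeds for gradient
classification — sizes at which the statistical assertions (3-standard-
error bounds) are already tight while the whole suite stays fast.

## Limitations

- The grouping fixtures are illustrative; faithful CCFv3-2017 or WHSv2
  id tables must be supplied by the user as grouping/mapping TSVs.
- One published validity pair ("16% higher", manual 905 vs automated 961)
  is arithmetically inconsistent with its own counts (≈ 6.2%); it is not
  used as a golden value anywhere, and no intent is guessed.
- Bilateral totals assume the reference-atlas volumes are bilateral, as
  published atlas volume tables are; unilateral densities require the
  caller to supply unilateral volumes.
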