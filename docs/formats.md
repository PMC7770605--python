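# File and report formats

All tabular files are UTF-8, tab-separated, LF line endings, one header
row, fixed column order. Integers print plain; densities and percentages
print with 2 decimals; missing values print empty.

## Inputs

### Ontology TSV
```
id  acronym  name  parent_id  r  g  b  volume_mm3  oversaturated
```
One row per region. `parent_id` empty for the (single) root;
`oversaturated` ∈ {0, 1}; `volume_mm3` is the bilateral region volume from
the 3D reference atlas. Ids must be unique, colors unique, volumes ≥ 0,
and the parent links must form a single rooted tree. Only leaf ids may
appear in atlas label images.

### Atlas section: `<stem>.flat` + `<stem>.hdr.json`
`.flat` is the label image as little-endian unsigned 32-bit integers,
row-major, origin top-left (file size = width × height × 4 bytes).
`.hdr.json` carries exactly the fields
`width, height, pixel_size_um, thickness_um, section_index, axis_coord_mm`.
Pixel value 0 means "outside atlas".

### Segmentation mask PNG
8-bit grayscale, 0 = background, 255 = cell, same shape as the section's
label image.

### Grouping TSV
```
leaf_id  group_acronym
```
Each leaf maps to at most one group; unmapped leaves report as
`UNGROUPED`.

### Cross-atlas mapping TSV
```
target_acronym  atlasA_ids  atlasB_ids
```
Id lists are comma-separated, non-empty, and disjoint across rows within
each atlas.

### Exclusion registry TSV
```
section  row  col
```
One reference point per excluded object (pixel coordinates).

### Ground-truth TSV (synthetic data)
```
section  region_id  object_id  row  col  radius  is_artifact
```

## Outputs

### Objects TSV (`extract`, `run`)
```
section  object_id  pixel_count  row  col  region_id  hemisphere  excluded
```
`row`/`col` are the object centroid; `region_id` 0 means unassigned;
`excluded` ∈ {0, 1}.

### Region report TSV (`quantify`, `run`)
```
region  n_raw  n_corrected  total_estimate  volume_mm3  density_per_mm3  status
```
`status` is `ok`, `density omitted (no volume)`, or
`not reported (oversaturated)` (the latter with all numbers suppressed).

### Validity TSV (`compare`)
```
region  count_ref  count_test  pct_diff  pct_diff_rounded
```
Includes an `ALL` row over summed counts.

### Rater TSV (`raters`)
```
rater  region  abs_pct_diff
```
plus a final `RANGE` row carrying the maximum.

### Cross-species TSV (`crossspecies`)
```
target  density_a  density_b  ratio  pct_lower_a_vs_b  status
```

### Gradient TSV (`gradient`)
```
axis_coord_mm  density_per_mm3
```
ordered dorsal → ventral; ρ and the classification go to stdout.

### Manifest (`run`): `manifest.json`
Config snapshot, SHA-256 checksums of all inputs and outputs, per-stage
row counts (sections, objects extracted/excluded, profiles counted,
regions reported), and warnings. Written atomically at run end.
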