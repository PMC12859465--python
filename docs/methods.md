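# Methods

## Scope and conventions

The package quantifies osteocyte lacunar-canalicular network (OLCN)
integration across bone remodeling interfaces in 3D gray-value volumes.
Axis order is (z, y, x), 0-based, slice index = z; voxel size is isotropic,
carried in nanometres; physical distances are `voxel_size × Euclidean index
distance`; voxel centers sit at `(index + 0.5) × voxel_size`. Gray values
are canonically 16-bit unsigned; float inputs are processed without
rescaling. Connectivity is 26 in 3D and 8 in 2D throughout, so thin tubes
survive diagonal steps.

All structuring elements are Euclidean balls (3D) or disks (2D): "size"
parameters are read as radius. They are implemented by exact Euclidean
distance transforms (erode: distance to background > r, with the outside of
the grid counting as background; dilate: distance to foreground ≤ r,
clipped at the grid), which is exact and fast even for the 50 px region
erosion. The radius reading and the 3D (rather than slice-wise) execution
of the mineralization-stage morphology are config keys
(`region_erosion_radius_px`, `b_dilation_px`, `c_erosion_px`,
`opening_radius_vox`), so the alternate readings are one config change.

## Segmentation model

* **Otsu threshold** (`otsu_threshold`): 256 uniform bins over the observed
  [min, max]; the boundary maximizing between-class variance, ties to the
  lower boundary; foreground (low-intensity element) = value ≤ threshold.
  This matches classic 8-bit Otsu while supporting 16-bit and float data.
  Inverted-contrast data (bright pores) must be inverted by the caller.
* **Mask B** — all low-intensity elements (lacunae, canaliculi, vessels,
  noise) by one global Otsu. This presumes the histogram structure of
  phase-contrast bone data: a dominant mineral hump with subtle
  inter-region contrast and a far-darker pore tail. It is the same premise
  that motivates normalizing mineral GV by lacunar GV, and the phantom is
  built to respect it (see below).
* **Mask C** — lacunae: Otsu mask → opening with ball radius 7 vx
  (separates touching pores and erases canaliculi/noise) → 26-connected
  components → discard components below 1500 voxels (exactly 1500 is
  retained) → compact relabeling.
* **2D canaliculi** (`segment_canaliculi_2d`): black top-hat (closing minus
  image, disk radius 10 px — about 10–20× a canalicular radius, so tubes
  are enhanced while wide pores are not) on a minimum-intensity projection,
  Otsu on the response (foreground = response ≥ threshold), 8-connected
  components, drop components below 100 px.

## Projections

`min_intensity_projections` uses consecutive non-overlapping windows
starting at slice 0 (offset and window count/length configurable; defaults
15 × 130 slices), trailing slices unused. Label volumes are projected by
taking, per pixel, the label at the argmin slice of the gray volume (ties →
first slice), so a dark canalicular pixel inherits the region in which that
minimum actually lives and gray/label projections stay aligned.

## Regional mineralization and ranking

Per region: erode by `region_erosion_radius_px` (default 50 px; removes
scan-edge effects and the cement lines, which is also why regions partition
the volume with no dedicated cement label), subtract mask B dilated by
10 px → mineral matrix; lacunae are assigned to regions by majority voxel
vote (ties → lower region id) and sampled through mask C eroded by 10 px.
`norm_mean_gv = mean GV(mineral) / mean GV(lacunar cores)` cancels
low-frequency reconstruction artifacts. Regions losing all mineral voxels
or holding no lacuna are flagged and excluded. Ranking is ascending
`norm_mean_gv` (rank 1 = youngest; mineralization, hence GV, grows with
local tissue age), ties toward the lower region id.

An advisory check (`validate_regions_against_gv`) compares pairwise region
mean-GV separations against `margin_factor` (default 2) × the pooled
within-region SD of slice-wise means; it warns but never blocks.

## Region-mask interpolation

Sparse manual labels on ≥ 2 slices are densified by shape-based
interpolation: per region, a signed Euclidean distance map (positive
inside) per labeled slice, linear blending between bracketing slices, label
= argmax of the blended maps (ties → lower label), nearest-slice copy
outside the labeled range. Labeled slices are reproduced exactly.
Equivalence with any specific external toolchain's interpolation is not
claimed.

## Connection counting

Candidates are lacunar components that touch no volume face, whose majority
region has an older-ranked region within `proximity_um` (default 25 µm,
matching the counting radius) of their surface; the nearest such older
region is the neighbor. For each candidate: a minimum-intensity projection
over exactly its slices; 2D canalicular segmentation; other lacunae
excluded from the lacunar projection; the target footprint OR-ed into the
canalicular mask; the 8-connected component containing the lacuna is the
cluster ("the component containing the lacuna" implements "largest
components kept, which included the lacuna" — the lacuna-bearing component
is the object of interest regardless of size rank). The interface band is
the older region's 2D projection dilated by 3 px minus itself. Each
8-connected component of cluster ∩ band is one candidate crossing; two
canaliculi merging before the band count once, and disjoint band
intersections of one grazing tube count separately. A component counts
toward `N.Conn` iff its minimum pixel distance to the lacuna footprint is
≤ `radius_um` (default 25 µm). Distance is measured from the projected
surface, not the centroid, so large lacunae are not penalized
(`distance_mode="centroid"` is available). The 25 µm radius is applied
in-plane on the projection, since the whole procedure is projection-based.

One numerical detail: on sharp-edged data the top-hat's closing
reconstructs the dark lacuna 1–2 px beyond its segmented footprint, leaving
a thin low-response ring that can detach emerging canaliculi. The footprint
added to the canalicular mask is therefore dilated by `bridge_px` (default
2 px) purely to span that ring; distances are always measured from the
undilated footprint.

## Statistics

`porosity_group_test`: pooled `pCan.P` of rank-1 regions vs all
older-ranked regions, two-sample Student's t (equal variance; Welch via
config), two-sided. The procedure is described as comparing group medians
with a t-test, which is formally tense (a t-test compares means); the test
is run on the values with both group medians reported alongside, plus a
Pearson correlation of porosity against rank. Constant groups are handled
explicitly (identical → t = 0, p = 1; exactly separated → infinite
statistic, p = 0, flagged). `connection_correlation`: Pearson r of `N.Conn`
against the neighbor's normalized mean GV, p from the t-transform
`t = r√((n−2)/(1−r²))` on n−2 df, two-sided. α = 0.05. No multiple-testing
correction (two tests); lacunae are treated as independent.

## The phantom

`generate_phantom` rasterizes, in draw order mineral regions → cement line
→ canaliculi → lacunae/vessels/specks (pores overwrite), then adds Gaussian
noise; ground truth is computed on the noise-free rasterization and the
seed drives only the noise. Regions are slabs along x separated by
sinusoidal sheets of constant thickness (amplitude/periods configurable),
mirroring the wave-like resorption-front topology preserved in cement
lines. Lacunae are axis-aligned ellipsoids; canaliculi are tubes (voxels
whose centers lie within the radius of a polyline — simple and
exhaustively checkable); vessels are thick tubes that may cross the field
of view; specks are sub-filter spheres standing in for image noise.
Declared canaliculus kinds are validated geometrically (a `crossing`
intersects the cement surface exactly once; `loop`/`intra_region` paths
never come within one tube radius of it), and each crossing's in-plane
distance from its source lacuna's projected footprint to the crossing point
is computed from the rasterization — the same measurement convention the
counting stage uses — and split at the 25 µm radius in
`true_crossing_counts`.

Gray values: pores 25, regions 170/180 (young → old), cement 200, noise SD
7 by default (≈ 5 % of the 145 GV pore-mineral contrast). The inter-region
contrast is deliberately subtle (≈ 6 %) against a dominant pore contrast:
that is both what phase-contrast bone data look like and the premise under
which a single global Otsu for "low-intensity elements" is meaningful. The
paper's canalicular radius is not published; the phantom exposes it as a
parameter and the fixture uses 0.4 µm (literature range ~0.1–0.5 µm
diameter ~0.2–1 µm).

The documented validation fixture (`default_validation_phantom`) is a
160 × 240 × 240 grid at 250 nm voxels (40 × 60 × 60 µm): two regions, a
wavy cement line at x ≈ 30 µm, five lacunae ≈ 12–14 × 10³ voxels each (one
clipped at the z = 0 face, one in the older region), a vascular canal, ten
0.5 µm specks, and ten canaliculi: three crossings from one lacuna
(≈ 6–7 µm), single crossings at 7 and 19 µm from two others, one long
wandering crossing whose interface intersection lies 33 µm from its source
(beyond the counting radius), one loop, two intra-region tubes and one
detached tube. The voxel size is coarser than nano-CT practice (the
`PhantomParams` default is 100 nm) so that the 25 µm counting radius
(100 px) and realistic lacunae fit a grid the full pipeline traverses in
tens of seconds; all physical thresholds are converted through the voxel
size, never hard-coded in voxels. Phantom analyses use 4 projections of 40
slices over the 160-slice stack in place of the full-stack default 15×130.

What the phantom does *not* emulate: phase-contrast physics and partial
volume blur (edges are razor-sharp), ring/beam artifacts, curved or
branching canaliculi, realistic lacunar density gradients, or the paper's
actual histograms. Passing tests therefore demonstrate the correctness of
the measurement chain on data satisfying the method's stated assumptions,
not segmentation robustness on raw synchrotron reconstructions.

## Phantom families for the statistical properties

Two statistical claims are validated on families rather than single
phantoms, using the real segmentation/counting code on smaller grids:

* porosity family — 16 × 24 × 24 µm members, young:old generated tube
  density 2:1 (8 vs 4 random 12 µm tubes), no lacunae; 6 members give 6
  young and 6 older `pCan.P` values for the group t-test;
* connection family — 12 × 16 × 16 µm members, one lacuna per region, the
  number of generated crossings varying monotonically (1–4) against an
  older-region GV sweep of 174–188; the counting path runs with region
  erosion 6 px / B-dilation 3 px / C-erosion 3 px (standard config keys
  scaled to the member size). Every crossing lies within the 25 µm radius
  at this scale, so the family tests count and correlation recovery, not
  the distance cut (which the fixture and unit tests cover).

## Degenerate inputs and numerical choices

Constant volumes cannot be Otsu-thresholded (error); constant projections
yield empty canalicular masks (no error). An empty interface band (no older
neighbor in the window) warns and counts zero. Regions annihilated by the
50 px erosion are excluded and unranked. Otsu near-ties across empty
histogram bins are exact ties in real arithmetic; the implementation's
vectorized cumulative moments may differ from a per-boundary summation in
the last float ulps there, which is why validation compares achieved
between-class variance rather than boundary indices alone. CSV outputs
contain no timestamps, and all randomness flows from the single config
seed, so identical configs produce bit-identical outputs.
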