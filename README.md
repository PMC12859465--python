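# olcn — osteocyte lacunar-canalicular network integration across bone remodeling interfaces

Bone is continuously remodeled in discrete patches. Each (re)modeling cycle
leaves behind a hyper-mineralized **cement line** separating tissue
generations, and the osteocytes embedded in the new matrix must decide — or
fail — to reconnect their dendrite network (the lacunar-canalicular network,
OLCN) to the older tissue on the far side. In phase-contrast synchrotron
nano-CT, voxel gray value (GV) tracks mineral density: younger regions are
darker, cement lines locally brighter, and pores (lacunae, canaliculi,
vessels) darkest of all. This package implements the quantitative analysis
of that integration for 3D gray-value stacks, plus a synthetic bone phantom
with exact ground truth so that every stage can be validated without
proprietary scan data.

The three analyses, for regions `r` of a remodeling-labeled volume:

1. **Degree of mineralization.** Dense region labels (mask A, interpolated
   from sparse manual slice labels), a global Otsu mask of all low-intensity
   elements (mask B), and a lacunar mask (mask C: Otsu → opening, ball
   radius 7 vx → 26-connected components → discard < 1500 voxels). After a
   50 px region erosion (removes edges and cement lines), B⊕10 px is
   subtracted to isolate mineral matrix and C⊖10 px samples lacunar cores;
   the **normalized mean GV** `= mean GV(mineral_r) / mean GV(lacunae_r)`
   cancels low-frequency artifacts, and regions are ranked by it
   (rank 1 = youngest).
2. **Projected canalicular porosity.** Minimum-intensity projections over
   consecutive slice windows (default 15 × 130 slices); canaliculi
   segmented per projection by black top-hat (disk radius 10 px) + Otsu,
   dropping 2D components < 100 px; per region
   `pCan.P = Σᵢ pCan.V(i) / Σᵢ pMin.V(i)` pools canalicular over mineral
   pixel counts across projections `i`.
3. **Canalicular connections (N.Conn).** For each lacuna near the cement
   line, in the locally younger region and fully inside the scan, a
   projection over exactly its slices is built; the 8-connected canalicular
   component containing the lacuna is intersected with the interface band
   (older region ⊕ 3 px minus itself) and the components of that
   intersection within 25 µm of the lacuna are counted.

Statistics: Student's t-test of youngest-region `pCan.P` against older
regions, and a Pearson correlation of `N.Conn` against the older neighbor's
normalized mean GV (two-sided, α = 0.05).

## Worked example

The built-in validation phantom is a 40 × 60 × 60 µm volume at 250 nm
voxels: two remodeling regions split by a wavy cement line, five lacunae,
a vascular canal, and canaliculi that cross the interface, loop back from
it, or stay within their region — all with known ground truth.

```python
from olcn import PipelineConfig, run_pipeline

config = PipelineConfig(
    use_validation_phantom=True, seed=1,
    window_slices=40, n_projections=4,   # the phantom stack has 160 slices
    region_source="supplied",
)
result = run_pipeline(config)
for s in result.region_stats:
    print(f"region {s.region_id}: rank={s.rank} norm_mean_gv={s.norm_mean_gv:.3f}")
for p in result.porosity:
    print(f"region {p.region_id}: pCan.P={p.pcan_p:.4f}")
for row in result.connection_rows:
    print(f"lacuna {row['lacuna_id']}: N.Conn={row['n_conn']}")
```

prints

```
region 1: rank=1 norm_mean_gv=6.779
region 2: rank=2 norm_mean_gv=7.188
region 1: pCan.P=0.0209
region 2: pCan.P=0.0084
lacuna 3: N.Conn=1
lacuna 5: N.Conn=3
lacuna 6: N.Conn=1
```

Region 1 (younger, less mineralized: lower normalized GV, rank 1) carries a
~2.5× denser projected canalicular network than region 2, and the three
candidate lacunae recover exactly the generated numbers of interface
crossings within the 25 µm counting radius (1, 3 and 1; a fourth generated
crossing sits beyond 25 µm and is correctly not counted).

The same pipeline runs on real data: `olcn run --config config.yaml` with a
multipage TIFF volume plus dense or sparse region labels; see also
`olcn phantom`, `olcn porosity`, `olcn connections`.

## Limitations

`pCan.P` is an explicitly *projected* quantity, far higher than a true 3D
porosity; no absolute mineral-density calibration is attempted; canalicular
loops are rendered by the phantom but not algorithmically detected; and CT
cannot resolve whether a canaliculus still hosts a living cell process.
See `docs/methods.md` for the full model description and design choices.
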