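"""Synthetic nano-CT-like bone phantoms with full ground truth.

The phantom emulates the gray-value structure of phase-contrast nano-CT of
remodeled bone: remodeling regions whose mean gray value increases with
local tissue age (younger matrix is less mineralized, hence darker), a
hyper-mineralized cement line modeled as a wavy sinusoidal sheet of
constant thickness, ellipsoidal osteocyte lacunae, tubular canaliculi
(including ones crossing the cement line and U-shaped loops that approach
it without crossing), sub-resolution noise specks, and additive Gaussian
image noise.  Every structure is rasterized from an analytic description,
so the generator can also report exact ground truth: the noise-free region
partition, labeled lacunae, per-region canalicular/mineral voxel ratios,
and per-lacuna counts of interface-crossing canaliculi split at the
counting radius.

Draw order is mineral regions -> cement line -> canaliculi -> lacunae
(pores overwrite), Gaussian noise is added last; ground truth is computed
on the noise-free rasterization.  Voxel centers sit at
``(index + 0.5) * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume_io import Volume

DEFAULT_COUNTING_RADIUS_UM = 25.0


class PhantomGeometryError(ValueError):
    """Raised when a phantom structure does not fit its declared contract."""


@dataclass
class LacunaSpec:
    """Axis-aligned ellipsoidal lacuna; center/semi-axes in micrometres (z, y, x)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    region_id: int = 0
    touches_boundary: bool = False


@dataclass
class SpeckSpec:
    """Small spherical pore below the lacunar size filter (image-noise stand-in)."""

    center: tuple[float, float, float]
    radius_um: float


@dataclass
class VesselSpec:
    """Vascular canal: a thick tube at pore gray value.

    Vessels belong to the low-intensity mask (B) but are neither lacunae
    nor canaliculi; they may exit the grid (a canal crossing the field of
    view is the common case) and are rasterized clipped.
    """

    path: np.ndarray
    radius_um: float

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=float)


@dataclass
class CanaliculusSpec:
    """Tube along a polyline of (z, y, x) points in micrometres.

    ``kind`` is one of ``intra_region`` (never touches the interface),
    ``crossing`` (intersects the cement-line surface exactly once),
    ``loop`` (starts and ends on the same lacuna without touching the
    interface) or ``dead_end``.  For crossings the generator fills
    ``crossing_distance_um`` with the in-plane distance from the source
    lacuna's projected footprint to the crossing point.
    """

    path: np.ndarray
    radius_um: float
    kind: str = "intra_region"
    source_lacuna: int | None = None
    crossing_distance_um: float | None = None

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=float)
        if self.path.ndim != 2 or self.path.shape[1] != 3 or len(self.path) < 2:
            raise ValueError("canaliculus path must be an (N>=2, 3) array of points")
        if self.kind not in ("intra_region", "crossing", "loop", "dead_end"):
            raise ValueError(f"unknown canaliculus kind {self.kind!r}")


@dataclass
class PhantomParams:
    """Full description of a synthetic volume.

    Gray values must satisfy
    ``lacuna_gv < min(region_gv_means) < ... < max(region_gv_means) < cement_gv``
    with ``region_gv_means`` ordered young -> old (mineralization, and
    hence gray value, increases with local tissue age).  Regions are slabs
    along x separated by wavy cement-line sheets.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_nm: float = 100.0
    region_gv_means: tuple[float, ...] = (165.0, 180.0)
    cement_gv: float = 200.0
    cement_thickness_um: float = 2.0
    cement_wave_amplitude_um: float = 2.0
    cement_wave_period_um: float = 25.0
    cement_wave_period_z_um: float | None = None
    cement_positions_um: tuple[float, ...] | None = None
    lacuna_specs: list[LacunaSpec] = field(default_factory=list)
    canaliculus_specs: list[CanaliculusSpec] = field(default_factory=list)
    speck_specs: list[SpeckSpec] = field(default_factory=list)
    vessel_specs: list[VesselSpec] = field(default_factory=list)
    lacuna_gv: float = 25.0
    noise_sd: float = 0.0
    seed: int = 0
    counting_radius_um: float = DEFAULT_COUNTING_RADIUS_UM

    @classmethod
    def from_dict(cls, raw: dict) -> "PhantomParams":
        """Build parameters from a plain mapping (e.g. parsed YAML).

        Structure lists are given as mappings mirroring the spec dataclass
        fields, e.g. ``lacuna_specs: [{center: [z,y,x], semi_axes: [a,b,c]}]``.
        """
        raw = dict(raw)
        for key, spec_cls in (
            ("lacuna_specs", LacunaSpec),
            ("canaliculus_specs", CanaliculusSpec),
            ("speck_specs", SpeckSpec),
            ("vessel_specs", VesselSpec),
        ):
            if key in raw:
                raw[key] = [
                    item if isinstance(item, spec_cls) else spec_cls(**item)
                    for item in raw[key]
                ]
        for key in ("grid_shape", "region_gv_means", "cement_positions_um"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        import dataclasses as _dc

        known = {f.name for f in _dc.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown phantom parameters: {sorted(unknown)}")
        return cls(**raw)

    @property
    def n_regions(self) -> int:
        return len(self.region_gv_means)

    @property
    def voxel_size_um(self) -> float:
        return self.voxel_size_nm / 1000.0

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * self.voxel_size_um for n in self.grid_shape)

    def validate(self) -> None:
        gvs = list(self.region_gv_means)
        if any(b <= a for a, b in zip(gvs, gvs[1:])):
            raise ValueError(f"region_gv_means must be strictly increasing: {gvs}")
        if not self.lacuna_gv < gvs[0]:
            raise ValueError("lacuna_gv must be below the youngest region mean")
        if not self.cement_gv > gvs[-1]:
            raise ValueError("cement_gv must exceed the oldest region mean")
        if self.n_regions not in (1, 2, 3):
            raise ValueError("phantom supports 1-3 remodeling regions")
        ext = self.extent_um
        for i, lac in enumerate(self.lacuna_specs):
            lo = [c - s for c, s in zip(lac.center, lac.semi_axes)]
            hi = [c + s for c, s in zip(lac.center, lac.semi_axes)]
            inside = all(l >= 0 and h <= e for l, h, e in zip(lo, hi, ext))
            if not inside and not lac.touches_boundary:
                raise PhantomGeometryError(
                    f"lacuna {i} at {lac.center} um exceeds the grid extent {ext}"
                )
            if not any(0 <= c <= e for c, e in zip(lac.center, ext)):
                raise PhantomGeometryError(f"lacuna {i} lies fully outside the grid")
        for i, can in enumerate(self.canaliculus_specs):
            r = can.radius_um
            if (can.path - r < 0).any() or (can.path + r > np.array(ext)).any():
                raise PhantomGeometryError(
                    f"canaliculus {i} ({can.kind}) exceeds the grid extent {ext}"
                )
        for i, sp in enumerate(self.speck_specs):
            if any(c - sp.radius_um < 0 or c + sp.radius_um > e
                   for c, e in zip(sp.center, ext)):
                raise PhantomGeometryError(f"speck {i} exceeds the grid extent {ext}")


@dataclass
class CrossingCounts:
    """Per-lacuna ground-truth crossing tallies split at the counting radius."""

    within: int = 0
    beyond: int = 0


@dataclass
class GroundTruth:
    """Noise-free truth for every downstream stage."""

    region_labels: np.ndarray
    lacuna_labels: np.ndarray
    canaliculus_mask: np.ndarray
    speck_mask: np.ndarray
    vessel_mask: np.ndarray
    cement_mask: np.ndarray
    true_crossing_counts: dict[int, CrossingCounts]
    crossing_records: list[dict]
    analytic_region_porosity: dict[int, float]
    cement_surface: dict
    counting_radius_um: float
    voxel_size_nm: float


def _axis_coords(n: int, voxel_um: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * voxel_um


def _surface_x(params: PhantomParams, y_um: np.ndarray, z_um: np.ndarray, k: int) -> np.ndarray:
    """x position (um) of cement sheet k on a (z, y) grid."""
    positions = params.cement_positions_um
    if positions is None:
        ext_x = params.extent_um[2]
        positions = tuple(
            ext_x * (i + 1) / params.n_regions for i in range(params.n_regions - 1)
        )
    period_z = params.cement_wave_period_z_um or 1.6 * params.cement_wave_period_um
    wave = np.sin(2 * np.pi * y_um[None, :] / params.cement_wave_period_um) * np.cos(
        2 * np.pi * z_um[:, None] / period_z
    )
    return positions[k] + params.cement_wave_amplitude_um * wave


def _rasterize_ellipsoid(shape, voxel_um, center, semi_axes) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    lo = [max(0, int(np.floor((c - s) / voxel_um)) - 1) for c, s in zip(center, semi_axes)]
    hi = [min(n, int(np.ceil((c + s) / voxel_um)) + 1)
          for n, c, s in zip(shape, center, semi_axes)]
    if any(l >= h for l, h in zip(lo, hi)):
        return mask
    coords = [
        _axis_coords(n, voxel_um)[l:h] for n, l, h in zip(shape, lo, hi)
    ]
    zz = ((coords[0] - center[0]) / semi_axes[0]) ** 2
    yy = ((coords[1] - center[1]) / semi_axes[1]) ** 2
    xx = ((coords[2] - center[2]) / semi_axes[2]) ** 2
    sub = zz[:, None, None] + yy[None, :, None] + xx[None, None, :] <= 1.0
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub
    return mask


def _rasterize_tube(shape, voxel_um, path: np.ndarray, radius_um: float) -> np.ndarray:
    """Voxels whose centers lie within ``radius_um`` of the polyline."""
    mask = np.zeros(shape, dtype=bool)
    pad = radius_um + voxel_um
    for a, b in zip(path[:-1], path[1:]):
        lo_um = np.minimum(a, b) - pad
        hi_um = np.maximum(a, b) + pad
        lo = [max(0, int(np.floor(l / voxel_um))) for l in lo_um]
        hi = [min(n, int(np.ceil(h / voxel_um)) + 1) for n, h in zip(shape, hi_um)]
        if any(l >= h for l, h in zip(lo, hi)):
            continue
        coords = [_axis_coords(n, voxel_um)[l:h] for n, l, h in zip(shape, lo, hi)]
        pz = coords[0][:, None, None] - a[0]
        py = coords[1][None, :, None] - a[1]
        px = coords[2][None, None, :] - a[2]
        d = b - a
        seg_len2 = float(d @ d)
        if seg_len2 == 0:
            dist2 = pz**2 + py**2 + px**2
        else:
            t = (pz * d[0] + py * d[1] + px * d[2]) / seg_len2
            t = np.clip(t, 0.0, 1.0)
            dist2 = (pz - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (px - t * d[2]) ** 2
        sub = dist2 <= radius_um**2
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= sub
    return mask


def _densify(path: np.ndarray, step_um: float) -> np.ndarray:
    pts = [path[0]]
    for a, b in zip(path[:-1], path[1:]):
        seg = np.linalg.norm(b - a)
        n = max(1, int(np.ceil(seg / step_um)))
        for i in range(1, n + 1):
            pts.append(a + (b - a) * i / n)
    return np.asarray(pts)


def _surface_values(params: PhantomParams, pts: np.ndarray) -> np.ndarray:
    """Signed x-distance of points to each cement sheet (sheet index first)."""
    positions = params.cement_positions_um
    if positions is None:
        ext_x = params.extent_um[2]
        positions = tuple(
            ext_x * (i + 1) / params.n_regions for i in range(params.n_regions - 1)
        )
    period_z = params.cement_wave_period_z_um or 1.6 * params.cement_wave_period_um
    wave = np.sin(2 * np.pi * pts[:, 1] / params.cement_wave_period_um) * np.cos(
        2 * np.pi * pts[:, 0] / period_z
    )
    vals = np.empty((params.n_regions - 1, len(pts)))
    for k in range(params.n_regions - 1):
        surf = positions[k] + params.cement_wave_amplitude_um * wave
        vals[k] = pts[:, 2] - surf
    return vals


def _classify_crossings(params: PhantomParams, gt_lacuna_labels: np.ndarray):
    """Locate interface crossings and measure in-plane distances to source lacunae."""
    voxel_um = params.voxel_size_um
    records = []
    counts = {i: CrossingCounts() for i in range(len(params.lacuna_specs))}
    footprint_dist = {}
    for idx, can in enumerate(params.canaliculus_specs):
        pts = _densify(can.path, voxel_um / 2)
        signed = _surface_values(params, pts) if params.n_regions > 1 else np.empty((0, len(pts)))
        n_cross = 0
        crossing_pt = None
        for k in range(signed.shape[0]):
            s = np.sign(signed[k])
            nz = np.nonzero(s != 0)[0]
            # sign changes between consecutive nonzero samples (a sample may
            # land exactly on the surface)
            changes = np.nonzero(np.diff(s[nz]) != 0)[0]
            for c in changes:
                f, g = nz[c], nz[c + 1]
                n_cross += 1
                frac = abs(signed[k, f]) / (abs(signed[k, f]) + abs(signed[k, g]))
                crossing_pt = pts[f] + frac * (pts[g] - pts[f])
        if can.kind == "crossing":
            if n_cross != 1:
                raise PhantomGeometryError(
                    f"canaliculus {idx} declared 'crossing' intersects the cement "
                    f"surface {n_cross} times (expected exactly once)"
                )
        elif can.kind in ("loop", "intra_region"):
            if n_cross > 0 or (
                signed.size and float(np.abs(signed).min()) <= can.radius_um
            ):
                raise PhantomGeometryError(
                    f"canaliculus {idx} declared '{can.kind}' touches the interface"
                )
        if can.kind != "crossing" or can.source_lacuna is None:
            continue
        lac_id = can.source_lacuna + 1  # ground-truth labels are 1-based
        if lac_id not in footprint_dist:
            comp = gt_lacuna_labels == lac_id
            zs = np.nonzero(comp.any(axis=(1, 2)))[0]
            foot = comp[zs.min():zs.max() + 1].any(axis=0)
            dist = ndimage.distance_transform_edt(~foot) * voxel_um
            footprint_dist[lac_id] = dist
        iy = int(np.clip(round(crossing_pt[1] / voxel_um - 0.5), 0, gt_lacuna_labels.shape[1] - 1))
        ix = int(np.clip(round(crossing_pt[2] / voxel_um - 0.5), 0, gt_lacuna_labels.shape[2] - 1))
        d_um = float(footprint_dist[lac_id][iy, ix])
        can.crossing_distance_um = d_um
        within = d_um <= params.counting_radius_um
        cc = counts[can.source_lacuna]
        if within:
            cc.within += 1
        else:
            cc.beyond += 1
        records.append(
            {
                "canaliculus": idx,
                "source_lacuna": can.source_lacuna,
                "crossing_point_um": tuple(float(c) for c in crossing_pt),
                "distance_um": d_um,
                "within": bool(within),
            }
        )
    return counts, records


def generate_phantom(params: PhantomParams) -> tuple[Volume, GroundTruth]:
    """Rasterize a phantom and its ground truth.

    Deterministic for a fixed ``params.seed`` (which drives only the
    additive Gaussian noise); ground truth is computed on the noise-free
    rasterization.
    """
    params.validate()
    shape = tuple(params.grid_shape)
    voxel_um = params.voxel_size_um
    z_um = _axis_coords(shape[0], voxel_um)
    y_um = _axis_coords(shape[1], voxel_um)
    x_um = _axis_coords(shape[2], voxel_um)

    # regions and cement sheets (slabs along x, wavy boundaries)
    region_labels = np.ones(shape, dtype=np.uint8)
    cement_mask = np.zeros(shape, dtype=bool)
    surfaces = []
    for k in range(params.n_regions - 1):
        surf = _surface_x(params, y_um, z_um, k)  # (nz, ny)
        surfaces.append(surf)
        region_labels += (x_um[None, None, :] >= surf[:, :, None]).astype(np.uint8)
        cement_mask |= (
            np.abs(x_um[None, None, :] - surf[:, :, None])
            <= params.cement_thickness_um / 2
        )

    gv = np.asarray(params.region_gv_means, dtype=np.float32)[region_labels - 1]
    gv[cement_mask] = params.cement_gv

    canal_mask = np.zeros(shape, dtype=bool)
    for can in params.canaliculus_specs:
        canal_mask |= _rasterize_tube(shape, voxel_um, can.path, can.radius_um)

    lacuna_labels = np.zeros(shape, dtype=np.int32)
    for i, lac in enumerate(params.lacuna_specs):
        ell = _rasterize_ellipsoid(shape, voxel_um, lac.center, lac.semi_axes)
        lacuna_labels[ell] = i + 1

    speck_mask = np.zeros(shape, dtype=bool)
    for sp in params.speck_specs:
        speck_mask |= _rasterize_ellipsoid(
            shape, voxel_um, sp.center, (sp.radius_um,) * 3
        )

    vessel_mask = np.zeros(shape, dtype=bool)
    for ves in params.vessel_specs:
        vessel_mask |= _rasterize_tube(shape, voxel_um, ves.path, ves.radius_um)

    pore = canal_mask | (lacuna_labels > 0) | speck_mask | vessel_mask
    gv[pore] = params.lacuna_gv

    canal_only = canal_mask & (lacuna_labels == 0) & ~speck_mask & ~vessel_mask
    mineral = ~pore
    porosity = {}
    for r in range(1, params.n_regions + 1):
        in_r = region_labels == r
        n_min = int(np.count_nonzero(mineral & in_r))
        n_can = int(np.count_nonzero(canal_only & in_r))
        porosity[r] = n_can / n_min if n_min else float("nan")

    counts, records = _classify_crossings(params, lacuna_labels)

    ground_truth = GroundTruth(
        region_labels=region_labels,
        lacuna_labels=lacuna_labels,
        canaliculus_mask=canal_only,
        speck_mask=speck_mask,
        vessel_mask=vessel_mask,
        cement_mask=cement_mask,
        true_crossing_counts=counts,
        crossing_records=records,
        analytic_region_porosity=porosity,
        cement_surface={
            "positions_um": [float(s.mean()) for s in surfaces],
            "amplitude_um": params.cement_wave_amplitude_um,
            "period_um": params.cement_wave_period_um,
            "period_z_um": params.cement_wave_period_z_um
            or 1.6 * params.cement_wave_period_um,
            "thickness_um": params.cement_thickness_um,
        },
        counting_radius_um=params.counting_radius_um,
        voxel_size_nm=params.voxel_size_nm,
    )

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        gv = gv + rng.normal(0.0, params.noise_sd, size=shape).astype(np.float32)
    data = np.clip(np.rint(gv), 0, 65535).astype(np.uint16)
    return Volume(data=data, voxel_size_nm=params.voxel_size_nm), ground_truth


def default_validation_params(seed: int = 0, noise_sd: float = 7.0) -> PhantomParams:
    """Parameters of the documented validation fixture.

    A 40 x 60 x 60 um grid at 250 nm voxels with two remodeling regions
    separated by a wavy cement line at x ~ 30 um, five lacunae (one clipped
    at the z=0 face, one in the older region), crossing / loop / intra-region
    canaliculi, one detached tube, and sub-filter noise specks.  Geometry is
    fixed; ``seed`` drives only the additive noise.
    """
    lacunae = [
        LacunaSpec(center=(10.0, 14.0, 20.0), semi_axes=(3.0, 6.0, 3.0)),   # L0 young
        LacunaSpec(center=(20.0, 44.0, 22.0), semi_axes=(3.0, 6.0, 3.0)),   # L1 young
        LacunaSpec(center=(10.0, 30.0, 45.0), semi_axes=(3.0, 5.0, 3.0)),   # L2 old
        LacunaSpec(center=(30.0, 30.0, 8.0), semi_axes=(3.0, 5.0, 3.0)),    # L3 young
        LacunaSpec(center=(2.0, 54.0, 15.0), semi_axes=(3.0, 5.0, 3.0),
                   touches_boundary=True),                                   # L4 at z=0
    ]
    r = 0.4
    canaliculi = [
        # three crossings from L1, all well within the counting radius
        CanaliculusSpec(np.array([[20.0, 44.0, 23.0], [20.0, 44.0, 36.0]]), r,
                        "crossing", source_lacuna=1),
        CanaliculusSpec(np.array([[18.5, 41.0, 23.5], [18.5, 39.0, 36.0]]), r,
                        "crossing", source_lacuna=1),
        CanaliculusSpec(np.array([[21.5, 47.0, 23.5], [21.5, 49.0, 36.0]]), r,
                        "crossing", source_lacuna=1),
        # loop from L1 approaching the cement line without touching it
        CanaliculusSpec(np.array([[20.0, 41.0, 23.5], [20.0, 39.0, 25.8],
                                  [20.0, 40.5, 22.5]]), r, "loop", source_lacuna=1),
        # one near crossing from L0
        CanaliculusSpec(np.array([[10.0, 14.0, 21.0], [10.0, 14.0, 36.0]]), r,
                        "crossing", source_lacuna=0),
        # long wandering canaliculus from L0 crossing far beyond the radius;
        # it leaves L0's slice window (z rises to 14 um) before nearing other lacunae
        CanaliculusSpec(np.array([[10.0, 16.0, 22.5], [10.0, 30.0, 25.5],
                                  [14.0, 44.0, 26.0], [14.0, 52.0, 27.5],
                                  [14.0, 56.0, 36.0]]), r,
                        "crossing", source_lacuna=0),
        # mid-distance crossing from L3
        CanaliculusSpec(np.array([[30.0, 30.0, 10.0], [30.0, 30.0, 33.0]]), r,
                        "crossing", source_lacuna=3),
        # intra-region tubes
        CanaliculusSpec(np.array([[30.0, 22.0, 6.0], [30.0, 16.0, 12.0]]), r,
                        "intra_region", source_lacuna=3),
        CanaliculusSpec(np.array([[10.0, 34.0, 47.0], [10.0, 40.0, 54.0]]), r,
                        "intra_region", source_lacuna=2),
        # detached tube in the younger region
        CanaliculusSpec(np.array([[33.0, 50.0, 10.0], [33.0, 56.0, 16.0]]), r,
                        "intra_region"),
    ]
    # a vascular canal running through the whole stack in the younger region:
    # part of the low-intensity mask (B) but neither lacuna nor canaliculus
    vessels = [
        VesselSpec(np.array([[-1.0, 10.0, 12.0], [41.0, 10.0, 12.0]]), 3.5),
    ]
    speck_rng = np.random.default_rng(20260928)  # geometry is seed-independent
    specks = []
    for _ in range(10):
        z = speck_rng.uniform(25, 38)
        y = speck_rng.uniform(5, 25)
        x = speck_rng.uniform(34, 56)
        specks.append(SpeckSpec(center=(z, y, x), radius_um=0.5))
    return PhantomParams(
        grid_shape=(160, 240, 240),
        voxel_size_nm=250.0,
        region_gv_means=(170.0, 180.0),
        cement_gv=200.0,
        cement_thickness_um=2.0,
        cement_wave_amplitude_um=2.0,
        cement_wave_period_um=25.0,
        cement_wave_period_z_um=40.0,
        cement_positions_um=(30.0,),
        lacuna_specs=lacunae,
        canaliculus_specs=canaliculi,
        speck_specs=specks,
        vessel_specs=vessels,
        lacuna_gv=25.0,
        noise_sd=noise_sd,
        seed=seed,
    )


def default_validation_phantom(seed: int = 0, noise_sd: float = 7.0):
    """Generate the documented validation fixture (see default_validation_params)."""
    return generate_phantom(default_validation_params(seed=seed, noise_sd=noise_sd))


def projected_porosity_oracle(
    gt: GroundTruth, windows: list[tuple[int, int]]
) -> dict[int, float]:
    """Noise-free projected-porosity reference computed from ground-truth masks.

    For each projection window the canalicular and lacunar rasterizations
    are collapsed by logical OR along z and regions by per-pixel majority
    label; the pooled canalicular / mineral pixel ratio per region follows
    the same ratio-of-sums pooling as the pipeline but is independent of
    the gray-value segmentation it validates.
    """
    n_regions = int(gt.region_labels.max())
    num = {r: 0 for r in range(1, n_regions + 1)}
    den = {r: 0 for r in range(1, n_regions + 1)}
    for start, stop in windows:
        canal2d = gt.canaliculus_mask[start:stop].any(axis=0)
        lac2d = (
            (gt.lacuna_labels[start:stop] > 0) | gt.vessel_mask[start:stop]
        ).any(axis=0)
        counts = np.stack([
            (gt.region_labels[start:stop] == r).sum(axis=0)
            for r in range(1, n_regions + 1)
        ])
        region2d = np.argmax(counts, axis=0) + 1
        for r in range(1, n_regions + 1):
            in_r = region2d == r
            num[r] += int(np.count_nonzero(in_r & canal2d & ~lac2d))
            den[r] += int(np.count_nonzero(in_r & ~canal2d & ~lac2d))
    return {r: (num[r] / den[r] if den[r] else float("nan")) for r in num}


def phantom_with_noise(params: PhantomParams, seed: int, noise_sd: float):
    """Convenience: regenerate the same geometry with a different noise field."""
    return generate_phantom(replace(params, seed=seed, noise_sd=noise_sd))
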