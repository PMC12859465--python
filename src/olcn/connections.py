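"""Per-lacuna counting of canalicular connections crossing the cement line.

For every candidate lacuna (near the cement line, in the locally younger
region, fully inside the scan) a dedicated minimum-intensity projection is
built over exactly the slices containing the lacuna; gray, lacunar and
regional masks are projected over the identical window.  The canalicular
2D segmentation is combined with the target lacuna's footprint (other
lacunae removed) and the connected component containing the lacuna is the
canalicular cluster.  The interface toward the older region is the 2D
dilation-minus-original band (3 px); connected components of
cluster AND band within 25 um of the lacuna footprint are counted as
N.Conn, the number of cross-generational canalicular connections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._morphology import ball_dilate, label_components
from .mineralization import RegionStats
from .porosity import min_intensity_projections, project_labels, segment_canaliculi_2d
from .region_masks import InterfaceBand, RegionMaskSet, interface_band
from .volume_io import Volume

DEFAULT_RADIUS_UM = 25.0


@dataclass
class LacunaCandidate:
    """A lacuna eligible for connection counting."""

    lacuna_id: int
    region_id: int
    neighbor_region_id: int
    slice_range: tuple[int, int]  # half-open
    centroid_um: tuple[float, float, float]
    distance_to_interface_um: float
    fully_inside: bool = True


@dataclass
class ConnectionResult:
    """N.Conn for one lacuna, with the context needed for the GV relation."""

    lacuna_id: int
    n_conn: int
    radius_um: float
    region_id: int | None = None
    neighbor_region_id: int | None = None
    own_region_norm_gv: float = float("nan")
    neighbor_region_norm_gv: float = float("nan")
    crossing_distances_um: list[float] = field(default_factory=list)


def _touches_face(component: np.ndarray) -> bool:
    return bool(
        component[0].any() or component[-1].any()
        or component[:, 0].any() or component[:, -1].any()
        or component[:, :, 0].any() or component[:, :, -1].any()
    )


def select_lacunae(
    lacuna_labels: np.ndarray,
    masks: RegionMaskSet,
    stats: list[RegionStats],
    voxel_size_nm: float,
    proximity_um: float = DEFAULT_RADIUS_UM,
) -> list[LacunaCandidate]:
    """Candidate lacunae: fully inside, locally younger, near an older region.

    A lacuna qualifies when its component touches no volume face, its
    majority region is younger (lower rank) than some other region, and
    its surface lies within ``proximity_um`` of such an older region; the
    nearest older region becomes the neighbor.
    """
    voxel_um = voxel_size_nm / 1000.0
    ranks = {s.region_id: s.rank for s in stats if s.rank is not None}
    if not ranks:
        raise ValueError("region ranks must be computed before lacuna selection")
    older_dist: dict[int, np.ndarray] = {}

    def _dist_to(region: int) -> np.ndarray:
        if region not in older_dist:  # computed lazily: only older regions need it
            older_dist[region] = (
                ndimage.distance_transform_edt(masks.mask_a != region) * voxel_um
            )
        return older_dist[region]

    from .mineralization import assign_lacunae_to_regions

    assignment = assign_lacunae_to_regions(lacuna_labels, masks)
    candidates = []
    objects = ndimage.find_objects(lacuna_labels)
    for lac, region in sorted(assignment.items()):
        if region not in ranks:
            continue
        comp = lacuna_labels == lac
        if _touches_face(comp):
            continue
        older = [r for r, rank in ranks.items() if rank > ranks[region]]
        if not older:
            continue
        dists = {r: float(_dist_to(r)[comp].min()) for r in older}
        neighbor = min(dists, key=lambda r: (dists[r], r))
        if dists[neighbor] > proximity_um:
            continue
        sl = objects[lac - 1]
        centroid = ndimage.center_of_mass(comp)
        candidates.append(
            LacunaCandidate(
                lacuna_id=lac,
                region_id=region,
                neighbor_region_id=neighbor,
                slice_range=(sl[0].start, sl[0].stop),
                centroid_um=tuple(float(c) * voxel_um for c in centroid),
                distance_to_interface_um=dists[neighbor],
            )
        )
    return candidates


@dataclass
class LacunaCluster:
    """Projection bundle and canalicular cluster for one candidate lacuna."""

    candidate: LacunaCandidate
    cluster: np.ndarray  # bool 2D: lacuna footprint + connected canaliculi
    footprint: np.ndarray  # bool 2D: target lacuna alone
    region_proj: np.ndarray  # 2D region labels over the same window
    canal_mask: np.ndarray


def lacuna_cluster(
    volume: Volume,
    lacuna_labels: np.ndarray,
    masks: RegionMaskSet,
    candidate: LacunaCandidate,
    tophat_radius_px: int = 10,
    min_component_px: int = 100,
    bridge_px: float = 2,
) -> LacunaCluster:
    """Build the canalicular cluster connected to one lacuna.

    Minimum-intensity projection over exactly the slices containing the
    lacuna, canalicular segmentation on it, other lacunae removed from the
    lacunar projection, target lacuna OR-ed into the canalicular mask, and
    the 8-connected component containing the lacuna kept.

    The top-hat's closing reconstructs the dark lacuna slightly (1-2 px)
    beyond the segmented footprint, which leaves a thin low-response ring
    around the lacuna; ``bridge_px`` dilates the footprint added to the
    canalicular mask just enough to span that ring so canaliculi emerging
    from the lacuna stay attached.  Distances are always measured from the
    undilated footprint.
    """
    start, stop = candidate.slice_range
    if not (0 <= start < stop <= volume.shape[0]):
        raise ValueError(f"slice range {candidate.slice_range} outside the volume")
    sub = Volume(volume.data[start:stop], volume.voxel_size_nm)
    pset = min_intensity_projections(sub, window_slices=stop - start, n_projections=1)
    gray_proj = pset.projections[0]
    lac_proj = project_labels(lacuna_labels[start:stop], pset)[0]
    region_proj = project_labels(masks.mask_a[start:stop], pset)[0]
    footprint = lac_proj == candidate.lacuna_id
    if not footprint.any():
        raise ValueError(
            f"lacuna {candidate.lacuna_id} absent from its own projection window"
        )
    canal_mask = segment_canaliculi_2d(
        gray_proj, tophat_radius_px=tophat_radius_px, min_component_px=min_component_px
    )
    # other lacunae are excluded: only the target lacuna is added back
    combined = canal_mask | ball_dilate(footprint, bridge_px)
    labels, _ = label_components(combined, connectivity="full")
    target_ids = np.unique(labels[footprint])
    target_ids = target_ids[target_ids > 0]
    cluster = np.isin(labels, target_ids)
    return LacunaCluster(
        candidate=candidate,
        cluster=cluster,
        footprint=footprint,
        region_proj=region_proj,
        canal_mask=canal_mask,
    )


def count_connections(
    cluster: np.ndarray,
    band: InterfaceBand,
    lacuna_footprint: np.ndarray,
    radius_um: float = DEFAULT_RADIUS_UM,
    voxel_size_nm: float = 250.0,
    distance_mode: str = "surface",
) -> ConnectionResult:
    """Count interface-crossing canalicular components within the radius.

    The cluster is intersected with the interface band; each 8-connected
    component of the intersection is one candidate crossing and counts iff
    its minimum pixel distance to the lacuna footprint (``surface`` mode;
    ``centroid`` measures from the footprint centroid) is at most
    ``radius_um``.  Two canaliculi merging before the band count once.
    """
    voxel_um = voxel_size_nm / 1000.0
    cluster = np.asarray(cluster, bool)
    footprint = np.asarray(lacuna_footprint, bool)
    if cluster.shape != band.mask.shape or cluster.shape != footprint.shape:
        raise ValueError("cluster, band and footprint shapes disagree")
    if not band.mask.any():
        warnings.warn("empty interface band: no older neighbor in this window",
                      stacklevel=2)
        return ConnectionResult(lacuna_id=-1, n_conn=0, radius_um=radius_um)
    if distance_mode == "surface":
        dist = ndimage.distance_transform_edt(~footprint) * voxel_um
    elif distance_mode == "centroid":
        cy, cx = ndimage.center_of_mass(footprint)
        yy, xx = np.indices(footprint.shape)
        dist = np.hypot(yy - cy, xx - cx) * voxel_um
    else:
        raise ValueError(f"unknown distance mode {distance_mode!r}")
    intersection = cluster & band.mask
    labels, n = label_components(intersection, connectivity="full")
    distances = []
    n_conn = 0
    for comp in range(1, n + 1):
        d = float(dist[labels == comp].min())
        distances.append(d)
        if d <= radius_um:
            n_conn += 1
    return ConnectionResult(
        lacuna_id=-1,
        n_conn=n_conn,
        radius_um=radius_um,
        crossing_distances_um=sorted(distances),
    )


def analyze_connections(
    volume: Volume,
    lacuna_labels: np.ndarray,
    masks: RegionMaskSet,
    stats: list[RegionStats],
    radius_um: float = DEFAULT_RADIUS_UM,
    band_dilation_px: float = 3,
    proximity_um: float = DEFAULT_RADIUS_UM,
    tophat_radius_px: int = 10,
    min_component_px: int = 100,
    bridge_px: float = 2,
    distance_mode: str = "surface",
) -> list[ConnectionResult]:
    """Select candidates, build clusters and count N.Conn for each."""
    stats_by_id = {s.region_id: s for s in stats}
    candidates = select_lacunae(
        lacuna_labels, masks, stats, volume.voxel_size_nm, proximity_um
    )
    results = []
    for cand in candidates:
        cl = lacuna_cluster(
            volume, lacuna_labels, masks, cand,
            tophat_radius_px=tophat_radius_px, min_component_px=min_component_px,
            bridge_px=bridge_px,
        )
        band2d = interface_band(cl.region_proj, cand.neighbor_region_id,
                                band_dilation_px)
        res = count_connections(
            cl.cluster, band2d, cl.footprint, radius_um,
            volume.voxel_size_nm, distance_mode,
        )
        res.lacuna_id = cand.lacuna_id
        res.region_id = cand.region_id
        res.neighbor_region_id = cand.neighbor_region_id
        own = stats_by_id.get(cand.region_id)
        nb = stats_by_id.get(cand.neighbor_region_id)
        if own is not None:
            res.own_region_norm_gv = own.norm_mean_gv
        if nb is not None:
            res.neighbor_region_norm_gv = nb.norm_mean_gv
        results.append(res)
    return results


def connection_table(
    results: list[ConnectionResult],
    stats: list[RegionStats],
    porosity_by_region: dict[int, float] | None = None,
    sample: str = "sample",
) -> list[dict]:
    """Per-lacuna records joining N.Conn with regional context."""
    stats_by_id = {s.region_id: s for s in stats}
    rows = []
    for res in results:
        nb = stats_by_id.get(res.neighbor_region_id)
        row = {
            "sample": sample,
            "lacuna_id": res.lacuna_id,
            "n_conn": res.n_conn,
            "own_region_norm_gv": res.own_region_norm_gv,
            "neighbor_region_norm_gv": res.neighbor_region_norm_gv,
            "neighbor_region_pcan_p": (
                porosity_by_region.get(res.neighbor_region_id, float("nan"))
                if porosity_by_region else float("nan")
            ),
            "flagged": nb is None or not np.isfinite(res.neighbor_region_norm_gv),
        }
        rows.append(row)
    return rows
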