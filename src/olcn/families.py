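"""Phantom families for statistical-property validation.

Single phantoms validate the image-processing oracles; the statistical
claims (younger regions carry denser canalicular networks; network
integration falls with the neighboring region's mineralization) need
*families* of phantoms with controlled generating parameters.  Two small
desk-scale families are provided:

* a porosity family — paired young/old regions whose generated tube
  density differs by a configurable ratio, analyzed with the real
  projection + top-hat segmentation path, yielding (rank, pCan.P) records
  for the group t-test;
* a connection family — one lacuna per member whose number of generated
  interface crossings varies monotonically with the older region's gray
  value, analyzed with the real counting path, yielding
  (N.Conn, neighbor normalized mean GV) records for the correlation test.

Family members use smaller grids than the validation fixture (the 25 um
counting radius spans the whole member, so every crossing is countable)
and correspondingly reduced erosion radii via the standard config keys.
"""

from __future__ import annotations

import numpy as np

from .connections import analyze_connections
from .mineralization import (
    low_intensity_mask,
    rank_regions,
    regional_mean_gv,
    segment_lacunae,
)
from .phantom import (
    CanaliculusSpec,
    LacunaSpec,
    PhantomParams,
    generate_phantom,
)
from .porosity import compute_porosity
from .region_masks import supplied_region_mask


def _random_in_plane_tube(rng, z_range, y_range, x_range, length_um, radius_um):
    z = rng.uniform(*z_range)
    y0 = rng.uniform(*y_range)
    x0 = rng.uniform(*x_range)
    theta = rng.uniform(0, 2 * np.pi)
    dy, dx = length_um * np.sin(theta), length_um * np.cos(theta)
    y1 = float(np.clip(y0 + dy, *y_range))
    x1 = float(np.clip(x0 + dx, *x_range))
    return CanaliculusSpec(
        np.array([[z, y0, x0], [z, y1, x1]]), radius_um, "intra_region"
    )


def porosity_family_phantom(
    seed: int,
    young_tubes: int = 8,
    old_tubes: int = 4,
    noise_sd: float = 5.0,
):
    """One member of the porosity family: 16 x 24 x 24 um, two regions.

    Tube counts per region set the generated network-density ratio
    (default 2:1 young:old).
    """
    rng = np.random.default_rng(seed)
    tubes = []
    for _ in range(young_tubes):
        tubes.append(_random_in_plane_tube(
            rng, (1.0, 15.0), (1.0, 23.0), (1.0, 9.4), 12.0, 0.4))
    for _ in range(old_tubes):
        tubes.append(_random_in_plane_tube(
            rng, (1.0, 15.0), (1.0, 23.0), (14.6, 23.0), 12.0, 0.4))
    params = PhantomParams(
        grid_shape=(64, 96, 96),
        voxel_size_nm=250.0,
        region_gv_means=(170.0, 180.0),
        cement_gv=200.0,
        cement_thickness_um=1.0,
        cement_wave_amplitude_um=1.0,
        cement_wave_period_um=12.0,
        cement_positions_um=(12.0,),
        canaliculus_specs=tubes,
        lacuna_gv=25.0,
        noise_sd=noise_sd,
        seed=seed,
    )
    return generate_phantom(params)


def porosity_family_records(
    n_members: int = 6,
    seed: int = 0,
    young_tubes: int = 8,
    old_tubes: int = 4,
    noise_sd: float = 5.0,
) -> list[tuple[int, float]]:
    """(rank, pCan.P) records over the family, via the real porosity path.

    Ranks follow the generating order (region 1 young, region 2 old); the
    members carry no lacunae, so the lacunar projection is empty.
    """
    records = []
    for i in range(n_members):
        volume, gt = porosity_family_phantom(
            seed * 1000 + i, young_tubes, old_tubes, noise_sd
        )
        empty_lacunae = np.zeros(volume.shape, dtype=np.int32)
        _, _, porosity = compute_porosity(
            volume, gt.region_labels, empty_lacunae,
            window_slices=32, n_projections=2,
        )
        for p in porosity:
            if p.valid:
                records.append((p.region_id, p.pcan_p))
    return records


def connection_family_phantom(
    seed: int,
    n_crossings: int,
    old_gv: float,
    noise_sd: float = 5.0,
):
    """One member of the connection family: 12 x 16 x 16 um, one lacuna.

    ``n_crossings`` canaliculi cross the cement line at x = 8 um from the
    lacuna in the younger region toward a lacuna in the older region (each
    region needs a lacuna for its normalized mean GV); ``old_gv`` sets the
    older region's mean gray value (and with it the neighbor's norm. GV).
    """
    lacunae = [
        LacunaSpec(center=(6.0, 8.0, 4.5), semi_axes=(2.0, 3.0, 2.0)),
        LacunaSpec(center=(6.0, 8.0, 13.0), semi_axes=(2.0, 3.0, 2.0)),
    ]
    tubes = []
    for j in range(n_crossings):
        y = 5.0 + 2.0 * j
        tubes.append(CanaliculusSpec(
            np.array([[6.0, y, 5.5], [6.0, y, 12.0]]), 0.4,
            "crossing", source_lacuna=0,
        ))
    params = PhantomParams(
        grid_shape=(48, 64, 64),
        voxel_size_nm=250.0,
        region_gv_means=(170.0, float(old_gv)),
        cement_gv=230.0,
        cement_thickness_um=1.0,
        cement_wave_amplitude_um=0.5,
        cement_wave_period_um=8.0,
        cement_positions_um=(8.0,),
        lacuna_specs=lacunae,
        canaliculus_specs=tubes,
        lacuna_gv=25.0,
        noise_sd=noise_sd,
        seed=seed,
    )
    return generate_phantom(params)


def connection_family_records(
    n_members: int = 8,
    seed: int = 0,
    direction: str = "decreasing",
    noise_sd: float = 5.0,
) -> list[tuple[int, float]]:
    """(N.Conn, neighbor norm GV) records via the real counting path.

    ``direction`` controls whether the generated crossing count decreases
    or increases with the older region's gray value.
    """
    records = []
    for i in range(n_members):
        # a realistic, subtle mineralization sweep: the pore/mineral contrast
        # must stay dominant for the global Otsu mask to be meaningful
        old_gv = 174.0 + 2.0 * i
        frac = i / max(1, n_members - 1)
        n_cross = round(1 + 3 * (1 - frac if direction == "decreasing" else frac))
        volume, gt = connection_family_phantom(seed * 1000 + i, n_cross, old_gv,
                                               noise_sd)
        masks = supplied_region_mask(gt.region_labels)
        mask_b = low_intensity_mask(volume)
        seg = segment_lacunae(volume)
        stats = rank_regions(regional_mean_gv(
            volume, masks, mask_b, seg.labels,
            region_erosion_radius_px=6, b_dilation_px=3, c_erosion_px=3,
        ))
        results = analyze_connections(volume, seg.labels, masks, stats)
        for res in results:
            records.append((res.n_conn, res.neighbor_region_norm_gv))
    return records
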