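import dataclasses

import numpy as np
import pytest

from olcn.connections import (
    ConnectionResult,
    connection_table,
    count_connections,
    select_lacunae,
)
from olcn.mineralization import (
    RegionStats,
    low_intensity_mask,
    rank_regions,
    regional_mean_gv,
    segment_lacunae,
)
from olcn.phantom import default_validation_params, generate_phantom
from olcn.region_masks import InterfaceBand, supplied_region_mask
from tests.conftest import count_connections_vs_truth


def _band(shape, col_range):
    mask = np.zeros(shape, dtype=bool)
    mask[:, col_range[0]:col_range[1]] = True
    return InterfaceBand(mask=mask, older_label=2, dilation_px=3)


def _scene():
    """Footprint at the left edge, two crossings near, one far (200x400 px)."""
    shape = (200, 400)
    footprint = np.zeros(shape, dtype=bool)
    footprint[90:110, 5:25] = True
    cluster = footprint.copy()
    for row in (60, 140):  # near crossings: ~ (100-140 px) from footprint
        cluster[row:row + 3, 25:165] = True
    cluster[4:7, 25:165] = True  # far crossing: ~ 86 px vertically above
    return shape, footprint, cluster


def _brute_force_component_distances(cluster, band_mask, footprint, voxel_um):
    """Per band-component min pixel distance to the footprint, by full scan."""
    from scipy import ndimage

    labels, n = ndimage.label(cluster & band_mask, structure=np.ones((3, 3)))
    fp = np.argwhere(footprint)
    out = []
    for comp in range(1, n + 1):
        pix = np.argwhere(labels == comp)
        d = np.sqrt(((pix[:, None, :] - fp[None, :, :]) ** 2).sum(-1)).min()
        out.append(float(d) * voxel_um)
    return sorted(out)


def test_components_counted_within_radius_only():
    shape, footprint, cluster = _scene()
    band = _band(shape, (160, 164))
    voxel_nm = 250.0  # 25 um radius = 100 px
    res = count_connections(cluster, band, footprint, radius_um=25.0,
                            voxel_size_nm=voxel_nm)
    expected = _brute_force_component_distances(
        cluster, band.mask, footprint, voxel_nm / 1000.0
    )
    assert len(expected) == 3
    assert res.crossing_distances_um == pytest.approx(expected, abs=1e-9)
    assert res.n_conn == sum(d <= 25.0 for d in expected)

    wider = count_connections(cluster, band, footprint, radius_um=60.0,
                              voxel_size_nm=voxel_nm)
    assert wider.n_conn == 3


def test_n_conn_monotone_in_radius():
    shape, footprint, cluster = _scene()
    band = _band(shape, (160, 164))
    counts = [
        count_connections(cluster, band, footprint, radius_um=r,
                          voxel_size_nm=250.0).n_conn
        for r in (5.0, 25.0, 40.0, 60.0)
    ]
    assert counts == sorted(counts)
    assert counts[-1] == 3


def test_disjoint_band_components_of_one_tube_count_separately():
    # a tube grazing a wavy interface: its band intersection splits in two
    shape = (60, 120)
    footprint = np.zeros(shape, dtype=bool)
    footprint[25:35, 2:10] = True
    cluster = footprint.copy()
    cluster[29:31, 10:100] = True
    band = np.zeros(shape, dtype=bool)
    band[29:31, 40:44] = True
    band[29:31, 70:74] = True
    res = count_connections(
        cluster, InterfaceBand(band, 2, 3), footprint,
        radius_um=25.0, voxel_size_nm=250.0,
    )
    assert res.n_conn == 2


def test_empty_band_warns_and_counts_zero():
    shape, footprint, cluster = _scene()
    empty = InterfaceBand(np.zeros(shape, dtype=bool), 2, 3)
    with pytest.warns(UserWarning, match="empty interface band"):
        res = count_connections(cluster, empty, footprint)
    assert res.n_conn == 0


def test_candidate_selection_criteria(clean_phantom, clean_lacuna_seg,
                                      clean_region_stats):
    volume, gt = clean_phantom
    masks = supplied_region_mask(gt.region_labels)
    cands = select_lacunae(clean_lacuna_seg.labels, masks, clean_region_stats,
                           volume.voxel_size_nm)
    gt_of_seg = {}
    for lab in range(1, clean_lacuna_seg.n_lacunae + 1):
        sel = clean_lacuna_seg.labels == lab
        gt_of_seg[lab] = int(np.bincount(gt.lacuna_labels[sel]).argmax()) - 1
    selected_gt = sorted(gt_of_seg[c.lacuna_id] for c in cands)
    # fixture truth: lacunae 0, 1, 3 are young, fully inside and near the
    # interface; 2 sits in the older region; 4 touches the z=0 face
    assert selected_gt == [0, 1, 3]
    for c in cands:
        assert c.region_id == 1 and c.neighbor_region_id == 2
        assert c.distance_to_interface_um <= 25.0


def test_noise_free_counts_equal_ground_truth(clean_phantom, clean_counting):
    _, gt = clean_phantom
    expected = {
        idx: cc.within
        for idx, cc in gt.true_crossing_counts.items()
        if idx in clean_counting
    }
    assert clean_counting == expected
    assert len(clean_counting) == 3


def test_removing_one_crossing_lowers_count_by_one(clean_counting):
    params = default_validation_params(seed=1, noise_sd=0.0)
    # drop one within-radius crossing that originates from lacuna 1
    kept = [c for i, c in enumerate(params.canaliculus_specs) if i != 1]
    params = dataclasses.replace(params, canaliculus_specs=kept)
    volume, gt = generate_phantom(params)
    assert gt.true_crossing_counts[1].within == 2
    measured = count_connections_vs_truth(volume, gt)
    assert measured[1] == clean_counting[1] - 1


def test_connection_table_joins_and_flags():
    stats = rank_regions([
        RegionStats(region_id=1, norm_mean_gv=2.2),
        RegionStats(region_id=2, norm_mean_gv=3.1),
    ])
    results = [
        ConnectionResult(lacuna_id=1, n_conn=2, radius_um=25.0, region_id=1,
                         neighbor_region_id=2, own_region_norm_gv=2.2,
                         neighbor_region_norm_gv=3.1),
        ConnectionResult(lacuna_id=2, n_conn=0, radius_um=25.0, region_id=1,
                         neighbor_region_id=9),  # missing neighbor stats
    ]
    rows = connection_table(results, stats, {2: 0.02}, sample="s1")
    assert len(rows) == 2
    assert set(rows[0]) >= {"sample", "lacuna_id", "n_conn",
                            "own_region_norm_gv", "neighbor_region_norm_gv"}
    assert rows[0]["neighbor_region_pcan_p"] == 0.02
    assert not rows[0]["flagged"] and rows[1]["flagged"]


def test_cluster_excludes_detached_tube(clean_phantom, clean_lacuna_seg,
                                        clean_region_stats):
    from olcn.connections import lacuna_cluster
    from olcn.phantom import _rasterize_tube

    volume, gt = clean_phantom
    masks = supplied_region_mask(gt.region_labels)
    cands = select_lacunae(clean_lacuna_seg.labels, masks, clean_region_stats,
                           volume.voxel_size_nm)
    params = default_validation_params()
    detached = params.canaliculus_specs[-1]  # tube with no source lacuna
    tube3d = _rasterize_tube(tuple(params.grid_shape), params.voxel_size_um,
                             detached.path, detached.radius_um)
    for cand in cands:
        cl = lacuna_cluster(volume, clean_lacuna_seg.labels, masks, cand)
        start, stop = cand.slice_range
        tube2d = tube3d[start:stop].any(axis=0)
        assert not (cl.cluster & tube2d).any()
        # the lacuna footprint itself always belongs to its cluster
        assert (cl.cluster & cl.footprint).sum() == cl.footprint.sum()
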