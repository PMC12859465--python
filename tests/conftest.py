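import numpy as np
import pytest

from olcn.connections import analyze_connections
from olcn.mineralization import (
    low_intensity_mask,
    rank_regions,
    regional_mean_gv,
    segment_lacunae,
)
from olcn.phantom import default_validation_phantom
from olcn.porosity import compute_porosity
from olcn.region_masks import supplied_region_mask

FIXTURE_WINDOW_SLICES = 40
FIXTURE_N_PROJECTIONS = 4


@pytest.fixture(scope="session")
def fixture_windows():
    """Projection windows used for the validation fixture (4 x 40 slices)."""
    return [(i * FIXTURE_WINDOW_SLICES, (i + 1) * FIXTURE_WINDOW_SLICES)
            for i in range(FIXTURE_N_PROJECTIONS)]


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free validation phantom (volume, ground truth)."""
    return default_validation_phantom(seed=1, noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Validation phantom at the default noise level."""
    return default_validation_phantom(seed=1, noise_sd=7.0)


@pytest.fixture(scope="session")
def clean_lacuna_seg(clean_phantom):
    volume, _ = clean_phantom
    return segment_lacunae(volume)


@pytest.fixture(scope="session")
def clean_region_stats(clean_phantom, clean_lacuna_seg):
    volume, gt = clean_phantom
    masks = supplied_region_mask(gt.region_labels)
    mask_b = low_intensity_mask(volume)
    return rank_regions(
        regional_mean_gv(volume, masks, mask_b, clean_lacuna_seg.labels)
    )


@pytest.fixture(scope="session")
def clean_porosity(clean_phantom, clean_lacuna_seg):
    volume, gt = clean_phantom
    return compute_porosity(
        volume, gt.region_labels, clean_lacuna_seg.labels,
        window_slices=FIXTURE_WINDOW_SLICES,
        n_projections=FIXTURE_N_PROJECTIONS,
    )


def count_connections_vs_truth(volume, gt):
    """Run the counting path and key measured N.Conn by ground-truth lacuna index."""
    masks = supplied_region_mask(gt.region_labels)
    mask_b = low_intensity_mask(volume)
    seg = segment_lacunae(volume)
    stats = rank_regions(regional_mean_gv(volume, masks, mask_b, seg.labels))
    results = analyze_connections(volume, seg.labels, masks, stats)
    measured = {}
    for res in results:
        sel = seg.labels == res.lacuna_id
        gt_label = int(np.bincount(gt.lacuna_labels[sel]).argmax())
        measured[gt_label - 1] = res.n_conn
    return measured


@pytest.fixture(scope="session")
def clean_counting(clean_phantom):
    volume, gt = clean_phantom
    return count_connections_vs_truth(volume, gt)
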