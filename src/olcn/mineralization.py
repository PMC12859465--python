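"""Regional degree-of-mineralization analysis.

From a gray-value volume and a dense region mask this stage derives:

* mask B — all low-intensity elements (lacunae, canaliculi, vessels, image
  noise), one global Otsu threshold;
* mask C — lacunae: Otsu mask, opening with a ball of radius 7 voxels to
  separate touching pores, connected components (26-connectivity), size
  filter discarding components below 1500 voxels;
* per-region normalized mean gray value — mean GV of the mineralized
  matrix (region eroded by 50 px, minus mask B dilated by 10 px) divided by
  the mean GV inside that region's lacunae (mask C eroded by 10 px), which
  cancels low-frequency imaging artifacts;
* a tissue-age ranking: ascending normalized mean GV, rank 1 = youngest,
  because mineralization (and with it the gray value) increases with local
  tissue age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._morphology import (
    ball_dilate,
    ball_erode,
    ball_open,
    filter_small_components,
)
from .region_masks import RegionMaskSet
from .volume_io import Volume


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold over an ``nbins``-bin histogram of the observed range.

    Returns the gray value of the chosen bin boundary; foreground
    ("low-intensity element") is ``value <= threshold``.  Among boundaries
    with equal between-class variance the lowest is chosen.  Raises on
    constant input (degenerate histogram).
    """
    values = np.asarray(values).ravel()
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise ValueError("cannot threshold a constant sample")
    hist, edges = np.histogram(values, bins=nbins, range=(vmin, vmax))
    hist = hist.astype(np.float64)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(hist)[:-1]
    w1 = hist.sum() - w0
    m0 = np.cumsum(hist * centers)[:-1]
    m1 = (hist * centers).sum() - m0
    valid = (w0 > 0) & (w1 > 0)
    var_between = np.zeros(nbins - 1)
    var_between[valid] = (
        w0[valid] * w1[valid] * (m0[valid] / w0[valid] - m1[valid] / w1[valid]) ** 2
    )
    k = int(np.argmax(var_between))  # argmax returns the first (lowest) maximum
    return float(edges[k + 1])


def low_intensity_mask(volume: Volume, nbins: int = 256) -> np.ndarray:
    """Mask B: voxels at or below the global Otsu threshold.

    Assumes standard contrast (pores dark on bright mineral); with inverted
    contrast the caller must invert the data first.
    """
    thr = otsu_threshold(volume.data, nbins=nbins)
    return volume.data <= thr


@dataclass
class LacunaSegmentation:
    labels: np.ndarray
    n_lacunae: int
    threshold: float

    @property
    def binary(self) -> np.ndarray:
        return self.labels > 0


def segment_lacunae(
    volume: Volume,
    opening_radius_vox: float = 7,
    min_voxels: int = 1500,
    nbins: int = 256,
) -> LacunaSegmentation:
    """Mask C: Otsu mask -> opening (ball radius 7) -> components -> size filter.

    Components with fewer than ``min_voxels`` voxels are discarded (a
    component of exactly ``min_voxels`` is retained); survivors are
    relabeled compactly.  Connectivity is 26 in 3D.
    """
    thr = otsu_threshold(volume.data, nbins=nbins)
    mask = volume.data <= thr
    opened = ball_open(mask, opening_radius_vox)
    labels, n = filter_small_components(opened, min_voxels, connectivity="full")
    return LacunaSegmentation(labels=labels, n_lacunae=n, threshold=thr)


@dataclass
class RegionStats:
    """Per-region mineralization summary."""

    region_id: int
    mean_gv_mineral: float = float("nan")
    mean_gv_lacunar: float = float("nan")
    norm_mean_gv: float = float("nan")
    n_lacunae: int = 0
    rank: int | None = None
    excluded: bool = False
    notes: list[str] = field(default_factory=list)


def assign_lacunae_to_regions(
    lacuna_labels: np.ndarray, masks: RegionMaskSet
) -> dict[int, int]:
    """Region of each lacuna by majority voxel vote (ties -> lower region id)."""
    assignment: dict[int, int] = {}
    n_lac = int(lacuna_labels.max())
    for lac in range(1, n_lac + 1):
        regions = masks.mask_a[lacuna_labels == lac]
        if regions.size == 0:
            continue
        counts = np.bincount(regions, minlength=masks.n_regions + 1)
        assignment[lac] = int(np.argmax(counts[1:])) + 1
    return assignment


def regional_mean_gv(
    volume: Volume,
    masks: RegionMaskSet,
    mask_b: np.ndarray,
    lacuna_labels: np.ndarray,
    region_erosion_radius_px: float = 50,
    b_dilation_px: float = 10,
    c_erosion_px: float = 10,
) -> list[RegionStats]:
    """Normalized mean gray value per remodeling region.

    The region mask is eroded (ball radius 50 px) to exclude edge effects
    and the cement lines, mask B is dilated by 10 px and subtracted to
    leave pure mineral matrix, and mask C is eroded by 10 px to sample
    lacunar cores away from partial-volume rims.  Regions losing all
    mineral voxels or holding no lacuna are flagged and excluded.
    """
    data = volume.data
    if data.shape != masks.mask_a.shape:
        raise ValueError("volume and region mask shapes disagree")
    b_dilated = ball_dilate(np.asarray(mask_b, bool), b_dilation_px)
    c_eroded = ball_erode(lacuna_labels > 0, c_erosion_px)
    assignment = assign_lacunae_to_regions(lacuna_labels, masks)

    out = []
    for r in range(1, masks.n_regions + 1):
        stats = RegionStats(region_id=r)
        mineral = ball_erode(masks.mask_a == r, region_erosion_radius_px) & ~b_dilated
        lacunae_in_r = [lac for lac, reg in assignment.items() if reg == r]
        stats.n_lacunae = len(lacunae_in_r)
        lac_sel = np.isin(lacuna_labels, lacunae_in_r) & c_eroded if lacunae_in_r \
            else np.zeros_like(c_eroded)
        if not mineral.any():
            stats.excluded = True
            stats.notes.append("no mineral voxels survive erosion/subtraction")
        if not lac_sel.any():
            stats.excluded = True
            stats.notes.append("no eroded lacunar voxels assigned to region")
        if not stats.excluded:
            stats.mean_gv_mineral = float(data[mineral].mean())
            stats.mean_gv_lacunar = float(data[lac_sel].mean())
            stats.norm_mean_gv = stats.mean_gv_mineral / stats.mean_gv_lacunar
        out.append(stats)
    return out


def rank_regions(stats: list[RegionStats]) -> list[RegionStats]:
    """Rank regions by normalized mean GV: rank 1 = lowest = youngest.

    Ties break toward the lower region id; excluded regions stay unranked.
    """
    ranked = [s for s in stats if not s.excluded and np.isfinite(s.norm_mean_gv)]
    if not ranked:
        raise ValueError("no region with a valid normalized mean GV")
    order = sorted(ranked, key=lambda s: (s.norm_mean_gv, s.region_id))
    for rank, s in enumerate(order, start=1):
        s.rank = rank
    return stats
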