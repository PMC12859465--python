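"""Projected canalicular porosity (pCan.P).

Canaliculi are too thin to segment reliably slice-by-slice, so they are
segmented in minimum-intensity projections: per-pixel minimum gray value
over windows of consecutive slices (default 15 windows of 130 slices).
Dark tubular structures are enhanced with a black top-hat (disk radius
10 px) and thresholded with Otsu; 2D components below 100 pixels are
discarded as noise.  Companion projections of the lacunar and regional
label volumes take, per pixel, the label at the argmin slice of the gray
volume, keeping gray and label projections aligned.  Per region,

    pCan.P = sum_i pCan.V(i) / sum_i pMin.V(i)

pools canalicular pixel counts over mineral pixel counts across all
projections; the quantity is an explicitly *projected* network-density
measure, far higher than a true 3D porosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import black_tophat, disk

from ._morphology import filter_small_components
from .mineralization import otsu_threshold
from .volume_io import Volume


@dataclass
class ProjectionSet:
    """Ordered minimum-intensity projections with their slice windows."""

    projections: list[np.ndarray]
    windows: list[tuple[int, int]]  # half-open, 0-based
    argmin_slices: list[np.ndarray]  # absolute slice index of the per-pixel minimum

    def __len__(self) -> int:
        return len(self.projections)


def min_intensity_projections(
    volume: Volume,
    window_slices: int = 130,
    n_projections: int = 15,
    offset: int = 0,
) -> ProjectionSet:
    """Consecutive non-overlapping minimum-intensity projections from ``offset``.

    Trailing slices beyond ``offset + n_projections * window_slices`` are
    unused.  The per-pixel argmin slice (ties -> first slice of the window)
    is retained for aligned label projection.
    """
    nz = volume.shape[0]
    needed = offset + n_projections * window_slices
    if needed > nz:
        raise ValueError(
            f"{n_projections} projections of {window_slices} slices need "
            f"{needed} slices, volume has {nz}"
        )
    projections, windows, argmins = [], [], []
    for i in range(n_projections):
        start = offset + i * window_slices
        stop = start + window_slices
        block = volume.data[start:stop]
        arg = np.argmin(block, axis=0)
        projections.append(np.take_along_axis(block, arg[None], axis=0)[0])
        argmins.append(arg + start)
        windows.append((start, stop))
    return ProjectionSet(projections=projections, windows=windows, argmin_slices=argmins)


def project_labels(labels: np.ndarray, pset: ProjectionSet) -> list[np.ndarray]:
    """Label projections aligned with the gray projections via the argmin rule."""
    out = []
    for arg in pset.argmin_slices:
        yy, xx = np.indices(arg.shape)
        out.append(labels[arg, yy, xx])
    return out


def segment_canaliculi_2d(
    projection: np.ndarray,
    tophat_radius_px: int = 10,
    min_component_px: int = 100,
    nbins: int = 256,
) -> np.ndarray:
    """Segment dark tubular structures in one minimum-intensity projection.

    Black top-hat (closing minus image, disk radius ``tophat_radius_px``)
    -> Otsu on the response (foreground = response >= threshold) ->
    8-connected components -> drop components below ``min_component_px``
    pixels.  A constant projection yields an empty mask.
    """
    projection = np.asarray(projection)
    response = black_tophat(projection, footprint=disk(tophat_radius_px))
    try:
        thr = otsu_threshold(response, nbins=nbins)
    except ValueError:
        return np.zeros(projection.shape, dtype=bool)
    mask = response >= thr
    labels, _ = filter_small_components(mask, min_component_px, connectivity="full")
    return labels > 0


@dataclass
class RegionalPorosity:
    """Per-region canalicular / mineral pixel tallies and the pooled ratio."""

    region_id: int
    pcan_v: list[int] = field(default_factory=list)
    pmin_v: list[int] = field(default_factory=list)
    pcan_p: float = float("nan")
    valid: bool = True


def regional_porosity(
    region_projs: list[np.ndarray],
    canal_masks: list[np.ndarray],
    lacunar_projs: list[np.ndarray],
) -> list[RegionalPorosity]:
    """Tally pCan.V(i) and pMin.V(i) per region and pool into pCan.P.

    The canalicular mask is multiplied with the projected regional mask to
    assign pixels; mineral pixels are the region pixels minus the lacunar
    and canalicular projections.  Regions with no mineral pixels anywhere
    are flagged invalid (undefined ratio).
    """
    if not (len(region_projs) == len(canal_masks) == len(lacunar_projs)):
        raise ValueError("projection lists must have equal length")
    n_regions = int(max(int(rp.max()) for rp in region_projs))
    results = {r: RegionalPorosity(region_id=r) for r in range(1, n_regions + 1)}
    for rp, cm, lp in zip(region_projs, canal_masks, lacunar_projs):
        if not (rp.shape == cm.shape == lp.shape):
            raise ValueError("per-projection shapes disagree")
        lac = np.asarray(lp) > 0
        cm = np.asarray(cm, bool)
        for r in range(1, n_regions + 1):
            in_r = rp == r
            results[r].pcan_v.append(int(np.count_nonzero(in_r & cm)))
            results[r].pmin_v.append(int(np.count_nonzero(in_r & ~cm & ~lac)))
    for res in results.values():
        total_min = sum(res.pmin_v)
        if total_min == 0:
            res.valid = False
        else:
            res.pcan_p = sum(res.pcan_v) / total_min
    return list(results.values())


def compute_porosity(
    volume: Volume,
    region_labels: np.ndarray,
    lacuna_labels: np.ndarray,
    window_slices: int = 130,
    n_projections: int = 15,
    offset: int = 0,
    tophat_radius_px: int = 10,
    min_component_px: int = 100,
) -> tuple[ProjectionSet, list[np.ndarray], list[RegionalPorosity]]:
    """Full porosity stage: projections, 2D segmentation, regional pooling."""
    pset = min_intensity_projections(volume, window_slices, n_projections, offset)
    canal_masks = [
        segment_canaliculi_2d(p, tophat_radius_px, min_component_px)
        for p in pset.projections
    ]
    region_projs = project_labels(region_labels, pset)
    lacunar_projs = project_labels(lacuna_labels, pset)
    porosity = regional_porosity(region_projs, canal_masks, lacunar_projs)
    return pset, canal_masks, porosity
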