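"""Dense remodeling-region masks and the cement-line interface band.

The dense region label volume ("mask A") is either supplied directly (e.g.
phantom ground truth or a precomputed label TIFF) or interpolated from
sparse manual labels drawn on selected slices.  Regions partition the
volume; the cement line is not a separate label — it is excluded later by
the large region erosion in the mineralization stage.  The interface band
toward an older region is the morphological dilation of that region minus
the region itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._morphology import ball_dilate
from .volume_io import SparseRegionLabels, Volume


@dataclass
class RegionMaskSet:
    """Dense region labels: every voxel carries exactly one label 1..n_regions."""

    mask_a: np.ndarray
    provenance: str  # "interpolated" | "supplied"
    n_regions: int

    def region(self, label: int) -> np.ndarray:
        if not 1 <= label <= self.n_regions:
            raise ValueError(f"unknown region label {label}")
        return self.mask_a == label


@dataclass
class InterfaceBand:
    """Band of voxels just outside the older region, within dilation_px of it."""

    mask: np.ndarray
    older_label: int
    dilation_px: float


@dataclass
class RegionValidationReport:
    region_means: dict[int, float]
    slice_mean_sd: float
    min_separation: float
    margin: float
    passed: bool


def _signed_distance(mask2d: np.ndarray) -> np.ndarray:
    """Positive inside the mask, negative outside (2D Euclidean)."""
    if not mask2d.any():
        return np.full(mask2d.shape, -1e9)
    inside = ndimage.distance_transform_edt(mask2d)
    outside = ndimage.distance_transform_edt(~mask2d)
    return inside - outside


def interpolate_region_mask(
    labels: SparseRegionLabels, target_shape: tuple[int, int, int]
) -> RegionMaskSet:
    """Shape-based interpolation of sparse slice labels to a dense mask.

    Labeled slices are reproduced exactly.  Between two labeled slices each
    region's signed distance map is blended linearly and every pixel takes
    the region with the maximal blended value (ties -> lower label id).
    Slices outside the labeled range copy the nearest labeled slice.
    """
    if len(labels.entries) < 2:
        raise ValueError(
            f"need >=2 labeled slices for interpolation, got {len(labels.entries)}"
        )
    nz, ny, nx = target_shape
    n_regions = labels.n_regions
    present = set()
    for _, img in labels.entries:
        if img.shape != (ny, nx):
            raise ValueError(
                f"label image shape {img.shape} does not match target in-plane "
                f"shape {(ny, nx)}"
            )
        present |= set(np.unique(img).tolist())
    for r in range(1, n_regions + 1):
        if r not in present:
            raise ValueError(f"region {r} absent from every labeled slice")
    idx = [i for i, _ in labels.entries]
    if idx[-1] >= nz or idx[0] < 0:
        raise ValueError(f"labeled slice indices {idx} outside target depth {nz}")

    sdfs = {
        i: np.stack([_signed_distance(img == r) for r in range(1, n_regions + 1)])
        for i, img in labels.entries
    }
    imgs = dict(labels.entries)
    dense = np.empty((nz, ny, nx), dtype=np.uint8)
    for z in range(nz):
        if z in imgs:
            # reproduce labeled slices exactly; background pixels (if any)
            # fall back to the signed-distance argmax so regions partition
            img = imgs[z]
            out = img.astype(np.uint8).copy()
            if (img == 0).any():
                fill = np.argmax(sdfs[z], axis=0).astype(np.uint8) + 1
                out[img == 0] = fill[img == 0]
            dense[z] = out
            continue
        below = [i for i in idx if i < z]
        above = [i for i in idx if i > z]
        if not below:
            src = sdfs[above[0]]
        elif not above:
            src = sdfs[below[-1]]
        else:
            i, j = below[-1], above[0]
            t = (z - i) / (j - i)
            src = (1 - t) * sdfs[i] + t * sdfs[j]
        dense[z] = np.argmax(src, axis=0).astype(np.uint8) + 1
    return RegionMaskSet(mask_a=dense, provenance="interpolated", n_regions=n_regions)


def supplied_region_mask(labels_3d: np.ndarray) -> RegionMaskSet:
    """Wrap a precomputed dense label volume (e.g. phantom ground truth)."""
    labels_3d = np.asarray(labels_3d)
    present = np.unique(labels_3d)
    if present[0] == 0:
        raise ValueError("supplied region mask must partition the volume (no 0s)")
    n_regions = int(present[-1])
    if not np.array_equal(present, np.arange(1, n_regions + 1)):
        raise ValueError(f"region labels must be consecutive 1..n, got {present}")
    return RegionMaskSet(mask_a=labels_3d, provenance="supplied", n_regions=n_regions)


def validate_regions_against_gv(
    volume: Volume, masks: RegionMaskSet, margin_factor: float = 2.0
) -> RegionValidationReport:
    """Advisory check that region labels match the gray-value data.

    Passes when all pairwise region mean-GV separations exceed
    ``margin_factor`` times the pooled within-region standard deviation of
    slice-wise means.  Never blocks the pipeline.
    """
    if volume.data.shape != masks.mask_a.shape:
        raise ValueError("volume and mask shapes disagree")
    means = {}
    slice_sds = []
    for r in range(1, masks.n_regions + 1):
        sel = masks.mask_a == r
        means[r] = float(volume.data[sel].mean()) if sel.any() else float("nan")
        per_slice = [
            float(volume.data[z][sel[z]].mean())
            for z in range(volume.shape[0])
            if sel[z].any()
        ]
        if len(per_slice) > 1:
            slice_sds.append(np.std(per_slice, ddof=1))
    pooled_sd = float(np.sqrt(np.mean(np.square(slice_sds)))) if slice_sds else 0.0
    vals = sorted(means.values())
    if len(vals) < 2:
        min_sep = float("inf")
    else:
        min_sep = float(min(b - a for a, b in zip(vals, vals[1:])))
    margin = margin_factor * pooled_sd
    return RegionValidationReport(
        region_means=means,
        slice_mean_sd=pooled_sd,
        min_separation=min_sep,
        margin=margin,
        passed=bool(min_sep > margin),
    )


def interface_band(
    masks: RegionMaskSet | np.ndarray, older_label: int, dilation_px: float = 3
) -> InterfaceBand:
    """Dilate the older region and subtract it: the band toward the younger side.

    Works on 3D label volumes and on 2D projected label images alike; the
    structuring element is a Euclidean ball/disk of radius ``dilation_px``
    and the band never exits the grid.
    """
    labels = masks.mask_a if isinstance(masks, RegionMaskSet) else np.asarray(masks)
    older = labels == older_label
    if not older.any():
        if isinstance(masks, RegionMaskSet) and not (
            1 <= older_label <= masks.n_regions
        ):
            raise ValueError(f"unknown region label {older_label}")
        warnings.warn(
            f"older region {older_label} empty in this view; interface band is empty",
            stacklevel=2,
        )
        band = np.zeros(labels.shape, dtype=bool)
    else:
        band = ball_dilate(older, dilation_px) & ~older
    return InterfaceBand(mask=band, older_label=older_label, dilation_px=dilation_px)
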