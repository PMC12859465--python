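"""End-to-end orchestration: regions -> mineralization -> porosity ->
connections -> statistics.

A :class:`PipelineConfig` carries every tunable of the analysis with
defaults matching the reference procedure (Otsu over 256 bins, opening
radius 7 voxels, 1500-voxel lacunar size filter, 50 px region erosion,
10 px B-dilation / C-erosion, 15 projections of 130 slices, top-hat radius
10 px, 100 px 2D component filter, 3 px interface dilation, 25 um counting
radius, alpha 0.05).  Inputs are either a volume on disk (with sparse or
dense region labels) or a phantom specification; all randomness flows from
the single config seed, and a rerun with an identical config writes
bit-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .connections import analyze_connections, connection_table
from .mineralization import (
    low_intensity_mask,
    rank_regions,
    regional_mean_gv,
    segment_lacunae,
)
from .phantom import default_validation_phantom
from .porosity import compute_porosity
from .region_masks import (
    interpolate_region_mask,
    supplied_region_mask,
    validate_regions_against_gv,
)
from .stats import connection_correlation, porosity_group_test
from .volume_io import SparseRegionLabels, read_volume, write_results

log = logging.getLogger("olcn")


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults follow the reference procedure."""

    # input: either a volume path (+ labels) or the built-in phantom fixture
    volume_path: str | None = None
    labels_path: str | None = None
    voxel_size_nm: float | None = None
    use_validation_phantom: bool = False
    phantom_noise_sd: float = 7.0
    region_source: str = "sparse"  # "sparse" | "supplied"
    sparse_label_stride: int = 16
    # mineralization
    otsu_bins: int = 256
    opening_radius_vox: float = 7
    lacuna_min_voxels: int = 1500
    region_erosion_radius_px: float = 50
    b_dilation_px: float = 10
    c_erosion_px: float = 10
    # porosity
    window_slices: int = 130
    n_projections: int = 15
    projection_offset: int = 0
    tophat_radius_px: int = 10
    min_component_px: int = 100
    # connections
    radius_um: float = 25.0
    band_dilation_px: float = 3
    proximity_um: float = 25.0
    bridge_px: float = 2
    distance_mode: str = "surface"
    # stats
    alpha: float = 0.05
    equal_var: bool = True
    gv_margin_factor: float = 2.0
    # bookkeeping
    sample_id: str = "sample"
    seed: int = 0
    out_dir: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    config: PipelineConfig
    region_stats: list
    porosity: list
    connections: list
    connection_rows: list[dict]
    tests: list
    validation: object
    tables: dict = field(default_factory=dict)
    written: dict = field(default_factory=dict)


class PipelineError(RuntimeError):
    """A stage failure, wrapped with the stage name."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


def _load_inputs(config: PipelineConfig):
    if config.use_validation_phantom:
        volume, gt = default_validation_phantom(
            seed=config.seed, noise_sd=config.phantom_noise_sd
        )
        return volume, gt.region_labels
    if config.volume_path is None:
        raise ValueError("config needs volume_path or use_validation_phantom")
    volume = read_volume(config.volume_path, voxel_size_nm=config.voxel_size_nm)
    labels = None
    if config.labels_path:
        lab_vol = read_volume(config.labels_path, voxel_size_nm=volume.voxel_size_nm)
        labels = lab_vol.data
    return volume, labels


def _sparse_from_dense(labels_3d: np.ndarray, stride: int) -> SparseRegionLabels:
    nz = labels_3d.shape[0]
    idx = sorted(set(range(0, nz, stride)) | {nz - 1})
    return SparseRegionLabels(entries=[(i, labels_3d[i]) for i in idx])


@_stage("region_masks")
def _region_stage(config: PipelineConfig, labels_3d, shape):
    if labels_3d is None:
        raise ValueError("no region labels available")
    if config.region_source == "supplied":
        return supplied_region_mask(labels_3d)
    sparse = _sparse_from_dense(labels_3d, config.sparse_label_stride)
    return interpolate_region_mask(sparse, shape)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and (optionally) write CSVs and a manifest."""
    logging.basicConfig(level=config.log_level)
    volume, labels_3d = _load_inputs(config)
    masks = _region_stage(config, labels_3d, volume.shape)
    log.info("region mask: %d regions (%s)", masks.n_regions, masks.provenance)

    validation = validate_regions_against_gv(volume, masks, config.gv_margin_factor)
    if not validation.passed:
        log.warning("region/GV validation advisory failed: %s", validation)

    @_stage("mineralization")
    def _mineral():
        mask_b = low_intensity_mask(volume, nbins=config.otsu_bins)
        seg = segment_lacunae(
            volume,
            opening_radius_vox=config.opening_radius_vox,
            min_voxels=config.lacuna_min_voxels,
            nbins=config.otsu_bins,
        )
        stats = regional_mean_gv(
            volume, masks, mask_b, seg.labels,
            region_erosion_radius_px=config.region_erosion_radius_px,
            b_dilation_px=config.b_dilation_px,
            c_erosion_px=config.c_erosion_px,
        )
        return mask_b, seg, rank_regions(stats)

    mask_b, lacuna_seg, region_stats = _mineral()

    @_stage("porosity")
    def _porosity():
        return compute_porosity(
            volume, masks.mask_a, lacuna_seg.labels,
            window_slices=config.window_slices,
            n_projections=config.n_projections,
            offset=config.projection_offset,
            tophat_radius_px=config.tophat_radius_px,
            min_component_px=config.min_component_px,
        )

    _, _, porosity = _porosity()
    pcan_by_region = {p.region_id: p.pcan_p for p in porosity if p.valid}

    @_stage("connections")
    def _connections():
        results = analyze_connections(
            volume, lacuna_seg.labels, masks, region_stats,
            radius_um=config.radius_um,
            band_dilation_px=config.band_dilation_px,
            proximity_um=config.proximity_um,
            tophat_radius_px=config.tophat_radius_px,
            min_component_px=config.min_component_px,
            bridge_px=config.bridge_px,
            distance_mode=config.distance_mode,
        )
        rows = connection_table(
            results, region_stats, pcan_by_region, sample=config.sample_id
        )
        return results, rows

    conn_results, conn_rows = _connections()

    @_stage("stats")
    def _stats():
        tests = []
        group_records = [
            (s.rank, pcan_by_region.get(s.region_id, float("nan")))
            for s in region_stats if s.rank is not None
        ]
        young = [r for r, _ in group_records if r == 1]
        older = [r for r, _ in group_records if r and r > 1]
        if len(young) >= 2 and len(older) >= 2:
            tests.append(porosity_group_test(
                group_records, equal_var=config.equal_var, alpha=config.alpha))
        else:
            log.info("porosity group test skipped: too few regions per group")
        try:
            tests.append(connection_correlation(
                [(r["n_conn"], r["neighbor_region_norm_gv"]) for r in conn_rows],
                alpha=config.alpha,
            ))
        except ValueError as exc:
            log.info("connection correlation skipped: %s", exc)
        return tests

    tests = _stats()

    tables = {
        "regions": [
            {
                "sample": config.sample_id,
                "region_id": s.region_id,
                "rank": s.rank,
                "norm_mean_gv": s.norm_mean_gv,
                "pcan_p": pcan_by_region.get(s.region_id, float("nan")),
            }
            for s in region_stats
        ],
        "lacunae": [
            {k: row[k] for k in
             ("sample", "lacuna_id", "n_conn",
              "own_region_norm_gv", "neighbor_region_norm_gv")}
            for row in conn_rows
        ],
        "tests": [
            {"name": t.name, "statistic": t.statistic, "p_value": t.p_value}
            for t in tests
        ],
    }

    result = PipelineResult(
        config=config,
        region_stats=region_stats,
        porosity=porosity,
        connections=conn_results,
        connection_rows=conn_rows,
        tests=tests,
        validation=validation,
        tables=tables,
    )
    if config.out_dir:
        out_dir = Path(config.out_dir)
        result.written = write_results(tables, out_dir)
        manifest = {
            "config": config.to_dict(),
            "olcn_version": __version__,
            "outputs": {k: str(v) for k, v in result.written.items()},
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
    return result
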