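"""Reading and writing volumes, sparse slice labels, and tabular results.

Conventions used throughout the package: axis order is (z, y, x) with
0-based indices, slice index = z; the voxel size is isotropic and carried
in nanometres; physical distances are ``voxel_size * Euclidean index
distance``.  Gray values are canonically 16-bit unsigned, but float data
are accepted and processed without rescaling.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

REGION_COLUMNS = ["sample", "region_id", "rank", "norm_mean_gv", "pcan_p"]
LACUNA_COLUMNS = [
    "sample",
    "lacuna_id",
    "n_conn",
    "own_region_norm_gv",
    "neighbor_region_norm_gv",
]
TEST_COLUMNS = ["name", "statistic", "p_value"]


@dataclass
class Volume:
    """A 3D gray-value grid with isotropic voxel size.

    Attributes
    ----------
    data : ndarray, shape (nz, ny, nx)
        Gray values, axis order (slice z, row y, column x).
    voxel_size_nm : float
        Isotropic voxel edge length in nanometres.
    """

    data: np.ndarray
    voxel_size_nm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or 0 in self.data.shape:
            raise ValueError(
                f"volume data must be non-empty 3D, got shape {self.data.shape}"
            )
        if not self.voxel_size_nm > 0:
            raise ValueError(f"voxel size must be positive, got {self.voxel_size_nm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_um(self) -> float:
        return self.voxel_size_nm / 1000.0


@dataclass
class SparseRegionLabels:
    """Manual region labels on selected slices.

    ``entries`` maps slice index -> 2D label image (background 0, regions
    1..n_regions).  At least two labeled slices are required before the
    dense mask can be interpolated.
    """

    entries: list[tuple[int, np.ndarray]] = field(default_factory=list)
    n_regions: int = 0

    def __post_init__(self) -> None:
        self.entries = sorted(
            ((int(i), np.asarray(img)) for i, img in self.entries),
            key=lambda e: e[0],
        )
        shapes = {img.shape for _, img in self.entries}
        if len(shapes) > 1:
            raise ValueError(f"label images differ in shape: {sorted(shapes)}")
        present = set()
        for _, img in self.entries:
            present |= set(np.unique(img).tolist())
        present.discard(0)
        if self.n_regions == 0:
            self.n_regions = int(max(present)) if present else 0
        expected = set(range(1, self.n_regions + 1))
        if present - expected:
            raise ValueError(
                f"labels must be consecutive integers 1..{self.n_regions}, "
                f"found {sorted(present)}"
            )


def _natural_key(name: str):
    return [int(tok) if tok.isdigit() else tok.lower() for tok in re.split(r"(\d+)", name)]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json") if path.suffix else path / "meta.json"


def read_volume(path: str | Path, voxel_size_nm: float | None = None) -> Volume:
    """Read a multipage TIFF or a directory of single-page TIFF slices.

    Directory slices are ordered by natural sort of the file names
    (s1, s2, ..., s10).  The voxel size comes from the JSON sidecar written
    by :func:`write_volume` unless given explicitly.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")),
            key=lambda p: _natural_key(p.name),
        )
        if not files:
            raise FileNotFoundError(f"no TIFF slices found in {path}")
        slices = []
        shape = None
        for f in files:
            img = tifffile.imread(f)
            if img.ndim != 2:
                raise ValueError(f"slice file {f} is not a single 2D page")
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise ValueError(
                    f"slice {f.name} has shape {img.shape}, expected {shape}"
                )
            slices.append(img)
        data = np.stack(slices, axis=0)
        sidecar = path / "meta.json"
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        sidecar = _sidecar_path(path)
    if voxel_size_nm is None:
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            voxel_size_nm = float(meta["voxel_size_nm"])
        else:
            raise ValueError(
                f"no voxel size: {sidecar} missing and voxel_size_nm not given"
            )
    return Volume(data=data, voxel_size_nm=voxel_size_nm)


def write_volume(volume: Volume, path: str | Path, extra_meta: dict | None = None) -> None:
    """Write a volume as a multipage TIFF plus a JSON metadata sidecar.

    The round trip through :func:`read_volume` is lossless for integer and
    float dtypes (data and voxel size).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.data)
    meta = {"voxel_size_nm": volume.voxel_size_nm, "shape": list(volume.shape)}
    if extra_meta:
        meta.update(extra_meta)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def _as_frame(records, columns: list[str]) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame(list(records), columns=columns if not records else None)
    for col in columns:
        if col not in frame.columns:
            frame[col] = np.nan
    return frame.loc[:, columns]


def write_results(
    tables: dict,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the pipeline's tabular results as CSV files.

    ``tables`` may contain the keys ``regions`` (per-region rows:
    sample, region_id, rank, norm_mean_gv, pcan_p), ``lacunae``
    (sample, lacuna_id, n_conn, own_region_norm_gv,
    neighbor_region_norm_gv) and ``tests`` (name, statistic, p_value);
    each value is a DataFrame or a list of dicts.  Empty inputs produce
    header-only files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    schema = {
        "regions": REGION_COLUMNS,
        "lacunae": LACUNA_COLUMNS,
        "tests": TEST_COLUMNS,
    }
    written = {}
    for key, columns in schema.items():
        if key not in tables:
            continue
        frame = _as_frame(tables[key], columns)
        dest = out_dir / f"{key}.csv"
        frame.to_csv(dest, index=False)
        written[key] = dest
    return written
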