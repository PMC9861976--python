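"""File formats and run configuration.

Only standard containers are used: multipage TIFF or PNG stacks for cubes
and masks, CSV for layer boundaries and lesion tables, PNG (0/255) for
binary en face maps, 32-bit TIFF for confidence maps, JSON for reports and
geometry sidecars, YAML for run configuration.  Proprietary OCT containers
are out of scope; layer boundaries arrive as tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .enface import DEFAULT_BINARIZE_THRESHOLD, EnFaceMap
from .ga_mask import DEFAULT_THICKNESS_PX, DEFAULT_TOL_PX, GAMaskBScan, LayerSet
from .lesions import CAM_THRESHOLD_UM, LesionReport
from .phantom import DeviceGeometry

__all__ = [
    "read_cube",
    "write_cube",
    "read_layers",
    "write_layers",
    "read_enface",
    "write_enface",
    "read_masks",
    "write_masks",
    "write_geometry",
    "read_geometry",
    "lesion_report_to_json",
    "lesion_report_to_csv",
    "RunConfig",
    "load_config",
]

LAYER_COLUMNS = ["bscan_index", "ascan_index", "ez_row", "rpe_row", "bm_row"]


class FormatError(ValueError):
    """Raised when an input file violates the documented dialect."""


# ---------------------------------------------------------------------------
# intensity cubes
# ---------------------------------------------------------------------------


def write_cube(cube: np.ndarray, path) -> None:
    """Write an (n_bscans, n_depth, n_ascans) cube.

    ``.tif``/``.tiff`` paths get one TIFF page per B-scan; any other path is
    treated as a directory of zero-padded PNG pages (integer cubes only).
    """
    cube = np.asarray(cube)
    if cube.ndim != 3:
        raise FormatError("cube must be 3-D (n_bscans, n_depth, n_ascans)")
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, cube)
    else:
        import imageio.v3 as iio

        if cube.dtype.kind not in "ui":
            raise FormatError("PNG stacks require an integer cube; use TIFF for float data")
        path.mkdir(parents=True, exist_ok=True)
        for b in range(cube.shape[0]):
            iio.imwrite(path / f"bscan_{b:04d}.png", cube[b])


def read_cube(path) -> np.ndarray:
    """Read a cube written by :func:`write_cube`; lossless for integer data."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    if path.is_dir():
        import imageio.v3 as iio

        pages = sorted(path.glob("*.png"))
        if not pages:
            raise FormatError(f"no PNG pages in {path}")
        arrays = [iio.imread(p) for p in pages]
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise FormatError(f"ragged page sizes in {path}: {sorted(shapes)}")
        return np.stack(arrays)
    cube = tifffile.imread(path)
    if cube.ndim == 2:
        cube = cube[None]
    if cube.ndim != 3:
        raise FormatError(f"{path} is not a 2-D page stack")
    return cube


# ---------------------------------------------------------------------------
# layer boundary tables
# ---------------------------------------------------------------------------


def write_layers(layer_sets: list[LayerSet], path) -> None:
    """Long-format CSV, one row per (B-scan, A-scan); NaN rows become blanks."""
    frames = []
    for ls in layer_sets:
        frames.append(
            pd.DataFrame(
                {
                    "bscan_index": ls.bscan_index,
                    "ascan_index": np.arange(ls.n_ascans),
                    "ez_row": ls.ez_row,
                    "rpe_row": ls.rpe_row,
                    "bm_row": ls.bm_row,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_layers(path, n_depth: int | None = None) -> list[LayerSet]:
    """Read a boundary CSV into per-B-scan structures.

    Blank cells mark undefined boundaries (excluded from GA detection).
    Duplicate (bscan, ascan) rows and, when ``n_depth`` is given, rows
    outside [0, n_depth) are rejected with the offending cell named.
    """
    df = pd.read_csv(path)
    missing = [c for c in LAYER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["bscan_index", "ascan_index"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicate entry for bscan {int(row.bscan_index)}, "
            f"ascan {int(row.ascan_index)}"
        )
    if n_depth is not None:
        for col in ("ez_row", "rpe_row", "bm_row"):
            bad = df.index[(df[col] < 0) | (df[col] >= n_depth)]
            if len(bad):
                r = df.loc[bad[0]]
                raise FormatError(
                    f"{path}: {col} out of range at bscan {int(r.bscan_index)}, "
                    f"ascan {int(r.ascan_index)}: {r[col]}"
                )
    out = []
    for b, grp in df.groupby("bscan_index", sort=True):
        grp = grp.sort_values("ascan_index")
        n = int(grp["ascan_index"].max()) + 1
        if len(grp) != n or not np.array_equal(grp["ascan_index"].to_numpy(), np.arange(n)):
            raise FormatError(f"{path}: bscan {b}: A-scan indices are not dense 0..{n - 1}")
        out.append(
            LayerSet(
                bscan_index=int(b),
                ez_row=grp["ez_row"].to_numpy(float),
                rpe_row=grp["rpe_row"].to_numpy(float),
                bm_row=grp["bm_row"].to_numpy(float),
            )
        )
    return out


# ---------------------------------------------------------------------------
# masks and en face maps
# ---------------------------------------------------------------------------


def write_masks(masks: list[GAMaskBScan], path) -> None:
    """Multipage TIFF, 0/255 uint8, one page per B-scan."""
    stack = np.stack([m.mask for m in masks]).astype(np.uint8) * 255
    tifffile.imwrite(Path(path), stack)


def read_masks(path) -> list[GAMaskBScan]:
    stack = read_cube(path)
    masks = []
    for b in range(stack.shape[0]):
        m = stack[b] > 0
        masks.append(GAMaskBScan(bscan_index=b, mask=m, ga_columns=m.any(axis=0)))
    return masks


def write_geometry(geometry: DeviceGeometry, path, seed: int | None = None, **extra) -> None:
    payload = {"geometry": geometry.to_dict(), **extra}
    if seed is not None:
        payload["seed"] = seed
    Path(path).write_text(json.dumps(payload, indent=2))


def read_geometry(path) -> DeviceGeometry:
    payload = json.loads(Path(path).read_text())
    return DeviceGeometry(**payload["geometry"])


def write_enface(emap: EnFaceMap, path, sidecar: bool = True) -> None:
    """Binary maps as 0/255 PNG; confidence maps as 32-bit float TIFF.

    A JSON sidecar (``<path>.json``) records geometry and kind so the map
    can be re-read with its physical scale.
    """
    path = Path(path)
    if emap.values.dtype == bool:
        import imageio.v3 as iio

        if path.suffix.lower() != ".png":
            raise FormatError("binary en face maps are written as PNG")
        iio.imwrite(path, emap.values.astype(np.uint8) * 255)
    else:
        if path.suffix.lower() not in (".tif", ".tiff"):
            raise FormatError("confidence en face maps are written as 32-bit TIFF")
        tifffile.imwrite(path, emap.values.astype(np.float32))
    if sidecar:
        write_geometry(emap.geometry, path.with_suffix(path.suffix + ".json"), kind=emap.kind)


def read_enface(path, geometry: DeviceGeometry | None = None) -> EnFaceMap:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    kind = "truth"
    if geometry is None:
        if not sidecar.exists():
            raise FormatError(f"{path}: no geometry given and no sidecar {sidecar.name}")
        payload = json.loads(sidecar.read_text())
        geometry = DeviceGeometry(**payload["geometry"])
        kind = payload.get("kind", kind)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        values = iio.imread(path) > 0
    else:
        values = tifffile.imread(path).astype(float)
    return EnFaceMap(values, geometry, kind=kind)


def lesion_report_to_json(report: LesionReport, path) -> None:
    payload = {
        "threshold_um": report.threshold_um,
        "area_percent_all": report.area_percent_all,
        "area_percent_cRORA_only": report.area_percent_cRORA_only,
        "n_lesions": len(report.lesions),
        "lesions": report.to_records(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def lesion_report_to_csv(report: LesionReport, path) -> None:
    pd.DataFrame(
        report.to_records(), columns=["label", "area_px", "area_um2", "gld_um", "cam_class"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated pipeline configuration; defaults equal the module defaults."""

    geometry_preset: str | None = "spectralis"
    n_bscans: int | None = None
    n_ascans: int | None = None
    n_depth: int | None = None
    tol_px: float = DEFAULT_TOL_PX
    thickness_px: int = DEFAULT_THICKNESS_PX
    connectivity: int = 8
    threshold_um: float = CAM_THRESHOLD_UM
    binarize_threshold: float = DEFAULT_BINARIZE_THRESHOLD
    icc_variant: str = "ICC2"
    seed: int = 0
    train: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tol_px < 0:
            raise ValueError("tol_px must be >= 0")
        if self.thickness_px < 1:
            raise ValueError("thickness_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.threshold_um <= 0:
            raise ValueError("threshold_um must be positive")
        if not 0 <= self.binarize_threshold <= 1:
            raise ValueError("binarize_threshold must be in [0, 1]")

    def make_geometry(self) -> DeviceGeometry:
        from .phantom import make_geometry

        if self.geometry_preset is not None:
            return make_geometry(self.geometry_preset)
        return make_geometry(
            n_bscans=self.n_bscans, n_ascans=self.n_ascans, n_depth=self.n_depth
        )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are errors."""
    import yaml

    payload = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(payload, dict):
        raise FormatError(f"{path}: top level must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(payload) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**payload)
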