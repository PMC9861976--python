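"""En face GA maps: compilation from B-scan masks, presence, projection.

An en face map is a top-down view of the macular field with one row per
B-scan.  Compilation reduces each B-scan mask to a row by taking the
maximum over depth per column, then resizes that row horizontally by block
maximum; there is no vertical rescaling.  The inverse operation projects a
binary en face map back onto every B-scan as a band centered on the BM line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ga_mask import DEFAULT_THICKNESS_PX, GAMaskBScan, LayerSet, build_bscan_mask
from .phantom import DeviceGeometry

__all__ = [
    "EnFaceMap",
    "compile_enface",
    "detect_presence",
    "project_to_bscans",
    "mean_projection",
    "binarize",
]

DEFAULT_BINARIZE_THRESHOLD = 0.5


@dataclass
class EnFaceMap:
    """2-D en face values plus the cube geometry they were derived from.

    ``values`` is (n_bscans, width); binary maps are boolean, confidence
    maps float in [0, 1].  ``kind`` is one of ``truth``, ``prediction``,
    ``confidence``, ``intensity``.
    """

    values: np.ndarray
    geometry: DeviceGeometry
    kind: str = "truth"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("en face values must be 2-D")
        if self.values.shape[0] != self.geometry.n_bscans:
            raise ValueError("row count must equal n_bscans")
        if self.values.dtype != bool:
            v = self.values.astype(float)
            if v.size and (v.min() < 0 or v.max() > 1 + 1e-9):
                raise ValueError("non-binary en face values must lie in [0, 1]")

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def um_per_px_x(self) -> float:
        """Horizontal spacing of *this* map (accounts for any resize)."""
        return 1000.0 * self.geometry.field_x_mm / self.width

    @property
    def um_per_px_y(self) -> float:
        return self.geometry.um_per_px_y


def _block_max_rows(rows: np.ndarray, target_width: int) -> np.ndarray:
    """Resize rows (n, W) -> (n, T) by maximum over the source columns that
    overlap each target column's half-open real interval [t*W/T, (t+1)*W/T)."""
    n, w = rows.shape
    t = target_width
    if t == w:
        return rows.copy()
    out = np.zeros((n, t), dtype=rows.dtype)
    for x in range(t):
        # a source column [s, s+1) contributes iff it overlaps the target interval
        s0 = int(np.floor(x * w / t))
        s1 = int(np.ceil((x + 1) * w / t))
        out[:, x] = rows[:, s0:min(s1, w)].max(axis=1)
    return out


def compile_enface(
    masks: list[GAMaskBScan],
    geometry: DeviceGeometry,
    target_width: int | None = None,
    kind: str = "truth",
) -> EnFaceMap:
    """Compile per-B-scan masks into an en face map.

    Each mask collapses to a row via per-column maximum over depth; the row
    is then block-max resized to ``target_width`` (default: native width).
    Row b of the map is B-scan b.
    """
    if len(masks) != geometry.n_bscans:
        raise ValueError(f"expected {geometry.n_bscans} masks, got {len(masks)}")
    widths = {m.mask.shape[1] for m in masks}
    if len(widths) != 1:
        raise ValueError(f"inconsistent mask widths: {sorted(widths)}")
    (w,) = widths
    if target_width is None:
        target_width = w
    if not 0 < target_width <= w:
        raise ValueError("target_width must be in [1, mask width]")
    rows = np.stack([m.mask.any(axis=0) for m in masks])  # (n_bscans, w)
    return EnFaceMap(_block_max_rows(rows, target_width), geometry, kind=kind)


def binarize(values: np.ndarray, threshold: float = DEFAULT_BINARIZE_THRESHOLD) -> np.ndarray:
    """Threshold a confidence array into a boolean mask (>= threshold)."""
    v = np.asarray(values)
    if v.dtype == bool:
        return v
    return v >= threshold


def detect_presence(map_or_mask, threshold: float = DEFAULT_BINARIZE_THRESHOLD) -> bool:
    """True iff any pixel is positive (confidence inputs are binarized first)."""
    if isinstance(map_or_mask, EnFaceMap):
        v = map_or_mask.values
    elif isinstance(map_or_mask, GAMaskBScan):
        v = map_or_mask.mask
    else:
        v = np.asarray(map_or_mask)
    if v.size == 0:
        raise ValueError("empty array has no presence")
    return bool(binarize(v, threshold).any())


def project_to_bscans(
    emap: EnFaceMap,
    layer_sets: list[LayerSet],
    thickness_px: int = DEFAULT_THICKNESS_PX,
) -> list[GAMaskBScan]:
    """Project a binary en face map back onto B-scans along the BM line.

    The map is widened to the B-scan width by nearest-source-column
    expansion (source column s takes target column floor(s*T/W)); each
    positive column then receives the same BM-centered band convention as
    mask construction.
    """
    if emap.values.dtype != bool:
        raise ValueError("projection requires a binary en face map")
    if len(layer_sets) != emap.geometry.n_bscans:
        raise ValueError("need one layer set per map row")
    w = layer_sets[0].n_ascans
    t = emap.width
    if t > w:
        raise ValueError("map wider than B-scans; cannot expand")
    src_to_target = (np.arange(w) * t) // w
    n_depth = emap.geometry.n_depth
    out = []
    for b, ls in enumerate(layer_sets):
        cols = emap.values[b][src_to_target]
        if np.any(cols & ~np.isfinite(ls.bm_row)):
            raise ValueError(f"B-scan {ls.bscan_index}: positive column with missing BM row")
        out.append(
            build_bscan_mask(cols, ls.bm_row, n_depth, thickness_px, bscan_index=ls.bscan_index)
        )
    return out


def mean_projection(intensity_cube: np.ndarray, geometry: DeviceGeometry) -> EnFaceMap:
    """Mean-over-depth intensity en face image (visualization / model input).

    No segmentation slab is used: the whole cube is averaged along depth,
    so hypertransmissive (atrophic) columns appear brighter.
    """
    cube = np.asarray(intensity_cube)
    if cube.shape[0] != geometry.n_bscans or cube.shape[2] != geometry.n_ascans:
        raise ValueError("cube shape does not match geometry")
    vals = cube.mean(axis=1)
    vals = np.clip(vals, 0.0, 1.0)
    return EnFaceMap(vals, geometry, kind="intensity")
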