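"""Rule-based GA detection on B-scans.

A column of a B-scan is atrophic when the EZ, RPE and BM segmentation lines
are confluent there: both the EZ-RPE and the RPE-BM thickness are (within a
sub-pixel tolerance) zero.  Flagged columns are rasterized into a band of
fixed pixel thickness centered on the BM line, which is the per-B-scan
ground-truth mask consumed by the en face compiler and the model trainer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LayerSet",
    "GAMaskBScan",
    "detect_confluence",
    "build_bscan_mask",
    "mask_volume",
]

DEFAULT_TOL_PX = 0.5
DEFAULT_THICKNESS_PX = 10


@dataclass
class LayerSet:
    """Per-B-scan boundary rows for EZ, RPE and BM.

    Rows are real-valued image rows (sub-pixel allowed), one per A-scan
    column; NaN marks a column where that boundary is undefined.  Wherever
    all three are defined, ``ez_row <= rpe_row <= bm_row`` must hold
    (row 0 is the vitreous side).
    """

    bscan_index: int
    ez_row: np.ndarray
    rpe_row: np.ndarray
    bm_row: np.ndarray

    def __post_init__(self) -> None:
        self.ez_row = np.asarray(self.ez_row, dtype=float)
        self.rpe_row = np.asarray(self.rpe_row, dtype=float)
        self.bm_row = np.asarray(self.bm_row, dtype=float)
        if not (self.ez_row.shape == self.rpe_row.shape == self.bm_row.shape):
            raise ValueError("EZ/RPE/BM row vectors must have equal length")
        ok = self.defined
        if np.any(self.ez_row[ok] > self.rpe_row[ok] + 1e-9) or np.any(
            self.rpe_row[ok] > self.bm_row[ok] + 1e-9
        ):
            raise ValueError("anatomical ordering violated: need ez_row <= rpe_row <= bm_row")

    @property
    def n_ascans(self) -> int:
        return self.ez_row.shape[0]

    @property
    def defined(self) -> np.ndarray:
        """Columns where all three boundaries are present."""
        return np.isfinite(self.ez_row) & np.isfinite(self.rpe_row) & np.isfinite(self.bm_row)


@dataclass
class GAMaskBScan:
    """Binary GA mask for one B-scan plus its column-level flags."""

    bscan_index: int
    mask: np.ndarray  # bool, (n_depth, n_ascans)
    ga_columns: np.ndarray  # bool, (n_ascans,)


def detect_confluence(layer_set: LayerSet, tol_px: float = DEFAULT_TOL_PX) -> np.ndarray:
    """Flag columns where EZ-RPE and RPE-BM thickness are both <= ``tol_px``.

    Columns with any undefined boundary are never flagged: the rule requires
    all three lines to be present and concurrent.
    """
    if tol_px < 0:
        raise ValueError("tol_px must be >= 0")
    d = layer_set.defined
    ez_rpe = layer_set.rpe_row - layer_set.ez_row
    rpe_bm = layer_set.bm_row - layer_set.rpe_row
    with np.errstate(invalid="ignore"):
        return d & (ez_rpe <= tol_px) & (rpe_bm <= tol_px)


def build_bscan_mask(
    ga_columns: np.ndarray,
    bm_row: np.ndarray,
    n_depth: int,
    thickness_px: int = DEFAULT_THICKNESS_PX,
    bscan_index: int = 0,
) -> GAMaskBScan:
    """Dilate flagged columns into a ``thickness_px`` band centered on BM.

    For a flagged column with BM at row r the band covers rows
    ``[round(r) - thickness//2, round(r) + (thickness+1)//2)`` intersected
    with the image (an even thickness puts the extra pixel above the BM
    row).  Unflagged columns stay empty.
    """
    if thickness_px < 1:
        raise ValueError("thickness_px must be >= 1")
    ga_columns = np.asarray(ga_columns, dtype=bool)
    bm_row = np.asarray(bm_row, dtype=float)
    if bm_row.shape != ga_columns.shape:
        raise ValueError("bm_row and ga_columns must have the same length")
    n_ascans = ga_columns.shape[0]
    mask = np.zeros((n_depth, n_ascans), dtype=bool)
    cols = np.flatnonzero(ga_columns)
    if cols.size:
        if not np.all(np.isfinite(bm_row[cols])):
            raise ValueError("flagged column has undefined BM row")
        r0 = np.rint(bm_row[cols]).astype(int)
        lo = np.clip(r0 - thickness_px // 2, 0, n_depth)
        hi = np.clip(r0 + (thickness_px + 1) // 2, 0, n_depth)
        for c, a, b in zip(cols, lo, hi):
            mask[a:b, c] = True
    return GAMaskBScan(bscan_index=bscan_index, mask=mask, ga_columns=ga_columns)


def mask_volume(
    layer_sets: list[LayerSet],
    geometry,
    tol_px: float = DEFAULT_TOL_PX,
    thickness_px: int = DEFAULT_THICKNESS_PX,
) -> list[GAMaskBScan]:
    """Apply confluence detection + BM-band dilation to every B-scan in order."""
    if len(layer_sets) != geometry.n_bscans:
        raise ValueError(
            f"expected {geometry.n_bscans} layer sets, got {len(layer_sets)}"
        )
    out = []
    for ls in layer_sets:
        if ls.n_ascans != geometry.n_ascans:
            raise ValueError(f"B-scan {ls.bscan_index}: column count mismatch vs geometry")
        cols = detect_confluence(ls, tol_px=tol_px)
        out.append(
            build_bscan_mask(
                cols, ls.bm_row, geometry.n_depth, thickness_px, bscan_index=ls.bscan_index
            )
        )
    return out
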