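"""Synthetic macular OCT phantoms.

Generates volumes that carry the anatomy the downstream pipeline consumes:
per-B-scan EZ/RPE/BM boundary rows, banded-reflectivity intensity B-scans
with choroidal hypertransmission beneath atrophic regions, and an analytic
en face footprint of every lesion that serves as ground truth.

Atrophy is modelled as elliptical en face regions in which the ellipsoid
zone and RPE are lost: inside a lesion the EZ, RPE and BM boundaries
collapse onto a single line (zero EZ-RPE and RPE-BM thickness) and the
choroid below Bruch's membrane brightens because more light reaches it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ga_mask import LayerSet

__all__ = [
    "DeviceGeometry",
    "LesionSpec",
    "PhantomVolume",
    "make_geometry",
    "sample_lesions",
    "render_layers",
    "render_intensity",
    "analytic_enface",
    "generate_phantom",
]

#: preset name -> (n_bscans, n_ascans, n_depth); both cover a 6 mm x 6 mm field
GEOMETRY_PRESETS = {
    "spectralis": (97, 512, 496),
    "cirrus": (128, 512, 1024),
}


@dataclass(frozen=True)
class DeviceGeometry:
    """Sampling grid of a macular cube.

    ``n_bscans`` B-scans of ``n_depth`` rows x ``n_ascans`` columns over a
    ``field_x_mm`` x ``field_y_mm`` en face field.  Row 0 of a B-scan is the
    vitreous side; en face row b is B-scan b.
    """

    n_bscans: int
    n_ascans: int
    n_depth: int
    field_x_mm: float = 6.0
    field_y_mm: float = 6.0

    def __post_init__(self) -> None:
        for name in ("n_bscans", "n_ascans", "n_depth"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.field_x_mm <= 0 or self.field_y_mm <= 0:
            raise ValueError("field size must be positive")

    @property
    def um_per_px_x(self) -> float:
        """En face pixel spacing along a B-scan (A-scan direction), in um."""
        return 1000.0 * self.field_x_mm / self.n_ascans

    @property
    def um_per_px_y(self) -> float:
        """En face pixel spacing across B-scans, in um."""
        return 1000.0 * self.field_y_mm / self.n_bscans

    def to_dict(self) -> dict:
        return {
            "n_bscans": self.n_bscans,
            "n_ascans": self.n_ascans,
            "n_depth": self.n_depth,
            "field_x_mm": self.field_x_mm,
            "field_y_mm": self.field_y_mm,
        }


def make_geometry(
    preset: str | None = None,
    *,
    n_bscans: int | None = None,
    n_ascans: int | None = None,
    n_depth: int | None = None,
    field_x_mm: float = 6.0,
    field_y_mm: float = 6.0,
) -> DeviceGeometry:
    """Build a :class:`DeviceGeometry` from a preset name or explicit dims.

    Presets: ``"spectralis"`` (97 B-scans x 512 A-scans) and ``"cirrus"``
    (128 B-scans x 512 A-scans), both over a 6 mm x 6 mm field.  Explicit
    dimensions override nothing: either give a preset or all three counts.
    """
    if preset is not None:
        try:
            nb, na, nd = GEOMETRY_PRESETS[preset]
        except KeyError:
            raise ValueError(
                f"unknown preset {preset!r}; known: {sorted(GEOMETRY_PRESETS)}"
            ) from None
        return DeviceGeometry(nb, na, nd, field_x_mm, field_y_mm)
    if None in (n_bscans, n_ascans, n_depth):
        raise ValueError("without a preset, n_bscans, n_ascans and n_depth are all required")
    return DeviceGeometry(n_bscans, n_ascans, n_depth, field_x_mm, field_y_mm)


@dataclass(frozen=True)
class LesionSpec:
    """One elliptical atrophic region in en face (physical) coordinates.

    ``semi_axis_a_um >= semi_axis_b_um`` is not required; ``rotation_rad``
    rotates the a-axis counter-clockwise from the +x (A-scan) direction.
    """

    center_x_um: float
    center_y_um: float
    semi_axis_a_um: float
    semi_axis_b_um: float
    rotation_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.semi_axis_a_um <= 0 or self.semi_axis_b_um <= 0:
            raise ValueError("semi-axes must be positive")

    @property
    def major_axis_um(self) -> float:
        """Full greatest linear dimension of the ellipse, in um."""
        return 2.0 * max(self.semi_axis_a_um, self.semi_axis_b_um)

    def contains(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        """Point-in-ellipse test for arrays of physical coordinates."""
        dx = np.asarray(x_um, dtype=float) - self.center_x_um
        dy = np.asarray(y_um, dtype=float) - self.center_y_um
        c, s = math.cos(self.rotation_rad), math.sin(self.rotation_rad)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        return (u / self.semi_axis_a_um) ** 2 + (v / self.semi_axis_b_um) ** 2 <= 1.0


@dataclass
class PhantomVolume:
    """A complete synthetic cube plus its analytic ground truth."""

    geometry: DeviceGeometry
    lesions: list[LesionSpec]
    layer_sets: list[LayerSet]
    intensity: np.ndarray | None  # (n_bscans, n_depth, n_ascans) or None
    truth_enface: np.ndarray  # bool, (n_bscans, n_ascans)
    seed: int


def _pixel_centers(geometry: DeviceGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Physical (um) centers of the en face grid: x along A-scans, y across B-scans."""
    x = (np.arange(geometry.n_ascans) + 0.5) * geometry.um_per_px_x
    y = (np.arange(geometry.n_bscans) + 0.5) * geometry.um_per_px_y
    return x, y


def analytic_enface(geometry: DeviceGeometry, lesions: list[LesionSpec]) -> np.ndarray:
    """Rasterize the union of lesion ellipses onto the en face grid.

    Pixel (b, x) is set iff the physical center of that grid cell lies inside
    at least one lesion ellipse (pixel-center membership).
    """
    x, y = _pixel_centers(geometry)
    xx, yy = np.meshgrid(x, y)  # (n_bscans, n_ascans)
    out = np.zeros((geometry.n_bscans, geometry.n_ascans), dtype=bool)
    for les in lesions:
        out |= les.contains(xx, yy)
    return out


def sample_lesions(
    geometry: DeviceGeometry,
    n_lesions: int,
    axis_range_um: tuple[float, float] = (100.0, 600.0),
    seed: int = 0,
    *,
    min_axis_ratio: float = 0.5,
    max_tries: int = 2000,
) -> list[LesionSpec]:
    """Draw random non-touching lesions that fit inside the field.

    Full major axes (2 x semi_axis_a) are uniform in ``axis_range_um``; the
    minor axis is a uniform fraction in [min_axis_ratio, 1] of the major;
    rotation uniform in [0, pi).  Centers are rejected until every pair of
    bounding circles is separated by at least three coarse pixel spacings,
    keeping en face components distinct after rasterization.
    """
    if n_lesions < 0:
        raise ValueError("n_lesions must be >= 0")
    lo, hi = axis_range_um
    if not (0 < lo <= hi):
        raise ValueError("axis_range_um must be a positive interval")
    rng = np.random.default_rng(seed)
    gap = 3.0 * max(geometry.um_per_px_x, geometry.um_per_px_y)
    fx, fy = 1000.0 * geometry.field_x_mm, 1000.0 * geometry.field_y_mm

    lesions: list[LesionSpec] = []
    tries = 0
    while len(lesions) < n_lesions:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_lesions} non-touching lesions after {max_tries} tries"
            )
        tries += 1
        a = 0.5 * rng.uniform(lo, hi)
        b = a * rng.uniform(min_axis_ratio, 1.0)
        theta = rng.uniform(0.0, math.pi)
        if 2 * a + gap >= min(fx, fy):
            raise ValueError("axis_range_um too large for the field")
        cx = rng.uniform(a + gap / 2, fx - a - gap / 2)
        cy = rng.uniform(a + gap / 2, fy - a - gap / 2)
        ok = all(
            math.hypot(cx - p.center_x_um, cy - p.center_y_um)
            >= a + p.semi_axis_a_um + gap
            for p in lesions
        )
        if ok:
            lesions.append(LesionSpec(cx, cy, a, b, theta))
    return lesions


def render_layers(
    geometry: DeviceGeometry,
    lesions: list[LesionSpec],
    smooth_amp_px: float = 2.0,
    seed: int = 0,
) -> list[LayerSet]:
    """Draw EZ/RPE/BM boundary rows for every B-scan.

    Outside lesions the three boundaries ride a shared low-frequency
    undulation with fixed EZ-RPE and RPE-BM thicknesses; inside a lesion all
    three collapse onto the BM row, so both thicknesses are exactly zero.
    Confluence membership is decided at pixel centers, identical to
    :func:`analytic_enface`.
    """
    nb, na, nd = geometry.n_bscans, geometry.n_ascans, geometry.n_depth
    rng = np.random.default_rng(seed)

    # smooth random field: a few seeded low-frequency sinusoids over the en face plane
    xs = np.arange(na) / na
    ys = np.arange(nb) / nb
    und = np.zeros((nb, na))
    n_modes = 3
    amps = rng.uniform(0.5, 1.0, n_modes)
    amps *= smooth_amp_px / max(amps.sum(), 1e-12)
    for m in range(n_modes):
        fx = rng.uniform(0.5, 2.5)
        fy = rng.uniform(0.5, 2.5)
        ph = rng.uniform(0, 2 * math.pi)
        und += amps[m] * np.sin(2 * math.pi * (fx * xs[None, :] + fy * ys[:, None]) + ph)

    t_ez_rpe = max(2.0, 0.04 * nd)  # px, photoreceptor outer segment band
    t_rpe_bm = max(2.0, 0.025 * nd)  # px, RPE band
    ez_base = 0.55 * nd
    ez = ez_base + und
    rpe = ez + t_ez_rpe
    bm = rpe + t_rpe_bm
    if (ez < 0).any() or (bm >= nd).any():
        raise ValueError("smoothing amplitude pushes boundaries outside the depth range")

    inside = analytic_enface(geometry, lesions)
    ez = np.where(inside, bm, ez)
    rpe = np.where(inside, bm, rpe)

    return [
        LayerSet(bscan_index=b, ez_row=ez[b].copy(), rpe_row=rpe[b].copy(), bm_row=bm[b].copy())
        for b in range(nb)
    ]


# reflectivity of each band, arbitrary units in [0, 1]
_I_ABOVE_EZ = 0.30
_I_EZ_RPE = 0.75
_I_RPE_BM = 0.85
_I_CHOROID = 0.20


def render_intensity(
    layer_set: LayerSet,
    geometry: DeviceGeometry,
    hyper_gain: float = 2.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Render one banded-reflectivity B-scan (float32, (n_depth, n_ascans)).

    Columns where the boundaries are confluent lose the EZ-RPE and RPE-BM
    bands and their sub-BM choroid is ``hyper_gain`` times brighter than in
    intact columns (hypertransmission).  Gaussian noise with ``noise_sd`` is
    added after band composition.
    """
    if hyper_gain <= 1.0:
        raise ValueError("hyper_gain must exceed 1 (no hypertransmission contrast otherwise)")
    nd, na = geometry.n_depth, geometry.n_ascans
    if layer_set.ez_row.shape != (na,):
        raise ValueError("layer set width does not match geometry")
    rows = np.arange(nd, dtype=float)[:, None]  # (nd, 1)
    ez, rpe, bm = layer_set.ez_row[None, :], layer_set.rpe_row[None, :], layer_set.bm_row[None, :]
    img = np.full((nd, na), _I_ABOVE_EZ, dtype=float)
    img[(rows >= ez) & (rows < rpe)] = _I_EZ_RPE
    img[(rows >= rpe) & (rows < bm)] = _I_RPE_BM
    confluent = (layer_set.rpe_row - layer_set.ez_row <= 1e-9) & (
        layer_set.bm_row - layer_set.rpe_row <= 1e-9
    )
    choroid = np.where(confluent[None, :], hyper_gain * _I_CHOROID, _I_CHOROID)
    sub_bm = rows >= bm
    img[sub_bm] = np.broadcast_to(choroid, (nd, na))[sub_bm]
    if noise_sd > 0:
        img = img + np.random.default_rng(seed).normal(0.0, noise_sd, size=img.shape)
    return img.astype(np.float32)


def generate_phantom(
    geometry: DeviceGeometry,
    n_lesions: int,
    seed: int = 0,
    *,
    axis_range_um: tuple[float, float] = (100.0, 600.0),
    smooth_amp_px: float = 2.0,
    hyper_gain: float = 2.0,
    noise_sd: float = 0.05,
    with_intensity: bool = True,
) -> PhantomVolume:
    """Generate a full phantom; all randomness derives from ``seed``."""
    ss = np.random.SeedSequence(seed)
    s_les, s_lay, s_int = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    lesions = sample_lesions(geometry, n_lesions, axis_range_um, seed=s_les)
    layer_sets = render_layers(geometry, lesions, smooth_amp_px=smooth_amp_px, seed=s_lay)
    intensity = None
    if with_intensity:
        cube = np.empty((geometry.n_bscans, geometry.n_depth, geometry.n_ascans), dtype=np.float32)
        for b, ls in enumerate(layer_sets):
            cube[b] = render_intensity(
                ls, geometry, hyper_gain=hyper_gain, noise_sd=noise_sd, seed=s_int + b
            )
        intensity = cube
    truth = analytic_enface(geometry, lesions)
    return PhantomVolume(geometry, lesions, layer_sets, intensity, truth, seed)
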