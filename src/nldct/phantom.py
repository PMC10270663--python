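"""Analytic abdominal-slice attenuation phantom.

The phantom is a Shepp–Logan-style composition of ellipses painted in order
onto a Cartesian grid of linear attenuation coefficients at 60 keV.  Because
it is analytic it rescales exactly to any grid size, so region-of-interest
(ROI) semantics are preserved between a fast "desk" grid (128 px) and the
full-size grid (768 px).

Coordinate convention (fixed for reproducibility): row 0 is the top of the
image, column 0 the left; the physical origin sits at the image centre
(the isocenter); x increases with column, y increases with row; all
indexing is 0-based.

Attenuation anchors (NIST tabulations at 60 keV, in 1/mm):

* water           0.0206   (Hounsfield anchor: HU = 1000*(mu - mu_w)/mu_w)
* dry air         2.26e-5  (~ -998.9 HU; the phantom background)
* cortical bone   0.0604   (~ +1932 HU; the upper end of the allowed range)

Every tissue must lie within [dry air, cortical bone].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MU_WATER",
    "MU_AIR",
    "MU_BONE",
    "Ellipse",
    "TissueSpec",
    "AttenuationImage",
    "RoiSpec",
    "hu_value_to_mu",
    "mu_value_to_hu",
    "mu_to_hu",
    "hu_to_mu",
    "default_tissue_table",
    "build_phantom",
    "default_rois",
    "cnr_rois",
    "edge_mask",
    "PAPER_GRID",
]

#: linear attenuation coefficients at 60 keV [1/mm]
MU_WATER = 0.0206
MU_AIR = 2.26e-5
MU_BONE = 0.0604

#: grid size at which ROI pixel counts are quoted (768 px, 1 mm pixels)
PAPER_GRID = 768


def mu_value_to_hu(mu):
    """Scalar/array conversion mu [1/mm] -> Hounsfield units."""
    return 1000.0 * (np.asarray(mu, dtype=float) - MU_WATER) / MU_WATER


def hu_value_to_mu(hu):
    """Scalar/array conversion Hounsfield units -> mu [1/mm]."""
    return MU_WATER * (1.0 + np.asarray(hu, dtype=float) / 1000.0)


@dataclass(frozen=True)
class Ellipse:
    """An ellipse in physical coordinates (mm), origin at the isocenter.

    ``theta`` rotates the semi-axis ``a`` (along +x) towards +y (radians).
    """

    cx: float
    cy: float
    a: float
    b: float
    theta: float = 0.0

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("ellipse semi-axes must be positive")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        ct, st = np.cos(self.theta), np.sin(self.theta)
        u = (x - self.cx) * ct + (y - self.cy) * st
        v = -(x - self.cx) * st + (y - self.cy) * ct
        return (u / self.a) ** 2 + (v / self.b) ** 2 <= 1.0

    @property
    def bounding_radius(self) -> float:
        return float(np.hypot(self.cx, self.cy) + max(self.a, self.b))


@dataclass(frozen=True)
class TissueSpec:
    """A named tissue: an attenuation value and the ellipses it fills."""

    name: str
    mu: float
    ellipses: tuple[Ellipse, ...]

    def __post_init__(self):
        if not (MU_AIR <= self.mu <= MU_BONE):
            raise ValueError(
                f"tissue {self.name!r}: mu={self.mu:.5g} /mm outside the "
                f"dry-air..cortical-bone range [{MU_AIR:.3g}, {MU_BONE:.3g}]"
            )
        if not self.ellipses:
            raise ValueError(f"tissue {self.name!r} has no ellipses")


@dataclass
class AttenuationImage:
    """A 2-D map of linear attenuation (1/mm) or Hounsfield units.

    The image centre coincides with the isocenter of the acquisition
    geometry; ``pixel_size`` is in mm.
    """

    values: np.ndarray
    pixel_size: float
    units: str = "mu"  # "mu" or "HU"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("AttenuationImage requires a 2-D array")
        if self.units not in ("mu", "HU"):
            raise ValueError(f"unknown units {self.units!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attenuation image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "AttenuationImage":
        return AttenuationImage(self.values.copy(), self.pixel_size, self.units)


def mu_to_hu(image: AttenuationImage) -> AttenuationImage:
    if image.units != "mu":
        raise ValueError("mu_to_hu expects an image in mu units")
    return AttenuationImage(mu_value_to_hu(image.values), image.pixel_size, "HU")


def hu_to_mu(image: AttenuationImage) -> AttenuationImage:
    if image.units != "HU":
        raise ValueError("hu_to_mu expects an image in HU units")
    return AttenuationImage(hu_value_to_mu(image.values), image.pixel_size, "mu")


@dataclass(frozen=True)
class RoiSpec:
    """A rectangular ROI in pixel coordinates (top-left corner, height, width).

    Roles: ``muscle`` and ``liver`` are statistics ROIs; ``profile_row`` is a
    one-pixel-high full-width row; ``costa_edge`` is the short window
    straddling the lateral costa/lung boundary on the profile row.
    """

    role: str
    row: int
    col: int
    height: int
    width: int

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI height/width must be >= 1")

    def check_inside(self, shape: tuple[int, int]) -> None:
        if (
            self.row < 0
            or self.col < 0
            or self.row + self.height > shape[0]
            or self.col + self.width > shape[1]
        ):
            raise ValueError(f"ROI {self.role!r} {self} lies outside image {shape}")

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row, self.row + self.height),
            slice(self.col, self.col + self.width),
        )

    def extract(self, values: np.ndarray) -> np.ndarray:
        self.check_inside(values.shape)
        return values[self.slices()]


# ---------------------------------------------------------------------------
# default anatomy
# ---------------------------------------------------------------------------

# Tissue Hounsfield values (60 keV).  Liver - muscle is fixed at 55 HU, the
# contrast implied by the product CNR * sigma_FBP of the calibrated noise
# levels.  Contrast-filled vessels sit 200 HU above liver.
_TISSUE_HU = {
    "soft_tissue": 20.0,
    "liver": 95.0,
    "lung": -780.0,
    "muscle": 40.0,
    "vertebra": 700.0,
    "costa": 700.0,
    "vessel": 295.0,
}

# liver - muscle contrast in HU implied by the tissue table above
CONTRAST_LIVER_MUSCLE = _TISSUE_HU["liver"] - _TISSUE_HU["muscle"]

# Ellipse layout as fractions of the field of view F (center x, center y,
# semi-axis a, semi-axis b); y positive towards the bottom of the image.
# Painted in order; later tissues overwrite earlier ones.
_LAYOUT = [
    ("soft_tissue", [(0.0, 0.02, 0.36, 0.27)]),  # body outline
    ("liver", [(-0.13, 0.06, 0.14, 0.10)]),
    ("lung", [(-0.16, -0.10, 0.10, 0.09), (0.16, -0.10, 0.10, 0.09)]),
    ("muscle", [(-0.10, 0.20, 0.06, 0.045), (0.10, 0.20, 0.06, 0.045)]),
    ("vertebra", [(0.0, 0.18, 0.055, 0.05)]),
    (
        "costa",
        [
            (-0.285, -0.10, 0.022, 0.035),
            (0.285, -0.10, 0.022, 0.035),
            (-0.21, 0.16, 0.025, 0.018),
            (0.21, 0.16, 0.025, 0.018),
        ],
    ),
    ("vessel", [(-0.17, 0.04, 0.013, 0.013), (-0.08, 0.09, 0.010, 0.010)]),
]

# anchor positions (fractions of F) used by default_rois
_MUSCLE_ROI_CENTER = (-0.10, 0.20)
_LIVER_ROI_CENTER = (-0.13, 0.06)
_PROFILE_Y = -0.10
_COSTA_EDGE_X = -0.263


def default_tissue_table(fov_mm: float) -> list[TissueSpec]:
    """The built-in abdominal tissue table scaled to a field of view (mm)."""
    table = []
    for name, ellipses in _LAYOUT:
        mu = hu_value_to_mu(_TISSUE_HU[name])
        es = tuple(
            Ellipse(cx * fov_mm, cy * fov_mm, a * fov_mm, b * fov_mm)
            for cx, cy, a, b in ellipses
        )
        table.append(TissueSpec(name, float(mu), es))
    return table


def build_phantom(
    grid_size: int,
    pixel_size: float = 1.0,
    tissue_table: list[TissueSpec] | None = None,
) -> AttenuationImage:
    """Paint the tissue table onto a grid of attenuation coefficients.

    Deterministic: identical inputs give bit-identical images.  Background
    (outside every ellipse) is dry air.  Later tissues overwrite earlier
    ones, so the painting order of ``tissue_table`` matters.
    """
    if grid_size < 64:
        raise ValueError("grid_size must be >= 64")
    if tissue_table is None:
        tissue_table = default_tissue_table(grid_size * pixel_size)
    if not tissue_table:
        raise ValueError("tissue_table must be non-empty")

    half = grid_size * pixel_size / 2.0
    coords = (np.arange(grid_size) - (grid_size - 1) / 2.0) * pixel_size
    x, y = np.meshgrid(coords, coords)  # y varies along rows

    values = np.full((grid_size, grid_size), MU_AIR, dtype=np.float64)
    for tissue in tissue_table:
        for e in tissue.ellipses:
            if (
                abs(e.cx) + max(e.a, e.b) > half
                or abs(e.cy) + max(e.a, e.b) > half
            ):
                raise ValueError(
                    f"tissue {tissue.name!r}: ellipse {e} extends outside the "
                    f"{grid_size}x{grid_size} field of view"
                )
            values[e.contains(x, y)] = tissue.mu
    return AttenuationImage(values, pixel_size, "mu")


def _scaled(v: float, grid_size: int) -> int:
    return int(round(v * grid_size / PAPER_GRID))


def _centered_roi(role, cx_frac, cy_frac, h, w, grid_size) -> RoiSpec:
    r = int(round((grid_size - 1) / 2.0 + cy_frac * grid_size - h / 2.0 + 0.5))
    c = int(round((grid_size - 1) / 2.0 + cx_frac * grid_size - w / 2.0 + 0.5))
    return RoiSpec(role, r, c, h, w)


def default_rois(grid_size: int) -> list[RoiSpec]:
    """ROIs matching the analysis layout: muscle (60x20 px at the 768-px
    grid, scaled proportionally), liver, the horizontal profile row through
    the lateral costae, and the 20-px (at 768) costa-edge window straddling
    the lateral costa/lung boundary."""
    h, w = _scaled(60, grid_size), _scaled(20, grid_size)
    if h < 2 or w < 2:
        raise ValueError(
            f"grid_size {grid_size} too small to host a scaled 60x20 muscle ROI"
        )
    muscle = _centered_roi("muscle", *_MUSCLE_ROI_CENTER, h, w, grid_size)
    liver = _centered_roi("liver", *_LIVER_ROI_CENTER, h, w, grid_size)

    prow = int(round((grid_size - 1) / 2.0 + _PROFILE_Y * grid_size))
    profile = RoiSpec("profile_row", prow, 0, 1, grid_size)

    length = max(3, _scaled(20, grid_size))
    ccol = int(round((grid_size - 1) / 2.0 + _COSTA_EDGE_X * grid_size))
    costa = RoiSpec("costa_edge", prow, ccol - length // 2, 1, length)

    rois = [muscle, liver, profile, costa]
    for roi in rois:
        roi.check_inside((grid_size, grid_size))
    return rois


def cnr_rois(grid_size: int) -> tuple[RoiSpec, RoiSpec]:
    """The ``(liver_roi, muscle_roi)`` pair used for CNR measurement.

    These are the same ROIs as :func:`default_rois`, so the identity
    sigma_muscle = contrast / CNR holds on the same ROI the noise table
    uses; stability of the CNR estimate comes from averaging over repeated
    realizations rather than from enlarging the ROIs.
    """
    rois = {r.role: r for r in default_rois(grid_size)}
    return rois["liver"], rois["muscle"]


def edge_mask(phantom: AttenuationImage) -> np.ndarray:
    """Boolean mask of pixels adjacent to a tissue boundary of the phantom.

    A pixel is an edge pixel if any of its 8 neighbours has a different
    attenuation value on the noise-free phantom.
    """
    v = phantom.values
    mask = np.zeros(v.shape, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.roll(np.roll(v, dr, axis=0), dc, axis=1)
            mask |= shifted != v
    # roll wraps around; the phantom border is uniform air so this is safe
    return mask
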