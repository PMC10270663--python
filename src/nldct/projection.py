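"""Fan-beam, flat-detector forward and back projection.

The system operator is a Joseph-style interpolating line-integral projector:
each ray is traced from the point source through the centre of a detector
element, stepping one pixel along its dominant axis and interpolating
linearly along the other axis.  This integrates the bilinearly interpolated
image exactly along the ray.  The back projector is the exact algebraic
transpose of the forward projector (a matched pair), which the iterative
solvers (SIRT, CGLS) rely on.

The detector is a flat array whose element pitch is specified *at the
isocenter* (the physical detector pitch is the isocenter pitch magnified by
source_to_detector / source_to_isocenter); rays are parameterised by where
they cross the virtual detector line through the isocenter, which leaves
the ray geometry unchanged.

At desk-scale grids the operator is materialised once per geometry as a
sparse CSR matrix (and its transpose) and cached; all projections and
iterative reconstructions then reduce to sparse matrix times dense stack
products.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .phantom import AttenuationImage

__all__ = [
    "FanBeamGeometry",
    "Sinogram",
    "desk_geometry",
    "paper_geometry",
    "system_matrix",
    "forward_project",
    "forward_project_values",
    "back_project",
    "analysis_roi_slices",
]


@dataclass(frozen=True)
class FanBeamGeometry:
    """Fan-beam acquisition geometry with a flat detector.

    Angles are evenly spaced on [0, 2*pi); the source at angle beta sits at
    ``source_to_isocenter * (cos beta, sin beta)`` and the virtual detector
    line passes through the isocenter perpendicular to the source direction.
    """

    n_detectors: int
    detector_spacing_iso: float  # mm, element width at the isocenter
    n_angles: int
    source_to_detector: float  # mm
    source_to_isocenter: float  # mm
    image_rows: int
    image_cols: int
    pixel_size: float  # mm

    def __post_init__(self):
        if not (0 < self.source_to_isocenter < self.source_to_detector):
            raise ValueError("require 0 < source_to_isocenter < source_to_detector")
        if self.n_detectors < 2 or self.n_angles < 1:
            raise ValueError("need at least 2 detectors and 1 angle")
        if min(self.image_rows, self.image_cols) < 2 or self.pixel_size <= 0:
            raise ValueError("invalid image grid")
        # the fan must cover the reconstruction support circle
        if self.coverage_radius < self.support_radius:
            raise ValueError(
                f"fan covers a radius of {self.coverage_radius:.1f} mm but the "
                f"image support circle has radius {self.support_radius:.1f} mm"
            )

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_angles) * (2.0 * np.pi / self.n_angles)

    @property
    def detector_pitch_physical(self) -> float:
        return self.detector_spacing_iso * (
            self.source_to_detector / self.source_to_isocenter
        )

    @property
    def detector_coords(self) -> np.ndarray:
        """Signed detector-element centre positions on the isocenter line (mm)."""
        n = self.n_detectors
        return (np.arange(n) - (n - 1) / 2.0) * self.detector_spacing_iso

    @property
    def support_radius(self) -> float:
        """Radius of the support circle: the inscribed circle of the grid."""
        return min(self.image_rows, self.image_cols) * self.pixel_size / 2.0

    @property
    def coverage_radius(self) -> float:
        """Largest isocenter distance reached by any ray of the fan."""
        s = abs(self.detector_coords).max()
        d = self.source_to_isocenter
        return s * d / np.hypot(s, d)

    @property
    def sinogram_shape(self) -> tuple[int, int]:
        return (self.n_angles, self.n_detectors)

    @property
    def image_shape(self) -> tuple[int, int]:
        return (self.image_rows, self.image_cols)


def desk_geometry() -> FanBeamGeometry:
    """Fast preset: 128x128 image (1 mm pixels), 192 detectors, 360 angles."""
    return FanBeamGeometry(
        n_detectors=192,
        detector_spacing_iso=1.0,
        n_angles=360,
        source_to_detector=1085.6,
        source_to_isocenter=696.7,
        image_rows=128,
        image_cols=128,
        pixel_size=1.0,
    )


def paper_geometry() -> FanBeamGeometry:
    """Full-size preset: 768x768 image, 1474 detectors (1 mm at isocenter),
    1152 angles, source-to-detector 1085.6 mm, source-to-isocenter 696.7 mm."""
    return FanBeamGeometry(
        n_detectors=1474,
        detector_spacing_iso=1.0,
        n_angles=1152,
        source_to_detector=1085.6,
        source_to_isocenter=696.7,
        image_rows=768,
        image_cols=768,
        pixel_size=1.0,
    )


def analysis_roi_slices(geom: FanBeamGeometry) -> tuple[slice, slice]:
    """Central analysis window: 512/768 of the grid in each dimension."""
    h = int(round(geom.image_rows * 512 / 768))
    w = int(round(geom.image_cols * 512 / 768))
    r0 = (geom.image_rows - h) // 2
    c0 = (geom.image_cols - w) // 2
    return slice(r0, r0 + h), slice(c0, c0 + w)


@dataclass
class Sinogram:
    """Line integrals of attenuation indexed by (projection angle p, detector q)."""

    values: np.ndarray
    geometry: FanBeamGeometry

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geometry.sinogram_shape:
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"{self.geometry.sinogram_shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "Sinogram":
        return Sinogram(self.values.copy(), self.geometry)


def _angle_block(geom: FanBeamGeometry, beta: float) -> sp.csr_matrix:
    """Joseph weights for all rays of one projection angle as a sparse block
    of shape (n_detectors, image_rows * image_cols)."""
    nr, nc = geom.image_rows, geom.image_cols
    px = geom.pixel_size
    d = geom.source_to_isocenter

    src = np.array([d * np.cos(beta), d * np.sin(beta)])
    that = np.array([-np.sin(beta), np.cos(beta)])
    det = geom.detector_coords[:, None] * that[None, :]  # (q, 2)
    dirs = det - src[None, :]
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    xs = (np.arange(nc) - (nc - 1) / 2.0) * px  # column centres
    ys = (np.arange(nr) - (nr - 1) / 2.0) * px  # row centres

    rows_idx, cols_idx, data = [], [], []
    col_driven = np.abs(dirs[:, 0]) >= np.abs(dirs[:, 1])

    for driven_x in (True, False):
        rays = np.nonzero(col_driven == driven_x)[0]
        if rays.size == 0:
            continue
        dr = dirs[rays]
        if driven_x:
            # step across image columns, interpolate between two rows
            slope = dr[:, 1] / dr[:, 0]
            y_at = src[1] + (xs[None, :] - src[0]) * slope[:, None]
            f = y_at / px + (nr - 1) / 2.0  # fractional row index, (rays, nc)
            w = px * np.sqrt(1.0 + slope**2)  # intersection length per column
            n_steps = nc
        else:
            slope = dr[:, 0] / dr[:, 1]
            x_at = src[0] + (ys[None, :] - src[1]) * slope[:, None]
            f = x_at / px + (nc - 1) / 2.0  # fractional column index, (rays, nr)
            w = px * np.sqrt(1.0 + slope**2)
            n_steps = nr

        i0 = np.floor(f).astype(np.int64)
        frac = f - i0
        step = np.broadcast_to(np.arange(n_steps), f.shape)
        ray = np.broadcast_to(rays[:, None], f.shape)
        weight = np.broadcast_to(w[:, None], f.shape)

        for idx, wfrac in ((i0, 1.0 - frac), (i0 + 1, frac)):
            lim = nr if driven_x else nc
            ok = (idx >= 0) & (idx < lim) & (wfrac > 0)
            if driven_x:
                flat = idx[ok] * nc + step[ok]
            else:
                flat = step[ok] * nc + idx[ok]
            rows_idx.append(ray[ok])
            cols_idx.append(flat)
            data.append((weight * wfrac)[ok])

    block = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows_idx), np.concatenate(cols_idx))),
        shape=(geom.n_detectors, nr * nc),
    )
    return block.tocsr()


@functools.lru_cache(maxsize=4)
def system_matrix(geom: FanBeamGeometry) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Materialise the system operator A and its transpose for a geometry.

    Returns ``(A, AT)`` with A of shape (n_angles * n_detectors, n_pixels).
    Cached per geometry; desk-scale matrices occupy a few hundred MB.
    """
    blocks = [_angle_block(geom, beta) for beta in geom.angles]
    a = sp.vstack(blocks, format="csr")
    at = a.T.tocsr()
    return a, at


def forward_project(image: AttenuationImage, geom: FanBeamGeometry) -> Sinogram:
    """Line integrals of an attenuation image (mu units) along every ray."""
    if image.units != "mu":
        raise ValueError("forward_project expects an image in mu units")
    if image.shape != geom.image_shape:
        raise ValueError(
            f"image grid {image.shape} does not match geometry {geom.image_shape}"
        )
    a, _ = system_matrix(geom)
    vals = (a @ image.values.ravel()).reshape(geom.sinogram_shape)
    return Sinogram(vals, geom)


def forward_project_values(values: np.ndarray, geom: FanBeamGeometry) -> np.ndarray:
    """Forward projection of a raw array (or stack stacked on the last axis
    as (n_pixels, k)); no unit bookkeeping.  Used by the iterative solvers."""
    a, _ = system_matrix(geom)
    return a @ values


def back_project(sino: Sinogram, geom: FanBeamGeometry | None = None) -> AttenuationImage:
    """Exact adjoint of :func:`forward_project` (unfiltered backprojection)."""
    geom = geom or sino.geometry
    if sino.geometry != geom:
        raise ValueError("sinogram geometry does not match the requested geometry")
    _, at = system_matrix(geom)
    vals = (at @ sino.values.ravel()).reshape(geom.image_shape)
    return AttenuationImage(vals, geom.pixel_size, "mu")
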