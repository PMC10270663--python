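"""Nonlinear-distortion residual images (NLDobject, NLDobject', NLDnoise).

A reconstruction pipeline f is linear iff averaging commutes with it.  The
residuals computed here measure exactly that failure of superposition:

* ``NLDobject``  = SBbar_{n,N} - SBtilde_{n,N}: the average of N
  reconstructed noisy acquisitions minus the reconstruction of the averaged
  (approximately noise-free) sinogram.  Isolates the *systematic* nonlinear
  distortion of the object at noise level n.
* ``NLDobject'`` = SBbar_{n,N} - SBtilde'_{nlow}: the practical
  approximation that replaces the reconstruction of the averaged sinogram
  by one separately acquired low-noise image (no sinogram access needed);
  same expectation, higher random uncertainty.
* ``NLDnoise_i`` = Bbar_{n,i} - Btilde_{n,i}: per-acquisition difference
  between noise isolated *after* reconstruction (object present,
  Bbar_i = SB_i - SBbar) and noise isolated *before* reconstruction
  (object absent, Btilde_i = f(sb_i - sbtilde)).  Reveals how the pipeline
  treats noise differently when the object is present.

For a linear pipeline every one of these residuals vanishes to floating
point; any structure certifies nonlinearity of the noise-reduction step.

All images are in Hounsfield units; noise-only sinograms are reconstructed
on the HU scale (no -1000 offset) so the decomposition identities hold
exactly.  Per-acquisition distortion estimates D_i = f(sb_i) - SBtilde give
the pixelwise 5th/50th/95th percentile images; their mean over i equals
NLDobject identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import AttenuationImage, RoiSpec
from .projection import FanBeamGeometry, Sinogram
from .reconstruct import ReconConfig, reconstruct_stack
from .acquisition import AcquisitionStack

__all__ = [
    "NLDObjectResult",
    "NLDNoiseResult",
    "average_sinograms",
    "average_images",
    "nld_object",
    "nld_object_approx",
    "nld_noise",
    "roi_stats",
    "cnr",
    "extract_profile",
]

PERCENTILE_LEVELS = (5.0, 50.0, 95.0)


@dataclass
class NLDObjectResult:
    """Systematic nonlinear distortion of the object (exact or approximate)."""

    nld_image: np.ndarray  # HU
    sb_bar: np.ndarray  # average of reconstructions, HU
    sb_tilde: np.ndarray  # reconstruction of averaged sinogram (or low-noise), HU
    per_acquisition: np.ndarray  # D_i = f(sb_i) - sb_tilde, (N, rows, cols)
    percentiles: dict[float, np.ndarray]  # pixelwise over i at 5/50/95
    n: int
    cnr: float | None
    variant: str  # "exact" | "approx"

    def __post_init__(self):
        if not np.array_equal(
            self.nld_image, self.sb_bar - self.sb_tilde
        ):  # pragma: no cover - construction guard
            raise ValueError("nld_image must equal sb_bar - sb_tilde exactly")


@dataclass
class NLDNoiseResult:
    """Per-acquisition nonlinear distortion of noise."""

    series: np.ndarray  # (N, rows, cols), HU
    b_bar: np.ndarray  # noise isolated after reconstruction
    b_tilde: np.ndarray  # noise isolated before reconstruction
    n: int
    cnr: float | None


def average_sinograms(stack: AcquisitionStack) -> Sinogram:
    """Pixelwise mean of the stack's attenuation data (sbtilde_{n,N})."""
    if stack.n < 1:
        raise ValueError("empty acquisition stack")
    return Sinogram(stack.sinograms.mean(axis=0), stack.geometry)


def average_images(images) -> np.ndarray:
    """Pixelwise mean of a stack of congruent images (SBbar_{n,N})."""
    arr = np.asarray(
        [im.values if isinstance(im, AttenuationImage) else im for im in images],
        dtype=np.float64,
    )
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("need a non-empty stack of congruent 2-D images")
    return arr.mean(axis=0)


def _percentiles(per_acquisition: np.ndarray) -> dict[float, np.ndarray]:
    # linear interpolation between order statistics (numpy default)
    p = np.percentile(per_acquisition, PERCENTILE_LEVELS, axis=0, method="linear")
    return {level: p[k] for k, level in enumerate(PERCENTILE_LEVELS)}


def nld_object(
    stack: AcquisitionStack, config: ReconConfig, geom: FanBeamGeometry | None = None
) -> NLDObjectResult:
    """NLDobject: average after reconstruction minus reconstruction of the
    average, with per-acquisition percentile maps."""
    geom = geom or stack.geometry
    if stack.n < 2:
        raise ValueError("NLDobject needs at least 2 acquisitions")
    recons = reconstruct_stack(stack.sinograms, config, geom)
    sb_bar = recons.mean(axis=0)
    sb_tilde = reconstruct_stack(stack.sinograms.mean(axis=0), config, geom)
    per_acq = recons - sb_tilde
    return NLDObjectResult(
        nld_image=sb_bar - sb_tilde,
        sb_bar=sb_bar,
        sb_tilde=sb_tilde,
        per_acquisition=per_acq,
        percentiles=_percentiles(per_acq),
        n=stack.n,
        cnr=stack.cnr_target,
        variant="exact",
    )


def nld_object_approx(
    stack: AcquisitionStack,
    config: ReconConfig,
    low_noise_image: np.ndarray | AttenuationImage,
    geom: FanBeamGeometry | None = None,
) -> NLDObjectResult:
    """NLDobject': the averaged noisy reconstructions minus one separately
    acquired low-noise reconstruction (must use the same pipeline config)."""
    geom = geom or stack.geometry
    low = (
        low_noise_image.values
        if isinstance(low_noise_image, AttenuationImage)
        else np.asarray(low_noise_image, dtype=np.float64)
    )
    if low.shape != geom.image_shape:
        raise ValueError("low-noise image grid does not match geometry")
    recons = reconstruct_stack(stack.sinograms, config, geom)
    sb_bar = recons.mean(axis=0)
    per_acq = recons - low
    return NLDObjectResult(
        nld_image=sb_bar - low,
        sb_bar=sb_bar,
        sb_tilde=low,
        per_acquisition=per_acq,
        percentiles=_percentiles(per_acq),
        n=stack.n,
        cnr=stack.cnr_target,
        variant="approx",
    )


def nld_noise(
    stack: AcquisitionStack, config: ReconConfig, geom: FanBeamGeometry | None = None
) -> NLDNoiseResult:
    """NLDnoise series: noise reconstructed with the object present minus
    noise reconstructed with the object absent, per acquisition.

    The object-absent branch reconstructs signed, near-zero difference
    sinograms; every pipeline accepts negative attenuation values.
    """
    geom = geom or stack.geometry
    if stack.n < 2:
        raise ValueError("NLDnoise needs at least 2 acquisitions")
    recons = reconstruct_stack(stack.sinograms, config, geom)
    sb_bar = recons.mean(axis=0)
    b_bar = recons - sb_bar
    diffs = stack.sinograms - stack.sinograms.mean(axis=0)
    b_tilde = reconstruct_stack(diffs, config, geom, difference=True)
    return NLDNoiseResult(
        series=b_bar - b_tilde,
        b_bar=b_bar,
        b_tilde=b_tilde,
        n=stack.n,
        cnr=stack.cnr_target,
    )


# ---------------------------------------------------------------------------
# ROI statistics, CNR, profiles
# ---------------------------------------------------------------------------


def _values(image) -> np.ndarray:
    return image.values if isinstance(image, AttenuationImage) else np.asarray(image)


def roi_stats(image, roi: RoiSpec) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (N-1) over an ROI."""
    vals = roi.extract(_values(image))
    return float(vals.mean()), float(vals.std(ddof=1))


def cnr(image, liver_roi: RoiSpec, muscle_roi: RoiSpec) -> float:
    """(mean liver - mean muscle) / sigma muscle, on one image."""
    liver_mean, _ = roi_stats(image, liver_roi)
    muscle_mean, muscle_sigma = roi_stats(image, muscle_roi)
    if muscle_sigma == 0:
        raise ValueError("zero muscle standard deviation; CNR undefined")
    return float((liver_mean - muscle_mean) / muscle_sigma)


def extract_profile(image, row: int, col_start: int, length: int) -> np.ndarray:
    """Contiguous left-to-right pixel values of one image row segment."""
    vals = _values(image)
    if length < 1:
        raise ValueError("profile length must be >= 1")
    if not (0 <= row < vals.shape[0]):
        raise ValueError(f"profile row {row} outside image of {vals.shape[0]} rows")
    if col_start < 0 or col_start + length > vals.shape[1]:
        raise ValueError("profile segment extends beyond the image")
    return vals[row, col_start : col_start + length].copy()
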