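"""Simulated repeated CT acquisitions and noise-level calibration.

The acquisition chain: the noise-free sinogram (line integrals of mu) is
transformed by Beer-Lambert's law into expected detector counts
``I0 * exp(-s)``, Poisson noise is drawn per detector element, and the noisy
counts are log-transformed back to attenuation data.  Averaging always
happens on the attenuation (post-log) data.  The incident intensity I0 is
uniform over detector elements and angles (ideal system, no bowtie or tube
current modulation), and counts are floored at one photon before the log so
every sample stays finite even in photon starvation.

Noise levels are specified as a contrast-to-noise ratio (CNR) measured on
FBP reconstructions: (mean liver HU - mean muscle HU) / sigma of muscle HU.
``calibrate_incident_intensity`` inverts that definition, finding the I0
whose FBP images hit a target CNR, using the scaling CNR ~ sqrt(I0) for the
initial guess followed by bisection with common random numbers.  The
contrast term is taken from the FBP image of the noise-free sinogram (the
deterministic part of the estimator); the noise term averages the muscle-ROI
sample standard deviation over independent noisy realizations.

Seed policy: every acquisition i of a stack uses seed
``master_seed * 10**6 + i`` (i = 1..N); calibration, lambda tuning and the
separate low-noise acquisition draw from disjoint offsets of the same
master seed, so a whole experiment is reproducible from one integer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import AttenuationImage, RoiSpec
from .projection import FanBeamGeometry, Sinogram, forward_project
from .reconstruct import fbp_mu_stack, tvl1_denoise_values

__all__ = [
    "AcquisitionStack",
    "attenuation_to_counts",
    "apply_poisson",
    "counts_to_attenuation",
    "acquisition_seed",
    "simulate_stack",
    "simulate_low_noise",
    "measure_fbp_cnr",
    "calibrate_incident_intensity",
    "tune_tv_lambda",
]

COUNT_FLOOR = 1.0

# seed offsets for the independent random streams of one experiment
_SEED_STACK = 0  # + i, i = 1..N
_SEED_CALIBRATION = 500_000  # + j
_SEED_TUNING = 600_000  # + j
_SEED_LOW_NOISE = 999_999


def acquisition_seed(master_seed: int, i: int, offset: int = _SEED_STACK) -> int:
    """Derived seed for acquisition ``i``: ``master_seed * 10**6 + offset + i``."""
    return int(master_seed) * 10**6 + offset + int(i)


def attenuation_to_counts(sino: Sinogram | np.ndarray, i0: float) -> np.ndarray:
    """Beer-Lambert: expected counts ``I0 * exp(-line integral)``."""
    if i0 <= 0:
        raise ValueError("incident intensity I0 must be positive")
    values = sino.values if isinstance(sino, Sinogram) else np.asarray(sino)
    return i0 * np.exp(-values)


def apply_poisson(counts: np.ndarray, seed: int) -> np.ndarray:
    """Independent Poisson draw per sample; reproducible for a fixed seed."""
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("expected counts must be nonnegative")
    rng = np.random.default_rng(seed)
    return rng.poisson(counts).astype(np.float64)


def counts_to_attenuation(counts: np.ndarray, i0: float) -> np.ndarray:
    """Log transform back to line integrals, flooring counts at one photon."""
    if i0 <= 0:
        raise ValueError("incident intensity I0 must be positive")
    counts = np.asarray(counts, dtype=np.float64)
    return -np.log(np.maximum(counts, COUNT_FLOOR) / i0)


@dataclass
class AcquisitionStack:
    """N noisy sinograms of the same object at one noise level."""

    sinograms: np.ndarray  # (N, n_angles, n_detectors), attenuation data
    geometry: FanBeamGeometry
    incident_intensity: float
    master_seed: int
    seeds: tuple[int, ...]
    cnr_target: float | None = None
    noise_free: np.ndarray | None = None  # noise-free forward projection

    def __post_init__(self):
        self.sinograms = np.asarray(self.sinograms, dtype=np.float64)
        if self.sinograms.ndim != 3 or self.sinograms.shape[0] < 1:
            raise ValueError("stack must hold at least one sinogram")
        if self.sinograms.shape[1:] != self.geometry.sinogram_shape:
            raise ValueError("stack shape does not match geometry")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("per-acquisition seeds must be pairwise distinct")
        if not np.all(np.isfinite(self.sinograms)):
            raise ValueError("stack contains non-finite values")

    @property
    def n(self) -> int:
        return self.sinograms.shape[0]

    def sinogram(self, i: int) -> Sinogram:
        return Sinogram(self.sinograms[i], self.geometry)


def _noisy_sinograms(
    noise_free: np.ndarray, i0: float, seeds: list[int]
) -> np.ndarray:
    expected = attenuation_to_counts(noise_free, i0)
    out = np.empty((len(seeds),) + noise_free.shape)
    for k, seed in enumerate(seeds):
        out[k] = counts_to_attenuation(apply_poisson(expected, seed), i0)
    return out


def simulate_stack(
    phantom: AttenuationImage,
    geom: FanBeamGeometry,
    i0: float,
    n: int,
    master_seed: int,
    cnr_target: float | None = None,
) -> AcquisitionStack:
    """Simulate N independent noisy acquisitions of the phantom."""
    if n < 1:
        raise ValueError("need at least one acquisition")
    noise_free = forward_project(phantom, geom).values
    seeds = [acquisition_seed(master_seed, i) for i in range(1, n + 1)]
    sinos = _noisy_sinograms(noise_free, i0, seeds)
    return AcquisitionStack(
        sinograms=sinos,
        geometry=geom,
        incident_intensity=float(i0),
        master_seed=int(master_seed),
        seeds=tuple(seeds),
        cnr_target=cnr_target,
        noise_free=noise_free,
    )


def simulate_low_noise(
    phantom: AttenuationImage,
    geom: FanBeamGeometry,
    i0: float,
    n: int,
    master_seed: int,
) -> Sinogram:
    """One acquisition at ``I0' = N * I0``: to first order its variance equals
    that of the average of N acquisitions at I0 (the separate low-noise
    acquisition used by the approximate object-distortion image)."""
    noise_free = forward_project(phantom, geom).values
    seed = acquisition_seed(master_seed, 0, _SEED_LOW_NOISE)
    values = _noisy_sinograms(noise_free, n * i0, [seed])[0]
    return Sinogram(values, geom)


# ---------------------------------------------------------------------------
# CNR calibration
# ---------------------------------------------------------------------------


def measure_fbp_cnr(
    phantom: AttenuationImage,
    geom: FanBeamGeometry,
    i0: float,
    liver_roi: RoiSpec,
    muscle_roi: RoiSpec,
    master_seed: int,
    n_realizations: int = 48,
    window: str = "hamming",
    _noise_free: np.ndarray | None = None,
) -> float:
    """Measured FBP CNR at intensity I0, averaged over fresh realizations.

    Contrast comes from the noise-free FBP reconstruction; sigma is the mean
    muscle-ROI sample standard deviation over ``n_realizations`` noisy FBP
    images.
    """
    if n_realizations < 8:
        raise ValueError("use at least 8 realizations to stabilize the estimate")
    noise_free = (
        forward_project(phantom, geom).values if _noise_free is None else _noise_free
    )
    ref = fbp_mu_stack(noise_free, geom, window)
    contrast = liver_roi.extract(ref).mean() - muscle_roi.extract(ref).mean()
    seeds = [
        acquisition_seed(master_seed, j, _SEED_CALIBRATION)
        for j in range(n_realizations)
    ]
    recons = fbp_mu_stack(_noisy_sinograms(noise_free, i0, seeds), geom, window)
    sigmas = [muscle_roi.extract(r).std(ddof=1) for r in recons]
    sigma = float(np.mean(sigmas))
    if sigma == 0:
        raise ValueError("zero muscle-ROI standard deviation")
    return float(contrast / sigma)


def calibrate_incident_intensity(
    phantom: AttenuationImage,
    geom: FanBeamGeometry,
    cnr_target: float,
    liver_roi: RoiSpec,
    muscle_roi: RoiSpec,
    master_seed: int,
    n_realizations: int = 48,
    tol: float = 0.01,
    i0_start: float = 1.0e5,
    window: str = "hamming",
) -> float:
    """Find the incident intensity I0 whose FBP images hit ``cnr_target``.

    Initial guess from CNR ~ sqrt(I0), then bisection on log I0 using common
    random numbers across evaluations (the measured CNR is then strictly
    monotone in I0 and the bisection is clean).
    """
    if cnr_target <= 0:
        raise ValueError("cnr_target must be positive")
    noise_free = forward_project(phantom, geom).values

    def measure(i0: float) -> float:
        return measure_fbp_cnr(
            phantom,
            geom,
            i0,
            liver_roi,
            muscle_roi,
            master_seed,
            n_realizations,
            window,
            _noise_free=noise_free,
        )

    c_start = measure(i0_start)
    i0 = i0_start * (cnr_target / c_start) ** 2  # CNR scales like sqrt(I0)
    c = measure(i0)
    if abs(c - cnr_target) <= tol * cnr_target:
        return float(i0)

    lo, hi = i0 / 1.5, i0 * 1.5
    c_lo, c_hi = measure(lo), measure(hi)
    doublings = 0
    while not (c_lo < cnr_target < c_hi):
        if c_lo >= cnr_target:
            lo /= 2.0
            c_lo = measure(lo)
        if c_hi <= cnr_target:
            hi *= 2.0
            c_hi = measure(hi)
        doublings += 1
        if doublings > 20:
            raise RuntimeError(
                f"CNR calibration failed to bracket target {cnr_target}"
            )
    for _ in range(40):
        mid = np.sqrt(lo * hi)
        c = measure(mid)
        if abs(c - cnr_target) <= tol * cnr_target:
            return float(mid)
        if c < cnr_target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


# ---------------------------------------------------------------------------
# TV regularisation weight tuning
# ---------------------------------------------------------------------------


def tune_tv_lambda(
    phantom: AttenuationImage,
    geom: FanBeamGeometry,
    i0: float,
    muscle_roi: RoiSpec,
    master_seed: int,
    n_realizations: int = 16,
    tv_iterations: int = 50,
    tol: float = 0.02,
    window: str = "hamming",
) -> float:
    """Tune the TV-L1 weight so its noise reduction matches the 3x3 median.

    The matching criterion is the ratio of the muscle-ROI sigma of FBP
    reconstructions of denoised vs. raw sinograms.  With common random
    numbers the ratio is a deterministic function of lambda; it falls from 1
    to a floor and rises again (over-regularised staircasing is amplified by
    the ramp filter), so the tuner scans a log grid and golden-refines the
    lambda whose ratio is *closest* to the median filter's.  When the median
    reduction lies below the achievable TV-L1 floor the closest match is the
    floor.  TV strength depends on grid resolution, so the weight is
    re-tuned per scale preset instead of reusing the full-size value.
    """
    import scipy.ndimage as ndi

    noise_free = forward_project(phantom, geom).values
    seeds = [acquisition_seed(master_seed, j, _SEED_TUNING) for j in range(n_realizations)]
    noisy = _noisy_sinograms(noise_free, i0, seeds)

    def mean_sigma(stack: np.ndarray) -> float:
        recons = fbp_mu_stack(stack, geom, window)
        return float(np.mean([muscle_roi.extract(r).std(ddof=1) for r in recons]))

    sigma_raw = mean_sigma(noisy)
    sigma_med = mean_sigma(ndi.median_filter(noisy, size=(1, 3, 3), mode="reflect"))
    target = sigma_med / sigma_raw

    def ratio(lam: float) -> float:
        den = tvl1_denoise_values(noisy, lam, tv_iterations)
        means = den.mean(axis=(1, 2))
        den *= (noisy.mean(axis=(1, 2)) / means)[:, None, None]
        return mean_sigma(den) / sigma_raw

    def mismatch(lam: float) -> float:
        return abs(ratio(lam) - target)

    grid = np.geomspace(0.05, 6.0, 13)
    scores = [mismatch(l) for l in grid]
    k = int(np.argmin(scores))
    if scores[k] <= tol * target:
        return float(grid[k])
    # golden-section refinement on log(lambda) around the best grid point
    lo = np.log(grid[max(k - 1, 0)])
    hi = np.log(grid[min(k + 1, len(grid) - 1)])
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = hi - invphi * (hi - lo)
    d = lo + invphi * (hi - lo)
    fc, fd = mismatch(np.exp(c)), mismatch(np.exp(d))
    for _ in range(12):
        if fc < fd:
            hi, d, fd = d, c, fc
            c = hi - invphi * (hi - lo)
            fc = mismatch(np.exp(c))
        else:
            lo, c, fc = c, d, fd
            d = lo + invphi * (hi - lo)
            fd = mismatch(np.exp(d))
    return float(np.exp((lo + hi) / 2.0))
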