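# Methods

## The residual method

A CT reconstruction pipeline `f` mapping a sinogram to an image is linear
iff it satisfies superposition, and in particular iff averaging commutes
with it: the average of N reconstructed noisy acquisitions equals the
reconstruction of the averaged sinogram.  `nldct` measures the failure of
exactly that commutation and presents it as images:

* **NLDobject** `= SB̄_{n,N} − SB̃_{n,N}`, where `SB̄` is the pixelwise
  average of the N reconstructions of noisy sinograms `sb_{n,i}` and `SB̃`
  is the reconstruction of their pixelwise average (an approximately
  noise-free sinogram).  Any structure in this residual is *systematic*
  nonlinear distortion of the object at noise level n.
* **NLDobject′** replaces `SB̃` by a single, separately acquired low-noise
  reconstruction (simulated at incident intensity `N·I0`, which to first
  order has the variance of an N-average).  It has the same expectation but
  higher random uncertainty; it is the variant available on a scanner that
  does not expose raw sinograms.
* **NLDnoise_i** `= B̄_{n,i} − B̃_{n,i}` per acquisition, where
  `B̄_i = f(sb_i) − SB̄` isolates noise *after* reconstruction (object
  present) and `B̃_i = f(sb_i − s̃b)` isolates noise *before* reconstruction
  (object absent).  It shows whether the pipeline treats noise differently
  when the object is present.

For any linear pipeline all three residuals vanish to floating-point
precision; the test suite verifies ≤ 1e−6 HU for FBP and for a single
zero-initialised SIRT sweep, and the acceptance criterion uses the looser
published bound of 1e−3 HU.

Per-acquisition distortion estimates are defined as
`D_i = f(sb_i) − SB̃`; their pixelwise mean is NLDobject up to float
reassociation, and their pixelwise 5th/50th/95th percentiles (linear
interpolation between order statistics) summarise the distortion
distribution.  This definition of `D_i` is a design choice: subtracting
`SB̄` instead would force the mean to zero and hide the systematic part.

### Units in the residual arithmetic

Reconstructions of *object* sinograms are converted to Hounsfield units
with the full affine map `HU = 1000(μ − μ_w)/μ_w`.  Reconstructions of
*difference* (noise-only) sinograms use the HU scale without the −1000
offset: applying the affine map to a noise-only reconstruction would add a
constant −1000 HU to `B̃` and make NLDnoise ≡ +1000 HU even for a
perfectly linear pipeline.  With the scale-only convention the linear-null
identities hold exactly; the nonlinear pipelines applied to difference data
are interpreted in the same HU-difference units.

## Simulation chain

**Phantom.** An analytic ellipse composition mimicking an abdominal slice:
body outline in soft tissue (20 HU), two lung fields (−780 HU), liver
(95 HU), two longissimus muscles (40 HU), a vertebra and four costae
(700 HU), and two contrast-filled vessels (liver + 200 HU).  Attenuation
anchors at 60 keV are taken from standard tabulations (water 0.0206 /mm;
dry air 2.26e−5 /mm; cortical bone 0.0604 /mm), and every tissue must lie
within the dry-air–cortical-bone range.  The liver−muscle contrast is
fixed at 55 HU, the value implied by the product of the calibrated CNR and
the corresponding FBP noise level (e.g. 2.4 × 23 HU ≈ 55).  Because the
phantom is analytic it rescales exactly; ROI definitions are quoted at the
768-px grid (muscle ROI 60×20 px, costa-edge window 20 px) and scaled
proportionally.  The vessel contrast (+200 HU) is a free choice — any value
well above liver demonstrates the vessel-distortion effect qualitatively.

**Geometry.** Fan beam, flat detector, element pitch defined at the
isocenter; source–isocenter 696.7 mm, source–detector 1085.6 mm, full
rotation with evenly spaced angles.  Two presets:

| preset | grid | pixel | detectors | angles |
|--------|------|-------|-----------|--------|
| desk   | 128² | 1 mm  | 192       | 360    |
| paper-scale | 768² | 1 mm | 1474 | 1152  |

All tests and the acceptance experiments run at desk scale so the whole
suite fits on one CPU in minutes; image statistics are restricted to the
central 512/768 fraction of the grid (the clinical field-of-view
convention), scaled per preset.

**Projector.** Joseph-style interpolating line integrals: each ray steps
one pixel along its dominant axis and interpolates linearly along the
other, which integrates the bilinearly interpolated image exactly along
the ray.  The back projector is the exact sparse transpose, so
`<Ax, y> = <x, Aᵀy>` holds to machine precision — SIRT and CGLS rely on the
matched pair.  At desk scale the operator is materialised once per
geometry as a CSR matrix (~10.7 M non-zeros) and applied to whole
acquisition stacks as sparse-times-dense products.

**Noise.** The noise-free sinogram is mapped to expected counts
`I0·exp(−s)` (Beer–Lambert), Poisson noise is drawn per detector element,
and noisy counts are mapped back by `−ln(max(counts, 1)/I0)`.  The
one-photon floor is the simplest finite-value policy for photon
starvation and matters only at the lowest noise level.  `I0` is uniform
across elements and angles (ideal system).  Averaging is always performed
on the post-log attenuation data.  Seeds: acquisition i of a stack uses
`master_seed·10⁶ + i`; calibration, tuning and the low-noise acquisition
use disjoint offsets of the same master seed.

**CNR calibration.** The noise level is specified as the contrast-to-noise
ratio of FBP images: (liver − muscle mean) / muscle σ, on the same
default ROIs used for all other statistics.  The calibration measures the
contrast on the FBP reconstruction of the noise-free sinogram (the
deterministic part of the estimator — standard simulation variance
reduction; a fully Monte-Carlo contrast estimate at CNR 0.4 would need
~10³ realizations for percent-level precision) and the muscle σ as the
mean spatial sample SD over ≥ 8 (default 48) noisy FBP realizations.  The
initial guess uses the scaling CNR ∝ √I0; bisection on log I0 with common
random numbers then converges to ~1%.  Calibrated intensities are strictly
increasing in the target CNR.

## Reconstruction pipelines

* **FBP** — cosine pre-weighting, ramp filter built from the exact
  band-limited spatial kernel and apodised with a Hamming window in
  frequency (zero-padding to the next power of two ≥ 2·n_detectors),
  distance-weighted (1/U²) pixel-driven backprojection over the full
  rotation with a factor ½ for the double ray coverage.
* **SIRTmed** — 3×3 median filter on the sinogram (reflect padding), then
  exactly 100 SIRT iterations `x ← x + C Aᵀ R (b − A x)` (R, C inverse
  row/column sums; zero sums map to zero) started from the FBP image of
  the filtered sinogram.  No positivity constraint, no early stopping.
* **CGLSTV** — TV-L1 denoising of the sinogram, contrast renormalisation
  by the mean ratio of unprocessed to processed sinogram, then exactly 100
  CGLS iterations warm-started at the FBP image of the denoised sinogram.

**TV-L1 solver.** First-order primal-dual (Chambolle–Pock) on
`E(u) = ‖u − g‖₁ + λ·TV(u)` with isotropic TV, forward-difference
gradient with Neumann boundaries, steps τ = σ = 1/√8 (bounded by the
gradient-operator norm), θ = 1, started at `u = g`, run for a fixed
iteration count (default 50 outer iterations).  The fidelity-first form
means larger λ smooths more; a constant input is an exact fixed point, and
the λ → 0 limit returns the input exactly.  The objective is observed to
be non-increasing on the test inputs and is asserted as such in the suite.

**λ tuning.** The TV weight is defined by matching the median filter's
noise reduction.  The package measures the reduction as the ratio of
muscle-ROI σ of FBP reconstructions of denoised vs. raw sinograms (the
same FBP probe that defines CNR), with common random numbers so the ratio
is a deterministic, resolution-dependent function of λ.  At desk scale the
TV-L1 ratio has a floor slightly above the median filter's ratio (the
staircase residual of strong TV is amplified by the ramp filter), so the
tuner returns the λ whose ratio is *closest* to the target: a log-grid
scan followed by golden-section refinement.  TV strength depends on grid
resolution, so the weight is re-tuned per scale preset rather than
reusing the full-size value (1.9); the tuned desk value lands near 0.5.

## Iterative noise amplification and scale

A finding the test suite documents honestly: the noise behaviour of a
fixed iteration count is strongly grid-size dependent.  On the desk grid
(16k unknowns), 100 CGLS iterations essentially reach the unregularised
least-squares solution and amplify the (denoised) sinogram noise by an
order of magnitude; 100 SIRT iterations amplify it by ~1.6×.  The same
experiment at 256² shows both factors falling (≈1.3× for SIRT), and at the
768² full-size grid the implied factors are small enough that the
reported noise reductions of the denoising pipelines (~40%) are dominated
by the sinogram denoisers themselves.  Consequently the desk-scale
noise-reduction acceptance experiment, which fixes 100 iterations,
measures *negative* reductions for the iterative pipelines; the package
computes and reports it faithfully rather than re-tuning the iteration
count, since the count is part of the study conditions.  The
corresponding acceptance test is expected to fail at desk scale and
documents this in its assertion message.

## What the synthetic data does and does not show

The generator reproduces the study conditions: an ideal monochromatic
system with a perfect detector, uniform I0, Poisson counting noise only,
and an ellipse phantom with uniform tissues.  Real acquisitions add
electronic noise, scatter, polychromatic beam hardening, focal-spot blur
and detector non-uniformity (ring artifacts) — all of which would appear
*inside* the NLD residuals of a real system, since the method cannot
distinguish the source of a nonlinearity.  Passing tests therefore show
the correctness of the residual arithmetic and of the simulation chain,
and the qualitative behaviour of the two denoising pipelines at desk
scale; they do not certify distortion magnitudes of any clinical system,
and the pixelwise values differ from any specific published figure
because the test object, projector discretization and TV solver are not
reproducible from text.

## Numerical choices

* All arithmetic in float64; the system matrix is exact-transpose matched.
* Count floor 1 photon before the log transform.
* Percentiles by linear interpolation between order statistics.
* "Exact" identity tests allow only float-reassociation tolerances
  (≤ 1e−9 HU); stochastic tests use CLT bounds with stated z-limits.
* Degenerate inputs: zero-row/column normalizations in SIRT map to zero
  update; contrast renormalisation refuses a zero-mean denoised sinogram
  (noise-only difference sinograms have near-zero means — their huge
  renormalisation ratios are a real property of the pipeline, reproduced
  deliberately, and explain the very large NLDnoise amplitudes of the TV
  pipeline).
* Desk-scale experiment sizes: N = 32 acquisitions for the NLD and noise
  tables (8/16/32 grid in the orchestrator), 48 realizations for
  calibration, 16 for λ tuning.  These sizes give ~1–4% standard errors on
  the statistics the tests assert.

## Known limitations

* 2-D fan beam only; no curved detector, cone beam, helical scan or short
  scans.
* No detector model, scatter, spectrum or focal-spot effects (by design —
  the study isolates algorithmic nonlinearity).
* The iterative-pipeline noise behaviour at desk scale differs
  structurally from full scale (see above); full-scale iterative runs are
  representable but not exercised by the test suite.
* No scalar figure of merit for distortion–object correlation; the
  outputs are images, profiles and ROI tables.
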