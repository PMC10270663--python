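# nldct

**Isolate and visualize the nonlinear distortion of CT noise-reduction
algorithms.**

Modern CT reconstruction reduces image noise with nonlinear algorithms
(sinogram filters, iterative techniques, learned denoisers).  Their effect
on image quality depends on the imaged object and on the noise level, so
linear-systems metrics no longer tell the whole story: part of the object
signal can be *distorted* — moved into other structures — rather than
merely blurred.  `nldct` implements a residual method that isolates exactly
this nonlinearity, for medical-physics researchers who want to audit a
noise-reduction pipeline independently of any other algorithm.

## The method

A reconstruction pipeline `f` is linear iff averaging commutes with it.
Given `N` repeated noisy acquisitions `sb_i` of the same object:

* **NLDobject** `= (1/N) Σ f(sb_i) − f((1/N) Σ sb_i)` — the average of the
  reconstructions minus the reconstruction of the averaged (approximately
  noise-free) sinogram.  Structure in this image is systematic nonlinear
  distortion of the *object* at that noise level.
* **NLDobject′** substitutes a separately acquired low-noise image for the
  second term — the practical variant when raw sinograms are unavailable.
* **NLDnoise_i** `= [f(sb_i) − SB̄] − f(sb_i − s̃b)` — noise isolated after
  reconstruction (object present) minus noise isolated before
  reconstruction (object absent); it shows how the pipeline's treatment of
  *noise* depends on the object.

For a linear pipeline all residuals vanish; any structure certifies
nonlinearity.  The package ships the full simulation chain needed to
exercise the method with no external data: an analytic abdominal ellipse
phantom, a matched Joseph fan-beam projector pair, Poisson acquisition with
CNR calibration, and three pipelines — FBP (Hamming), median-filtered SIRT
(`SIRTmed`) and TV-L1-filtered CGLS (`CGLSTV`).  See `docs/methods.md` for
the model details and design choices.

## Worked example

```python
import numpy as np
from nldct import (ReconConfig, build_phantom, desk_geometry,
                   nld_object, simulate_stack)

geom = desk_geometry()
phantom = build_phantom(geom.image_rows, geom.pixel_size)
stack = simulate_stack(phantom, geom, i0=2000.0, n=8, master_seed=1)

linear = nld_object(stack, ReconConfig.fbp_preset(), geom)
nonlin = nld_object(stack, ReconConfig.sirtmed_preset(), geom)
print(f"FBP     max |NLDobject| = {np.abs(linear.nld_image).max():.2e} HU")
print(f"SIRTmed max |NLDobject| = {np.abs(nonlin.nld_image).max():.1f} HU")
```

prints

```
FBP     max |NLDobject| = 3.18e-12 HU
SIRTmed max |NLDobject| = 88.8 HU
```

FBP is linear, so its residual sits at floating-point scale — twelve
orders of magnitude below the nonlinear pipeline, whose distortion
concentrates at tissue edges (run `examples/nonlinear_distortion_map.py`
for the edge-enrichment statistics, and the other `examples/` scripts for
the approximate variant and the linearity control).

## Command line

A thin CLI mirrors the library stages:

```sh
nldct phantom --scale desk --out out/
nldct calibrate --scale desk --cnr 2.4 --seed 1
nldct simulate --scale desk --i0 2978 -n 16 --out out/
nldct nld-object --stack out/stack.tiff --pipeline sirtmed --out out/
nldct run --scale desk --seed 1 --out out/run     # the full grid
nldct report --manifest out/run/manifest.json
```

`nldct run` calibrates each requested CNR (0.4, 0.7, 1.4, 2.4 by default),
simulates acquisition stacks, computes all NLD images, percentile maps,
profiles and the muscle-noise table, and writes float-TIFF artifacts with
a JSON manifest; `report` renders the panels at the study display windows
(NLDobject at −10..10 HU, NLDnoise at −50..50 HU).

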