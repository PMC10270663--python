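"""Linearity null test: FBP produces no nonlinear distortion.

Builds the desk-scale phantom, simulates eight noisy acquisitions, and
computes the NLDobject image and the NLDnoise series for plain FBP.  For a
linear pipeline both residuals vanish to floating point, far below the
published 1e-3 HU bound — this is the control experiment that validates
the residual arithmetic.
"""

import numpy as np

from nldct import (
    ReconConfig,
    build_phantom,
    desk_geometry,
    nld_noise,
    nld_object,
    simulate_stack,
)

geom = desk_geometry()
phantom = build_phantom(geom.image_rows, geom.pixel_size)
stack = simulate_stack(phantom, geom, i0=2000.0, n=8, master_seed=1)

cfg = ReconConfig.fbp_preset()
obj = nld_object(stack, cfg, geom)
noise = nld_noise(stack, cfg, geom)

print(f"max |NLDobject|  = {np.abs(obj.nld_image).max():.2e} HU")
print(f"max |NLDnoise_i| = {np.abs(noise.series).max():.2e} HU")
print("Both are at floating-point scale (<= 1e-3 HU): FBP is linear, so")
print("averaging before and after reconstruction commute and the residuals")
print("carry no structure.")
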