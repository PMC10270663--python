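"""Map the nonlinear distortion of a median-filtered SIRT pipeline.

Calibrates the incident intensity to a contrast-to-noise ratio of 2.4 on
FBP images, simulates N = 16 noisy acquisitions, and computes the
NLDobject image for the median + SIRT pipeline.  The residual concentrates
at tissue edges — the signature of noise-dependent smoothing by the
nonlinear filter — and its magnitude is orders above the linear-FBP floor.

Runtime: a couple of minutes on one CPU (the calibration and the
100-iteration SIRT reconstructions dominate).
"""

import numpy as np

from nldct import (
    ReconConfig,
    build_phantom,
    calibrate_incident_intensity,
    cnr_rois,
    desk_geometry,
    edge_mask,
    nld_object,
    simulate_stack,
)
from nldct.projection import analysis_roi_slices

geom = desk_geometry()
phantom = build_phantom(geom.image_rows, geom.pixel_size)
liver, muscle = cnr_rois(geom.image_rows)

i0 = calibrate_incident_intensity(phantom, geom, 2.4, liver, muscle, master_seed=1)
print(f"calibrated I0 = {i0:.0f} photons/element for CNR 2.4")

stack = simulate_stack(phantom, geom, i0, n=16, master_seed=1, cnr_target=2.4)
res = nld_object(stack, ReconConfig.sirtmed_preset(), geom)

sl = analysis_roi_slices(geom)
roi = res.nld_image[sl]
edges = edge_mask(phantom)[sl]
top = np.abs(roi) >= np.quantile(np.abs(roi), 0.9)
enrichment = edges[top].mean() / edges.mean()

print(f"mean |NLDobject| in analysis ROI = {np.abs(roi).mean():.2f} HU")
print(f"max  |NLDobject|                 = {np.abs(roi).max():.1f} HU")
print(f"edge enrichment of top-decile pixels = {enrichment:.2f}x")
print("Values far above the 1e-3 HU linear floor certify nonlinearity; the")
print("enrichment > 1 shows the distortion sits at tissue boundaries, i.e.")
print("the median filter smooths edges more as the noise level rises.")
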