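"""Compute the DTI-ALPS index on a diffusion phantom with known answer.

Builds a two-shell DWI phantom (2 x b=0, 45 directions at b=1000, 90 at
b=2500 s/mm^2) with projection-fiber blocks (principal axis Z) and
association-fiber blocks (principal axis Y), fits diffusion + kurtosis
tensors, and evaluates the ALPS ratio in four bilateral 16 mm^2 ROIs.
"""

import glymkit as gk

# ground-truth ALPS = ((1.5 + 1.5)/2) / ((1.0 + 1.0)/2) = 1.5
spec = gk.make_alps_tensor_field(
    dxx_proj=1.5e-3, dyy_proj=1.0e-3, dzz_proj=1.6e-3,
    dxx_assoc=1.5e-3, dyy_assoc=1.6e-3, dzz_assoc=1.0e-3,
    snr=30.0, noise_model="rician", seed=0,
)
print(f"analytic ground-truth ALPS: {spec.alps_truth:.4f}")

dwi, truth = gk.make_dwi_phantom(spec)
tf = gk.fit_dki_lls(dwi, spec.gtab, mask=spec.labels > 0, spacing=(spec.spacing,) * 3)
dxx, dyy, dzz = gk.extract_diffusivity_maps(tf)
rois = gk.make_alps_rois(spec.shape, (spec.spacing,) * 3, spec.roi_centers)
res = gk.compute_alps_index(dxx, dyy, dzz, rois, fit_mask=tf.mask, fit_method=tf.fit_method)

print(f"estimated ALPS at SNR 30:   {res.alps_index:.4f}")
print(f"  Dxx (projection, bilateral mean): {res.dxx_proj:.2e} mm^2/s")
print(f"  Dyy (projection):                 {res.dyy_proj:.2e} mm^2/s")
print(f"  Dxx (association):                {res.dxx_assoc:.2e} mm^2/s")
print(f"  Dzz (association):                {res.dzz_assoc:.2e} mm^2/s")
# ALPS > 1 means diffusivity along the perivascular (x) axis exceeds the
# diffusivity perpendicular to the fiber systems - the signature of an
# open perivascular transport route. The Rician-noise estimate should sit
# within a few percent of 1.5.
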