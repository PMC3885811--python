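"""Estimate tensors from a simulated DWI and derive scalar maps.

Shows the weighted-least-squares tensor fit recovering the phantom exactly
in the noise-free case, the negative-eigenvalue filter, and the standard
scalar maps (FA, MD, RD, AD) with their closed-form values.
"""

import numpy as np

import tractokit as tk
from tractokit.tensor import scalars_from_eigenvalues

spec = tk.PhantomSpec(shape=(12, 12, 12))
phantom = tk.make_tensor_phantom(spec)
table = tk.default_gradient_table(n_directions=6, b_value=1000.0)
dwi = tk.simulate_dwi(phantom, table, s0=1000.0, noise_sd=0.0)

est = tk.estimate_tensors(dwi, method="wls")
err = np.abs(est.tensors - phantom.tensors)[est.mask].max()
print(f"max tensor component error (noise-free fit): {err:.2e} mm^2/s")

filtered = tk.filter_negative_eigenvalues(est)
for name in ("fa", "md", "rd", "ad"):
    sm = tk.scalar_map(filtered, name)
    inside = sm.data[6, 6, 6]            # bundle voxel
    closed = scalars_from_eigenvalues(
        np.array(spec.eigenvalues_inside), name)
    print(f"{name.upper():>3}: bundle voxel {inside:.6f}  "
          f"closed form {closed:.6f}")
# The fitted maps agree with the closed forms evaluated on the phantom's
# eigenvalues; FA is guaranteed to lie in [0, 1] after filtering.

rgb = tk.color_fa(filtered)
print(f"color-FA at a bundle voxel (R,G,B): {np.round(rgb[6, 6, 6], 3)}")
# The bundle runs left-right, so the red channel carries all the FA.
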