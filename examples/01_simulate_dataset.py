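"""Simulate a synthetic ptychography dataset and look at what is in it.

Builds a Siemens-star-style complex object, a disk probe, and a jittered
raster scan; generates the noise-free diffraction stack through the exact
forward model; and writes everything (including the ground truth) to one
HDF5 file.
"""

import numpy as np

import ptychocg as pt

spec = pt.SimulationSpec(H=256, W=256, S=64, step=16, jitter=2, seed=0)
ds = pt.make_dataset(spec)
pt.write_dataset("star_dataset.h5", ds)

print(f"object          : {ds.shape[0]}x{ds.shape[1]} complex")
print(f"probe           : {ds.S}x{ds.S}, peak amplitude "
      f"{np.abs(ds.probe).max():.1f}")
print(f"scan            : {ds.n} positions, step {spec.step}, "
      f"jitter {spec.jitter}")
print(f"frames          : {ds.data.shape}, all >= 0: {bool((ds.data >= 0).all())}")
print(f"memory at scale : a 512-detector, 16K-pattern stack needs "
      f"{pt.estimate_diffraction_bytes(512, 16384, 4) / 2**30:.0f} GiB")

# The number of photons per frame is the total intensity; for noise-free
# data the stack is exactly |F Q psi|^2, so the gradient at the truth is 0.
g = pt.gradient(ds.ground_truth, ds.data, ds.probe, ds.positions)
print(f"gradient at truth: {np.linalg.norm(g):.2e}  (exact consistency)")
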