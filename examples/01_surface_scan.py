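"""Scan a phantom liver surface with tracked ultrasound and reconstruct it.

Builds a synthetic phantom, sweeps a tracked probe over it (with realistic
tracking noise and a few probe lift-offs), classifies per-frame contact,
filters candidate surface points with the local outlier factor, and
triangulates the accepted cloud into a surface mesh.
"""

import numpy as np

from sononav.insilico import train_default_contact_model
from sononav.phantom import PhantomConfig, generate_phantom, simulate_sweep
from sononav.scan import ScanConfig, scan_stream

config = PhantomConfig(seed=3, n_frames=300)
gt = generate_phantom(config)
frames, truth = simulate_sweep(gt, config)
model = train_default_contact_model()

cloud, mesh = scan_stream(frames, gt.calibration, model, ScanConfig())

true_z = gt.height_fn(cloud.points[:, :2])
err = np.abs(cloud.points[:, 2] - true_z)
n_contact = sum(l == "contact" for l in truth.contact_labels)

print(f"frames: {len(frames)} ({n_contact} with capsule contact)")
print(f"accepted surface points: {len(cloud)}")
print(f"mesh: {len(mesh.vertices)} vertices, {len(mesh.faces)} triangles")
print(f"surface error vs ground truth: mean {err.mean():.3f} mm, max {err.max():.3f} mm")
print()
print("The error is the vertical distance of each accepted point from the")
print("true phantom surface; with 0.2 mm tracking noise it stays well below")
print("1 mm, which is what makes margin-accurate planning possible.")
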