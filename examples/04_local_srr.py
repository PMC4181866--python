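"""Local (VOI) super-resolution reconstruction versus whole-volume.

Reconstructing only a padded box around a structure of interest gives
the same voxels inside the box at a fraction of the cost — the property
that makes interactive exploration of large volumes practical.
"""

import time

import numpy as np

from locsrr import VOI
from locsrr.phantom import (
    default_phantom_spec,
    default_study_geometry,
    generate_phantom,
    simulate_study,
)
from locsrr.solver import SRRConfig, reconstruct, reconstruct_voi, voi_core_slices

spec = default_phantom_spec(seed=1)
scene, truth = generate_phantom(spec)
stacks, ops = simulate_study(scene, 4, default_study_geometry(), seed=1)
cfg = SRRConfig()

t0 = time.perf_counter()
whole = reconstruct(stacks, ops, cfg)
t_whole = time.perf_counter() - t0

# a 2 mm box around the largest bead cluster
row = truth.table.loc[truth.table["size_vox"].idxmax()]
center = np.array([row.cx_mm, row.cy_mm, row.cz_mm])
voi = VOI(tuple(center - 1.0), tuple(center + 1.0))

t0 = time.perf_counter()
local = reconstruct_voi(voi, stacks, scene.grid, cfg)
t_local = time.perf_counter() - t0

core_local = local.image.data[voi_core_slices(voi, local.image.grid)]
core_whole = whole.image.data[voi_core_slices(voi, scene.grid)]
rel = np.linalg.norm(core_local - core_whole) / np.linalg.norm(core_whole)

n_ratio = scene.grid.num_voxels / local.image.grid.num_voxels
print(f"whole volume: {scene.grid.shape} = {scene.grid.num_voxels} voxels, "
      f"{t_whole:.1f} s")
print(f"local volume: {local.image.grid.shape} = "
      f"{local.image.grid.num_voxels} voxels, {t_local:.2f} s")
print(f"voxel-count ratio (predicted speedup): {n_ratio:.0f}x")
print(f"relative difference inside the VOI core: {rel:.2e}")
# the core difference is well below 1%: local SRR does not sacrifice
# reconstruction quality inside the region it was asked for
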