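"""Locate a VOI from planar optical views and register it to the MR frame.

A landmark seen in two planar views at different angles back-projects to
a unique 3D point; three or more such points fix a rigid transform
between the optical and MR frames.  Thresholding the optical signal then
yields VOIs that can be propagated into every rotated stack.
"""

import numpy as np

from locsrr import backproject_landmark, fit_rigid_landmarks, voi_from_signal
from locsrr.geometry import RigidTransform, VoxelGrid, rotation_about_y
from locsrr.voi import project_point

# ground truth for the demo: three landmarks in the optical world frame
landmarks_optical = np.array([[3.0, -2.0, 5.0], [-4.0, 1.5, 2.0], [0.5, 6.0, -3.0]])
# the (unknown) optical-to-MR transform we want to recover
T_true = RigidTransform(rotation_about_y(25.0), np.array([1.0, -0.5, 2.0]))
landmarks_mr = T_true.apply(landmarks_optical)

# step 1: each landmark observed in two planar views -> 3D by back-projection
recovered = []
for p in landmarks_optical:
    obs = [(0.0, project_point(p, 0.0)), (90.0, project_point(p, 90.0))]
    recovered.append(backproject_landmark(obs))
recovered = np.array(recovered)
print("back-projection error (mm):",
      float(np.abs(recovered - landmarks_optical).max()))

# step 2: rigid fit pairs the back-projected points with their MR positions
T_fit = fit_rigid_landmarks(recovered, landmarks_mr)
print("rotation error:", float(np.abs(T_fit.rotation - T_true.rotation).max()))
print("translation error (mm):",
      float(np.abs(T_fit.translation - T_true.translation).max()))

# step 3: threshold a synthetic optical-signal volume into VOIs
grid = VoxelGrid.centered((32, 32, 32), 0.5)
signal = np.zeros((32, 32, 32))
signal[8:12, 14:18, 20:24] = 10.0  # one bright focus
vois = voi_from_signal(signal, grid, threshold=5.0, margin_mm=1.0)
print(f"{len(vois)} VOI(s) found; first box: "
      f"{np.round(vois[0].min_mm, 2)} to {np.round(vois[0].max_mm, 2)} mm")
# these VOIs, mapped through the fitted transform, select the region each
# rotated stack contributes to a local reconstruction
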