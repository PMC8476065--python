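"""Simulate a ground-truthed BOLD phantom and verify ΔS/S self-consistency."""

import numpy as np

from olfbold import default_config, default_paradigm, delta_s_over_s, simulate_dataset

schedule = default_paradigm()
cfg = default_config()          # 40x40x24 voxels at 1.5 mm, 8 ROIs, tSNR 60
bold, truth = simulate_dataset(schedule, cfg, condition="t2prep_like", seed=42)

print(f"phantom: {bold.shape} voxels, TR {bold.tr_seconds:g} s")
print(f"positive voxels: {int(truth.pos_mask.sum())}, "
      f"negative voxels: {int(truth.neg_mask.sum())}")

# The bulb-like ROI has a true block-1 ΔS/S of 2.2% that habituates to
# 0.77% and 0.33%; with noise the voxelwise estimate scatters around that.
bulb = cfg.roi_layout[0].voxels(cfg.grid_shape)
voxel = tuple(np.argwhere(bulb)[7])
measured = [delta_s_over_s(bold.data[voxel], schedule, block=b) for b in (1, 2, 3)]
print("bulb voxel ΔS/S  (measured):", np.round(measured, 2), "%")
print("bulb voxel ΔS/S  (truth)   :", np.round(truth.true_delta[voxel], 2), "%")
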