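"""Full single-scan analysis: preprocess, KS activation map, ROI summary."""

from olfbold import (
    PreprocConfig,
    RoiSet,
    block_response,
    default_config,
    default_paradigm,
    ks_activation_map,
    preprocess_bold,
    roi_label_map,
    simulate_dataset,
)
from olfbold.metrics import roi_summarize

schedule = default_paradigm()
cfg = default_config()
bold, truth = simulate_dataset(schedule, cfg, seed=7)

# Testing path: smooth 4 mm, high-pass 1/180 Hz, regress the recorded
# respiratory trace.  The 0.03 Hz low-pass is reserved for time-course
# plots — it would wreck the temporal dof the KS test relies on.
pp = PreprocConfig(nuisance_traces=truth.nuisance_traces)
clean = preprocess_bold(bold, pp, lowpass=False)

amap = ks_activation_map(clean, schedule, alpha=0.01)
resp = block_response(clean, schedule)
print("voxel counts:", amap.counts())

labels, names = roi_label_map(cfg)
table = roi_summarize(amap.sign, resp.delta_pct, resp.tsnr, resp.cnr,
                      RoiSet(labels, names), sign="positive")
cols = ["roi", "n_active", "delta_pct_block1", "delta_pct_block2",
        "delta_pct_block3", "tsnr", "cnr"]
print(table[cols].round(2).to_string(index=False))
# n_active counts voxels with adjusted P < 0.01 and positive pooled ΔS/S;
# the block columns show the habituation cascade the phantom was given.
# Note the amplitudes are smaller than the generating values (bulb 2.2%)
# and tSNR is far above the thermal level (60): 4 mm smoothing dilutes
# small-ROI amplitudes and suppresses voxel noise — both maps describe the
# smoothed data, exactly as in a standard fMRI pipeline.
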