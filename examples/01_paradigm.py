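"""Build the pulsed olfactory block paradigm and inspect its structure."""

from olfbold import build_paradigm

# 60 s odorless baseline, then 3 x (60 s pulsed odorant + 120 s odorless),
# sampled every 2 s; each on block delivers 1 s odor / 2 s carrier pulses.
schedule = build_paradigm(
    tr_seconds=2.0, initial_off_seconds=60.0, n_blocks=3,
    on_seconds=60.0, off_seconds=120.0,
    pulse_on_seconds=1.0, pulse_off_seconds=2.0,
)

print(f"total duration : {schedule.total_seconds:.0f} s "
      f"({schedule.n_volumes} volumes at TR {schedule.tr_seconds:g} s)")
print(f"odor pulses    : {schedule.pulses_per_block} per on block")
print(f"ON volumes     : {int(schedule.is_on.sum())}  "
      f"OFF volumes: {int((~schedule.is_on).sum())}")
base = schedule.baseline_volume_mask(2)
t = schedule.times
print(f"block-2 ΔS/S baseline window: {t[base].min():.0f}-{t[base].max():.0f} s "
      "(second half of the preceding off period)")
# The baseline skips the first half of each off period because the BOLD
# signal needs up to a full on-duration to return to baseline after odor.
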