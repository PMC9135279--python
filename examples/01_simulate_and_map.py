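"""Simulate a propagating beat and map its spatial properties.

Generates a radial activation wave from electrode F7 at 300 um/ms on a
120-electrode array, detects beats, and prints the per-beat property maps'
headline numbers. The time-lag minimum is 0 by construction (the pacemaker
electrode), and the median conduction velocity should recover the simulated
wave speed.
"""

import numpy as np

import cardiomea as cm

cfg = cm.build_config("mcs_120")
spec = cm.radial_spec(cfg, cfg.coords["F7"], speed=300.0, bpm=40.0, n_beats=6,
                      noise_sigma=15.0, seed=42)
rec, truth = cm.generate_recording(spec)

res = cm.analyze_recording(
    rec, cm.BeatDetectParams(filter=cm.FilterSpec("lowpass", 100.0)), with_fpd=False
)
maps = res.maps

print(f"beats detected:        {res.beat_table.n_beats}")
print(f"electrodes included:   {len(res.beat_table.included)} / {cfg.n_electrodes}")
print(f"beat rate:             {res.beat_rate_bpm:.2f} bpm (simulated: 40.00)")
print(f"max time lag:          {maps.time_lag.to_numpy().max():.2f} ms")
print(f"median CV:             {np.nanmedian(maps.cv.to_numpy()):.1f} um/ms "
      f"(simulated: {spec.speed:.0f})")
print(f"median dV/dt_max:      {np.nanmedian(maps.dvdt_max.to_numpy()):.1f} uV/ms")
print(f"median amplitude:      {np.nanmedian(maps.amplitude.to_numpy()):.0f} uV")
print()
print("The time-lag map is normalized per beat: its minimum (the pacemaker")
print("electrode) is exactly 0 ms, and lag grows with distance from F7 at 1/speed.")
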