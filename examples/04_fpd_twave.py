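"""Field potential duration via the trapezoid T-wave-endpoint method.

The synthetic template has an exactly known T-wave endpoint (computed on a
fine reference grid). Running the estimator through the sampled, noisy
recording recovers the FPD to a few milliseconds.
"""

import numpy as np

import cardiomea as cm
from cardiomea.fpd import fpd_map

cfg = cm.build_config("mcs_120")
spec = cm.radial_spec(cfg, cfg.coords["F7"], speed=300.0, bpm=40.0, n_beats=6,
                      noise_sigma=15.0, seed=5)
rec, truth = cm.generate_recording(spec)
table = cm.find_beats(rec, cm.BeatDetectParams(filter=cm.FilterSpec("lowpass", 100.0)))

f = fpd_map(rec, table)
vals = f.to_numpy()
print(f"true FPD (template):   {truth.fpd:.1f} ms")
print(f"estimated FPD (mean):  {np.nanmean(vals):.1f} ms over "
      f"{np.isfinite(vals).sum()} electrode-beats")
print(f"estimated FPD (SD):    {np.nanstd(vals):.2f} ms")
print()
print("FPD = time from the R-wave-like peak to the T-wave endpoint, the")
print("field-potential analogue of the QT interval. The endpoint maximizes")
print("the trapezoid area anchored at the T-wave's steepest descent.")
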