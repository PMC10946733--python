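"""From raw forces/torques to per-trial touch behaviour.

Block-averages the 1000-Hz channels to 20 Hz, recovers the contact point
from the moments (centre of pressure), detects movement onset from velocity
peaks, and applies the trial-rejection rules.
"""

import numpy as np
import pandas as pd

from touchersp import StudyConfig, simulate_touch_trial
from touchersp.kinetics import (
    block_average,
    compute_kinetics,
    detect_movement_onset,
    qc_and_summarise,
)

cfg = StudyConfig(fs_sensor=500.0, seed=0)
rng = np.random.default_rng(0)
seg, truth = simulate_touch_trial(cfg, "hessian", rng)

cols = {c: block_average(seg[c].to_numpy(), cfg.fs_sensor, 20.0) for c in seg.columns}
trace = compute_kinetics(pd.DataFrame(cols), 20.0,
                         plate_thickness_mm=cfg.plate_thickness_mm)
onset = detect_movement_onset(trace, 0.0)

ev = pd.Series({"trial": 0, "cue_time_ms": 0.0, "texture": "hessian",
                "condition": "sensory"})
trial = qc_and_summarise([(trace, ev)])[0]

print(f"true onset   : {truth.onset_ms:7.1f} ms after the cue")
print(f"detected     : {onset:7.1f} ms  (velocity-peak detector, 20-Hz data)")
print(f"median speed : {trial.median_speed:7.1f} mm/s  (true {truth.median_speed:.1f})")
print(f"median load  : {trial.median_load:7.1f} g     (true {truth.median_load:.1f})")
print(f"median frict.: {trial.median_friction:7.3f} N   (true {truth.median_friction:.3f})")
print(f"accepted     : {trial.accepted}")
print()
print("The detected onset sits within one 50-ms block of the true latency and")
print("the medians match the generator's analytic values up to sensor noise;")
print("friction / (load in N) recovers the texture's friction coefficient.")
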