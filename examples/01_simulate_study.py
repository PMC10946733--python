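"""Simulate a small active-touch study and look at its ground truth.

The generator produces six-axis force/torque trials (friction = mu * load,
centre of pressure at the contact point), EEG with injected alpha-band ERD
on contralateral sensorimotor channels, trial-level VAS ratings, and a
ground-truth table that downstream tests compare against.
"""

from touchersp import StudyConfig, simulate_study

cfg = StudyConfig(n_subjects=2, trials_per_cell=4, fs_sensor=200.0,
                  fs_eeg=256.0, n_channels=16, seed=0)
study = simulate_study(cfg)

truth = study.truth_frame()
print(truth[["subject", "trial", "texture", "condition", "onset_ms",
             "median_friction", "median_load"]].head(8).to_string(index=False))
print()
per_tex = truth.groupby("texture")[["median_friction", "median_load"]].mean()
print(per_tex)
print()
print("Friction tracks load times the texture's friction coefficient, so the")
print("rough texture (hessian, mu=0.55) shows higher mean friction than silk")
print("(mu=0.35) at similar loads; onset latencies sit within 400 ms of the cue.")
print()
print("channel groups:", {k: len(v) for k, v in study.groups.items()})
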