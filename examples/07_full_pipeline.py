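"""The complete chain on a desk-scale synthetic study.

Simulation -> touch kinetics and QC -> behavioural statistics and covariate
screen -> EEG preprocessing -> Morlet ERSP -> scalp-time images -> GLM ->
cluster inference -> extracted cluster power.  Takes a couple of minutes.
"""

from touchersp import PipelineConfig, StudyConfig, run
from touchersp.pipeline import report

cfg = PipelineConfig(
    study=StudyConfig(n_subjects=8, trials_per_cell=12, fs_sensor=200.0,
                      fs_eeg=256.0, n_channels=24, seed=1),
    bands={"alpha": (8.0, 12.0)},
    time_decim=4,
)
res = run(cfg, "scratch/example_run", effects=("texture",))

print(f"accepted trials : {int(res.touch_trials['accepted'].sum())}/{len(res.touch_trials)}")
print(f"covariate plan  : {res.covariate_plan['covariates']}")
print(res.cluster_table.to_string(index=False))
pw = res.cluster_power
for cid, g in pw.groupby("cluster"):
    h = g[g.condition == "hessian"]["mean_db"].mean()
    s = g[g.condition == "silk"]["mean_db"].mean()
    print(f"cluster {cid}: hessian {h:+.2f} dB vs silk {s:+.2f} dB")
print()
print(report("scratch/example_run"))
print("Clusters sit over the left hemisphere (negative peak_x_mm) where the")
print("alpha ERD difference was injected, and extracted power is more negative")
print("for the rough texture - the injected direction.")
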