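"""End-to-end pipeline: simulate -> analyze -> classify -> plot -> report.

Produces the full bundle for one simulated animal: session CSV logs,
tidy result tables, PNG figures (training trajectory, per-contrast
performance with the fitted curve, latency comparison) and a single
markdown report.
"""

from psychopig import SessionConfig, end_to_end_report, preset

report = end_to_end_report(
    SessionConfig(seed=11), preset("good_cs"),
    out_dir="scratch/report_demo", n_sessions=4, animal_id="pig_sim",
)
print(f"report written to {report}")
print("alongside: per_contrast.csv, sessions.csv, latency.csv, fit.json,")
print("bands.csv, and PNG figure analogues of the standard result panels.")
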