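"""Simulate one self-run experimental session of a simulated animal.

A session is a seeded schedule of 100 trials (10 contrasts x 10
repetitions, sides counterbalanced) run through the mat-gated trial
state machine.  The observer answers from its psychometric curve and
produces outcome-dependent latencies; the resulting log is the same
CSV-ready structure a real touchscreen system would produce.
"""

from psychopig import SessionConfig, preset, run_session, write_session_csv

config = SessionConfig(seed=11)          # experimental phase, 100 trials
observer = preset("good_cs")             # threshold at 30% contrast

log = run_session(config, observer, animal_id="pig_sim")
print(f"session of {len(log.trials)} trials, {log.n_rewards} pellets dispensed")
print("first five trials (contrast, target, chosen, correct, latency s):")
for t in log.trials[:5]:
    print(f"  {t.contrast:4.1f}  side {t.target_side} -> {t.chosen_side}  "
          f"{str(t.correct):5s}  {t.latency_s:6.2f}")

path = write_session_csv(log, "scratch/session_demo.csv")
print(f"\nlog written to {path} in the trial CSV dialect;")
print("rewards always equal correct trials — the pellet contingency is exact.")
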