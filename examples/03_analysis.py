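"""Analyze four sessions: per-contrast performance, bias, latency.

Pools non-aborted trials per contrast level across sessions, tests each
level against the 50:50 chance expectation with an exact two-sided
binomial test, quantifies side bias, and compares correct vs incorrect
response latencies with a Mann-Whitney U test.
"""

from psychopig import (
    SessionConfig,
    latency_summary,
    per_contrast_performance,
    preset,
    run_sessions,
    side_bias,
    training_success,
)

logs = run_sessions(SessionConfig(seed=11), preset("good_cs"), 4)

print("contrast   n   correct   %correct   p vs chance")
for p in per_contrast_performance(logs):
    star = " *" if p.p_value_vs_chance < 0.05 else ""
    print(f"  {p.contrast:4.1f}    {p.n:3d}    {p.k:3d}     {p.percent_correct:5.1f}"
          f"     {p.p_value_vs_chance:8.2g}{star}")

pct1, biased = side_bias(logs)
print(f"\ntouches on side 1: {pct1:.1f}%  (significant bias: {biased})")

lat = latency_summary(logs)
print(f"mean latency correct {lat.mean_latency_correct_s:.1f} s, "
      f"incorrect {lat.mean_latency_incorrect_s:.1f} s "
      f"(ratio {lat.ratio_incorrect_over_correct:.1f}, "
      f"Mann-Whitney p = {lat.test_p_value:.2g})")
print(f"training criterion (>75% correct at 100% contrast): "
      f"{training_success(logs)}")
print("\nAn asterisk marks contrasts where performance differs from chance;")
print("a well-trained animal is significant at high contrast and slower when wrong.")
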