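"""Grade per-contrast points with the six-area CS-function bands.

Each (contrast, percent-correct) point falls in exactly one area:
A1/A2 (>= 75% correct at low/high contrast) indicate good-to-moderate
contrast sensitivity, A3/A4 (50-75%) weak CS with intact training, and
A5/A6 (below chance) weak or broken training.  Two simulated animals —
one with a 30%-contrast threshold, one responding at random — land in
different bands.
"""

from psychopig import (
    SessionConfig,
    band_summary,
    classify_point,
    per_contrast_performance,
    preset,
    run_sessions,
)

for name in ("good_cs", "random"):
    logs = run_sessions(SessionConfig(seed=21), preset(name), 4)
    points = [(p.contrast, p.percent_correct)
              for p in per_contrast_performance(logs)]
    labels = [classify_point(c, pc).label for c, pc in points]
    bands = band_summary(points)["bands"]
    print(f"{name}: areas {labels}")
    print(f"  bands: good/moderate={bands['good_moderate']} "
          f"weak_cs={bands['weak_cs']} weak_training={bands['weak_training']}\n")

print("A majority of points in A1+A2 indicates measurable CS function;")
print("the random observer scatters around chance into A3-A6.")
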