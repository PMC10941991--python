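# psychopig

Touchscreen contrast-sensitivity psychophysics for large animal models.

Contrast sensitivity (CS) — the ability to discern a patterned target
from its background — degrades early in many retinal diseases, often
before visual acuity does, which makes it a valuable functional readout
in the large preclinical models (minipigs in particular) used to test
ocular therapies. `psychopig` implements the complete computational side
of an operant two-alternative forced-choice (2AFC) CS task on a
two-panel touchscreen: an animal faces a striped target on one panel and
a luminance-matched uniform gray on the other, touches a panel with its
snout, and earns a food pellet for touching the target. The package
provides

- **stimuli** — calibrated square-wave gratings at 10%–100% Michelson
  contrast plus the matched gray control, written as 8-bit PNGs;
- **trial engine** — the self-run protocol as a seeded state machine
  (weight-mat arming, touch validation, reward contingency, 50–100-trial
  sessions) with a defined CSV log dialect;
- **observer** — a parametric simulated animal (psychometric curve,
  side bias, outcome-dependent latencies, fatigue, session-over-session
  learning) so the whole pipeline is testable without animal data;
- **analysis** — per-contrast performance with exact binomial tests
  against chance, side-bias quantification, bias–accuracy Spearman
  correlation, latency comparisons, the >75 %-correct training
  criterion, and maximum-likelihood psychometric fitting;
- **classification** — the six-area (A1–A6) grading of the
  (contrast, % correct) plane into good/moderate CS, weak CS, and
  weak-training bands.

## Model

The probability of a correct choice at contrast $c \in [0,1]$ is

$$p(c) = (1-b)\,\bigl[\gamma + (1-\gamma-\lambda)\,F(c;\alpha,\beta)\bigr] + \tfrac{b}{2},
\qquad F(c;\alpha,\beta) = \frac{1}{1+e^{-\beta (c-\alpha)}}$$

with guess rate $\gamma = 0.5$ fixed by the two-choice design, lapse
rate $\lambda \le 0.1$, threshold $\alpha$ and slope $\beta$ of the
logistic detection curve, and a side-bias mixture weight $b$: with
probability $b$ the animal touches its preferred panel regardless of
the stimulus, which is correct half the time under counterbalanced
target sides. Fitting maximizes the binomial likelihood of the pooled
per-contrast counts; the reported threshold is the contrast at 75 %
correct — 50 % recognition once guessing is corrected for — since a
two-choice curve never falls to the literal 50 % line.

## Worked example

Four simulated 100-trial sessions of a well-trained observer with a 30 %
contrast threshold (`examples/03_analysis.py`, `examples/04_psychometric_fit.py`):

```
contrast   n   correct   %correct   p vs chance
   0.1     40     19      47.5         0.87
   0.4     40     39      97.5      7.5e-11 *
   1.0     40     40     100.0      1.8e-12 *

touches on side 1: 50.2%  (significant bias: False)
mean latency correct 9.6 s, incorrect 30.2 s (ratio 3.1, Mann-Whitney p = 1.6e-27)
training criterion (>75% correct at 100% contrast): True

fitted alpha = 0.327  (generating value 0.3)
threshold, guessing-corrected (75% correct): 32.8% contrast
```

Performance sits at chance below threshold (47.5 % at 10 % contrast,
p = 0.87), saturates above it, and each contrast level is tested
against a fair-coin null with an exact binomial test (asterisks mark
p < 0.05 over 40 presentations). The animal shows no panel preference,
takes about three times longer when it answers wrong, and the fitted
psychometric threshold recovers the observer's generating value to a
few percent contrast. The other scripts in `examples/` cover stimulus
rendering, single-session simulation, the A1–A6 classification, and the
end-to-end markdown report; the same capabilities are reachable from
the shell via `psychopig stimgen|simulate|analyze|classify|report|fixtures`.

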