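"""Fit the psychometric function and estimate the contrast threshold.

Maximum-likelihood fit of p(c) = 0.5 + (0.5 - lambda) * F(c; alpha, beta)
to the pooled per-contrast counts.  The headline threshold is the
contrast at 75% correct — the stimulus recognized on half of the
non-guess trials once two-choice guessing is accounted for; the literal
50%-correct crossing coincides with chance and is reported as undefined.
"""

from psychopig import (
    SessionConfig,
    fit_psychometric,
    per_contrast_performance,
    preset,
    run_sessions,
)

observer = preset("good_cs")             # generating threshold alpha = 0.30
logs = run_sessions(SessionConfig(seed=11), observer, 4)
fit = fit_psychometric(per_contrast_performance(logs))

print(f"fitted alpha = {fit.alpha_hat:.3f}  (generating value {observer.alpha})")
print(f"fitted beta  = {fit.beta_hat:.1f}   lapse = {fit.lambda_hat:.3f}")
print(f"converged: {fit.converged}")
print(f"threshold, guessing-corrected (75% correct): "
      f"{fit.threshold_corrected * 100:.1f}% contrast")
print(f"threshold, literal 50%-correct crossing: {fit.threshold_raw}")
print(f"note: {fit.note}")
print("\nThe corrected threshold estimates the observer's alpha; the literal")
print("50% crossing is undefined because a two-choice curve never falls to chance.")
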