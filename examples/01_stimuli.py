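"""Render the 10-level contrast series and its luminance-matched control.

The task shows a striped target against a uniform gray of the same mean
luminance; this script renders the standard 10%..100% Michelson-contrast
series and verifies the calibration that makes the discrimination fair:
equal means, and achieved contrast within the 8-bit quantization bound.
"""

from pathlib import Path

from psychopig import make_control_image, make_stripe_image, standard_contrast_set
from psychopig.stimuli import write_stimulus_set

specs = standard_contrast_set()
control = make_control_image(specs[0].mean_luminance)

print(f"control: uniform gray level {control.pixels[0, 0]}")
print("contrast  stripe levels  achieved  |mean - control mean|")
for spec in specs:
    img = make_stripe_image(spec)
    lo, hi = spec.stripe_levels
    print(f"  {spec.contrast:4.1f}     ({lo:3d}, {hi:3d})    "
          f"{img.achieved_contrast():.4f}   {abs(img.pixels.mean() - control.pixels.mean()):.3f}")

out = Path("scratch/stimuli")
paths = write_stimulus_set(out)
print(f"\nwrote {len(paths)} PNGs to {out}/ (stripe_c010.png ... control.png)")
print("Each row above is one target image: levels are mean*(1 +/- contrast),")
print("so a 0.4-contrast target at mean 127.5 uses gray levels 77 and 179.")
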