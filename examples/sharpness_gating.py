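"""Edge sharpness across blur and enhancement settings.

Renders synthetic metacarpal-like edge images at several acquisition
blurs and post-processing gains, scores each with the contrast-invariant
sharpness statistic, and shows which quality gate would fire.  Film-like
images score around 5-6.5; the accepted window is (4, 13].
"""

from bonegate import ValidationConfig, image_sharpness, simulate_edge_image

config = ValidationConfig()
settings = [
    ("film-like (blur 0.6 mm)", dict(blur_sigma_mm=0.6)),
    ("mild blur 1.0 mm", dict(blur_sigma_mm=1.0)),
    ("heavy blur 2.0 mm", dict(blur_sigma_mm=2.0)),
    ("enhanced, gain 3", dict(blur_sigma_mm=0.6, enhance_gain=3.0)),
    ("enhanced, gain 5", dict(blur_sigma_mm=0.6, enhance_gain=5.0)),
    ("contrast x3 +50", dict(blur_sigma_mm=0.6, contrast_a=3.0, contrast_b=50.0)),
]

print(f"{'image':<28}{'sharpness':>10}   gate")
for label, kwargs in settings:
    img, rois = simulate_edge_image(seed=1, **kwargs)
    value = image_sharpness(img, rois).value
    if value > config.sharp_max:
        gate = "too sharp (rejected)"
    elif value < config.sharp_min:
        gate = "too blurred (rejected)"
    else:
        gate = "accepted"
    print(f"{label:<28}{value:>10.2f}   {gate}")

print("\nThe contrast-mapped image scores identically to the film-like one:")
print("the statistic depends only on edge geometry, not brightness/contrast.")
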