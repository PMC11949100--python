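"""Full assessment of one mask: invasion metrics and clinical grade."""

from pterygrade import PhantomSpec, assess_image, generate_phantom

# a lesion 30% of the way across the cornea, clear of the pupil
spec = PhantomSpec(invasion_distance_px=200.0 * (1 - 2 * 0.30),
                   pupil_radius_px=40.0)
mask, truth = generate_phantom(spec)

result = assess_image(mask)
m = result.metrics
print(f"invaded area fraction (cornea) alpha = {m.alpha_cornea:.4f}")
print(f"depth ratio beta                     = {m.beta:.4f} "
      f"(analytic truth {truth.beta_true:.4f})")
print(f"physical depth = beta x {m.reference_diameter_mm} mm reference "
      f"= {m.depth_mm:.2f} mm")
print(f"pupil covered: {m.pupil_covered}")
print(f"grade {result.grade}  ({result.rule_fired})")
# Depth above 3 mm without pupil involvement -> grade 2: surgical
# planning territory, but the optical axis is still clear.
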