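"""Measure a phantom with the analytic oracle classifier.

The scale search rescales the slice to 16 magnifications, asks the
classifier "is the lesion larger than 32 px in this 128x128 frame?" at
each rung, and converts the probability flip point into centimeters:
size = (32 / flip_magnification) x pixel spacing. With the hard oracle
standing in for the network, the answer is limited only by the ladder
resolution and bisection tolerance.
"""

from lesionmeter.ctio import CTSlice
from lesionmeter.phantom import PhantomSpec, ShapeFamily, synthesize_lesion
from lesionmeter.scalesearch import measure_lesion
from lesionmeter.sizeclassifier import oracle_classifier, phantom_size_lookup

spec = PhantomSpec(
    shape_family=ShapeFamily.SPICULATED,
    true_diameter_cm=3.7,
    spiculation_count=9,
    spiculation_length_frac=0.2,
    pixel_spacing_cm=0.08,
    rng_seed=4,
)
case = synthesize_lesion(spec)
ct = CTSlice(pixels=case.image.astype(float), spacing_cm=(case.spacing_cm, case.spacing_cm))
clf = oracle_classifier(phantom_size_lookup(case.true_diameter_cm, case.spacing_cm))

result = measure_lesion(ct, case.seed_point, clf)

print(f"true diameter      : {case.true_diameter_cm:.4f} cm")
print(f"measured diameter  : {result.size_cm:.4f} cm")
print(f"flip magnification : {result.flip_magnification:.4f}")
print(f"classifier calls   : {result.n_classifier_calls} (16 rungs + refinement)")
print("rung responses     :", " ".join(f"{p:.0f}" for p in result.rung_probs))
err = 100 * abs(result.size_cm - case.true_diameter_cm) / case.true_diameter_cm
print(f"relative error     : {err:.2f}%  (ladder+refinement resolution)")
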