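"""The bundled ssPERG+OCT RGC estimators and their loss accounting.

Prints the two reference models (one per pattern-ERG amplitude parameter),
predicts the healthy-group mean count, and recomputes the percent-loss and
annual age-related loss-rate accounting from the stored reference group
means.
"""

from rgcest import DEFAULT_PROFILES, annual_loss_rate, builtin_models, proportional_loss
from rgcest.linear_models import REPORTED_MODEL_GROUP_MEANS

mag, magd = builtin_models()
print(mag.formula())
print(magd.formula())
print()

p = DEFAULT_PROFILES["healthy"]
pred = float(mag.predict(p.mean("age_years"), p.mean("arnflt_um"), p.mean("mag_uv")))
print(f"Mag-model prediction at healthy-group means: {pred:,.0f} RGCs")
print()

print("percent loss relative to healthy eyes (GS = glaucoma suspect,")
print("PPG = preperimetric glaucoma):")
for label, col in (("ARNFLT", "arnflt_um"), ("Mag", "mag_uv"), ("MagD", "magd_uv")):
    ref = DEFAULT_PROFILES["healthy"].mean(col)
    gs = proportional_loss(ref, DEFAULT_PROFILES["GS"].mean(col))
    ppg = proportional_loss(ref, DEFAULT_PROFILES["PPG"].mean(col))
    print(f"  {label:8s} GS {gs:3.0f}%   PPG {ppg:3.0f}%")
for perg, model in (("Mag", mag), ("MagD", magd)):
    means = REPORTED_MODEL_GROUP_MEANS[perg]
    gs = proportional_loss(means["healthy"], means["GS"])
    ppg = proportional_loss(means["healthy"], means["PPG"])
    rate = annual_loss_rate(model, means["healthy"])
    print(f"  eRGC_{perg:5s} GS {gs:3.0f}%   PPG {ppg:3.0f}%   ({rate:.2f}%/year with age)")
print()
print("PERG amplitude losses in suspects (31-37%) far exceed structural and")
print("count losses (12-13%): RGC dysfunction precedes cell death.")
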