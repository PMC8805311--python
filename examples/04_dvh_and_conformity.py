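"""DVH parameters, ICRU 83 coverage and the Paddick conformity index.

A surrogate conformal dose (74 Gy prescription) is generated around the
PTV (prostate + 6 mm margin, 5 mm posterior). D98/D2 are the doses to the
hottest 98%/2% of the structure; V95% the volume fraction receiving at
least 95% of the prescription; rectum and bladder VX Gy the volume
percentages above X Gy. The Paddick CI compares the 95% isodose volume to
the PTV (1 = perfectly conformal).
"""

from rtsegeval import (
    DoseSurrogateSpec,
    MarginSpec,
    PhantomSpec,
    cumulative_dvh,
    dvh_D,
    dvh_V,
    expand_margin,
    generate_phantom,
    generate_surrogate_dose,
    icru83_check,
    paddick_ci,
)

_, gt = generate_phantom(PhantomSpec(), seed=1)
ptv = expand_margin(gt["prostate"], MarginSpec())
dose = generate_surrogate_dose(ptv, DoseSurrogateSpec(), seed=2)

curve = cumulative_dvh(dose, gt["prostate"])
print(f"prostate D98 = {dvh_D(curve, 98):.2f} Gy, D2 = {dvh_D(curve, 2):.2f} Gy, "
      f"V95% = {dvh_V(curve, 95, percent_of=74.0):.1f}%")

ptv_curve = cumulative_dvh(dose, ptv)
res = icru83_check(ptv_curve, 74.0)
print(f"ICRU 83 PTV check: D98 {res.d98_gy:.2f} Gy (>= 70.30: {res.d98_ok}), "
      f"D2 {res.d2_gy:.2f} Gy (<= 79.18: {res.d2_ok})")

for name, thresholds in (("rectum", (50.0, 65.0, 70.0)), ("bladder", (60.0, 65.0, 70.0))):
    c = cumulative_dvh(dose, gt[name])
    vals = ", ".join(f"V{t:g}Gy = {dvh_V(c, t):.2f}%" for t in thresholds)
    print(f"{name}: {vals}")

print(f"Paddick CI (95% isodose vs PTV) = {paddick_ci(ptv, dose, 74.0, 95.0):.3f}")
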