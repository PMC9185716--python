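"""Sample size needed to validate a screener's sensitivity.

n_cases = Z^2 p(1-p) / d^2 condition-positive cases are needed to estimate a
sensitivity p to within margin d; dividing by the anticipated prevalence
gives the total sample.  The study's design inputs (p = 0.85, d = 0.10,
prevalence 40.9%) give 49 cases and a 119-person total.
"""

import marsha_screen as ms

spec = ms.SampleSizeSpec(p_hat=0.85, d=0.10, prevalence=0.409)
print(f"Z = {spec.z:.4f} at alpha = {spec.alpha}")
print(f"cases required:  {ms.required_cases(spec)}")
print(f"total required:  {ms.required_total(spec)} "
      f"(ceil mode: {ms.required_total(spec, rounding='ceil')})")

# tighter margin -> many more cases
tight = ms.SampleSizeSpec(p_hat=0.85, d=0.05, prevalence=0.409)
print(f"\nhalving the margin to 0.05 raises the requirement to "
      f"{ms.required_cases(tight)} cases / {ms.required_total(tight)} total")
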