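"""Harmonize raw survey answers with a variable codebook.

Cohort questionnaires deliver labels ("no", "occasionally", "yes") plus
refusal codes.  The codebook fixes a monotone ordinal recoding per variable
(higher value = more of the phenotype), maps refusals to missing, and
binarizes the two social-isolation targets.
"""

import isorisk
from isorisk import binarize_target, recode_variable, zscore

cb = isorisk.demo_codebook()

smoking = ["no", "occasionally", "yes", "Prefer not to answer", "yes"]
codes = recode_variable(smoking, cb["current_tobacco_smoking"])
print(f"raw answers    {smoking}")
print(f"ordinal codes  {codes}  (refusal -> NaN, order preserved)")

confide = ["daily or almost daily", "weekly", "never", "weekly"]
y = binarize_target(confide, cb["confide_frequency"])
print(f"\nconfide answers {confide}")
print(f"lack-of-support target {y}  (1 = confides less than daily)")

z = zscore([5.5, 7.0, 8.0, 6.5, 7.5])
print(f"\nz-scored sleep hours: {z.round(3)}")
print("mean 0, sample SD 1: coefficients downstream are per 1 SD of the trait")
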