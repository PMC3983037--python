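"""SE of a genetic correlation: same-sample vs different-samples designs.

Measuring both traits on one sample of N individuals is far more precise
than two disjoint samples of the same total size: for independent traits the
variance ratio is N1*N2/N^2.
"""

import math

from gremlpower import (
    BivariateDesign,
    ratio_same_vs_diff,
    var_rg_cc_cc,
    var_rg_diff_samples,
    var_rg_same_sample,
)

# two psychiatric case-control studies on disjoint samples (SCZ vs BPD scale)
se = math.sqrt(var_rg_cc_cc(17012, 11922, 0.68, h2_obs_1=0.40, h2_obs_2=0.39))
print(f"SCZ-BPD-like pair: SE(rG) = {se:.4f} (~{se:.3f})")

# same sample vs different samples at rG = 0
same = BivariateDesign(mode="same_sample", n1=4000, h2_1=0.5, h2_2=0.5, rg=0.0, rp=0.0)
diff = BivariateDesign(mode="different_samples", n1=2000, n2=2000, h2_1=0.5, h2_2=0.5, rg=0.0)
print(f"same sample N=4000      : SE = {math.sqrt(var_rg_same_sample(same)):.4f}")
print(f"disjoint 2000+2000      : SE = {math.sqrt(var_rg_diff_samples(diff)):.4f}")
print(f"variance ratio (theory) : {ratio_same_vs_diff(4000, 2000, 2000):.3f}")
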