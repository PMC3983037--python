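"""Case-control design: observed- vs liability-scale SE and the effect of ascertainment.

A disease analysed as a 0/1 trait obeys the same SE formula as a quantitative
trait; the liability-scale SE is that value times the linear transform factor
c(K, v).  Because c < 1 for a rare, heavily ascertained disease, sampling
half cases/half controls of a 1%-prevalence disease yields a SMALLER
liability-scale SE (more power) than an unascertained design of the same size.
"""

import math

from gremlpower import CaseControlDesign, make_liability_model, power_for_design, se_h2_cc_liab, var_h2_cc_obs

# the multiple sclerosis study: 1604 cases, 1953 controls, K = 0.001
d = CaseControlDesign(n_cases=1604, n_controls=1953, prevalence=0.001)
print(f"N={d.n}, v={d.v:.3f}, c(K,v)={d.liability.c:.4f}")
print(f"SE observed scale : {math.sqrt(var_h2_cc_obs(d)):.4f}")
print(f"SE liability scale: {se_h2_cc_liab(d):.4f}")

# the transform factor across prevalences at balanced sampling
print("\nc(K, v=0.5) by prevalence (pi/2 at K=0.5):")
for K in (0.001, 0.01, 0.1, 0.5):
    print(f"  K={K}: c = {make_liability_model(K, 0.5).c:.4f}")

# power for a schizophrenia-like design targeting liability h2 = 0.23
scz = CaseControlDesign(n_cases=9087, n_controls=12171, prevalence=0.01, h2_liab=0.23)
res = power_for_design(scz)
print(f"\nSCZ-like design: SE(h2_liab)={res.se:.4f}, power={res.power:.4f}")
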