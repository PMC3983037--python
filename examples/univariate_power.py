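"""Plan a univariate SNP-heritability study: SE, power and minimum sample size.

The SE of the SNP-heritability estimate in unrelated samples depends only on
the sample size and the variance of SNP-derived relatedness (~2e-5 genome
wide), not on the heritability itself — so precision can be planned before
any phenotype is collected.
"""

import math

from gremlpower import UnivariateDesign, min_n_for_power, power_for_design, var_h2_qt

# the two classic height/BMI cohorts: SE is set by N alone
for n in (3925, 11586):
    se = math.sqrt(var_h2_qt(UnivariateDesign(n=n)))
    print(f"N={n:6d}: SE(h2_hat) = {se:.4f}  (~{se:.3f})")

# power to detect h2 = 0.2 with 4430 individuals (the 80% crossing point)
res = power_for_design(UnivariateDesign(n=4430, h2=0.2))
print(f"\nN=4430, h2=0.2: SE={res.se:.4f}, NCP={res.ncp:.2f}, power={res.power:.3f}")

# minimum N for 80% power across effect sizes, rounded up to the next 100
print("\nminimum N for 80% power at alpha=0.05:")
for h2 in (0.1, 0.2, 0.3, 0.4):
    sol = min_n_for_power(UnivariateDesign(n=1000, h2=h2))
    print(f"  h2={h2}: N={sol.n} (unrounded {sol.n_exact})")
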