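# gremlpower

Design and power analysis for SNP-based estimation of genetic (co)variance in
unrelated samples.

Genome-wide SNP data lets one estimate the proportion of phenotypic variance
captured by all common SNPs (h²_SNP) and the genetic correlation (r_G)
between two traits from *unrelated* individuals, via a mixed model with a
SNP-derived genetic relationship matrix (GREML) or the asymptotically
equivalent Haseman–Elston pairwise regression. Before collecting data the key
question is precision: how large a sample gives a usable standard error, and
what is the power to detect a given h² or r_G? `gremlpower` implements the
closed-form answers and verifies them by simulation.

## The theory in brief

With phenotypes standardized and var_π the variance of off-diagonal
SNP-relatedness among unrelated individuals (≈ 2×10⁻⁵ for genome-wide common
SNPs in humans),

- univariate: `var(ĥ²) ≈ 2 / (N² · var_π)` — independent of h² itself;
- two traits, same N individuals (phenotypic correlation r_P):
  `var(r̂_G) ≈ [(1 − r_G r_P)² + (r_G − r_P)²] / (N² var_π h²₁ h²₂)`;
- two traits on disjoint samples N₁, N₂:
  `var(r̂_G) ≈ (1/var_π) [ 1/(h²₁h²₂N₁N₂) + r_G²/(2h²₁²N₁²) + r_G²/(2h²₂²N₂²) ]`;
- case-control studies analysed on the 0/1 observed scale obey the same
  formulas; the liability-scale SE is the observed-scale SE times
  `c(K, v) = K²(1−K)² / (z² v(1−v))` (prevalence K, case proportion v,
  z the normal density at the liability threshold);
- the Wald statistic `(θ̂/SE)²` for θ ∈ {h², r_G} is non-central χ²₁ with
  NCP λ = θ²/var(θ̂), so power grows quadratically with N.

A synthetic-data module (unrelated individuals, independent HWE SNPs,
polygenic architectures, liability-threshold ascertainment) plus a replicate
harness checks every formula against Haseman–Elston estimates on simulated
cohorts, where `1/m` plays the role var_π = 2e-5 plays for real genomes.

## Worked example

```python
import math
from gremlpower import UnivariateDesign, var_h2_qt, min_n_for_power

se = math.sqrt(var_h2_qt(UnivariateDesign(n=3925)))
print(round(se, 3))                     # 0.081 — height, 3925 unrelateds
sol = min_n_for_power(UnivariateDesign(n=1000, h2=0.2))
print(sol.n, sol.n_exact)               # 4500 4430
```

Running `python examples/univariate_power.py` prints

```
N=  3925: SE(h2_hat) = 0.0806  (~0.081)
N= 11586: SE(h2_hat) = 0.0273  (~0.027)

N=4430, h2=0.2: SE=0.0714, NCP=7.85, power=0.800

minimum N for 80% power at alpha=0.05:
  h2=0.1: N=8900 (unrounded 8860)
  h2=0.2: N=4500 (unrounded 4430)
  h2=0.3: N=3000 (unrounded 2954)
  h2=0.4: N=2300 (unrounded 2215)
```

i.e. the SE of ĥ² is set by sample size alone, ~4430 unrelated individuals
give 80% power to detect h² = 0.2, and the reported minimum sizes round up
to the next hundred. The other scripts in `examples/` cover case-control
designs (`case_control_design.py`), genetic-correlation planning
(`genetic_correlation_planning.py`) and the simulation verification
(`simulation_verification.py`).

The same calculations are available from the shell:

```bash
greml-power power-qt --n 3925 --hsq 0.5
greml-power power-cc --ncase 1604 --ncontrol 1953 --prevalence 0.001
greml-power power-rg --mode diff --n1 17012 --n2 11922 \
    --hsq1 0.40 --hsq2 0.39 --rg 0.68
greml-power min-n --design qt --hsq 0.2
greml-power tables --table cc
greml-power verify --config sim.yaml
```

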