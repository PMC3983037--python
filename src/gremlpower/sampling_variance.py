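"""Closed-form sampling variances of SNP-heritability and genetic-correlation estimates.

For nominally unrelated individuals the GREML mixed-model estimate of the
proportion of phenotypic variance captured by genome-wide SNPs is
asymptotically equivalent to a regression of pairwise phenotype products on
pairwise SNP-derived relatedness.  With standardized phenotypes the sampling
variance of that slope is

    var(h2_hat) ~= 2 / (N^2 * var_pi)

where ``var_pi`` is the variance of the off-diagonal entries of the genetic
relationship matrix (about 2e-5 for genome-wide common SNPs in humans).  The
variance is independent of the heritability itself: only the number of
pairwise contrasts, N(N-1)/2 ~ N^2/2, and the spread of relatedness matter.

The genetic correlation ``rG = cov_g / sqrt(h2_1 * h2_2)`` between two traits
has, by a second-order Taylor (delta-method) expansion:

same sample (phenotypic correlation rP required):

    var(rG_hat) ~= [(1 - rG*rP)^2 + (rG - rP)^2] / (N^2 * var_pi * h2_1 * h2_2)

different samples (residual covariance undefined, rP must not be given):

    var(rG_hat) ~= (1/var_pi) * [ 1/(h2_1*h2_2*N1*N2)
                                  + rG^2/(2*h2_1^2*N1^2)
                                  + rG^2/(2*h2_2^2*N2^2) ]

Case-control studies analysed on the 0/1 observed scale obey the same
formulas; the univariate SE converts to the liability scale linearly via the
:mod:`~gremlpower.liability` factor ``c(K, v)``, and the genetic correlation
is scale-invariant so the different-samples formula applies with
observed-scale heritabilities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Optional

from .liability import LiabilityModel, h2_liab_to_obs, make_liability_model

__all__ = [
    "VAR_PI_DEFAULT",
    "UnivariateDesign",
    "CaseControlDesign",
    "BivariateDesign",
    "var_h2_qt",
    "var_h2_cc_obs",
    "se_h2_cc_liab",
    "var_rg_same_sample",
    "var_rg_diff_samples",
    "var_rg_cc_cc",
    "var_rg_qt_cc",
    "ratio_same_vs_diff",
]

#: Theoretical variance of SNP-derived relatedness among unrelated humans,
#: genome-wide common SNPs (effective population size ~1e4).
VAR_PI_DEFAULT = 2e-5

# Below this the rG variance approximation divides by a near-zero h2 and
# becomes unreliable.
_H2_TINY = 1e-3


def _check_var_pi(var_pi: float) -> None:
    if not var_pi > 0:
        raise ValueError(f"var_pi={var_pi!r} must be positive")


def _check_h2_for_rg(h2: float, name: str) -> None:
    if h2 <= 0:
        raise ValueError(f"{name}={h2!r}: rG sampling variance is undefined at h2 <= 0")
    if h2 < _H2_TINY:
        warnings.warn(
            f"{name}={h2} is below {_H2_TINY}; the rG variance approximation is "
            "unreliable at near-zero heritability",
            stacklevel=3,
        )


@dataclass(frozen=True)
class UnivariateDesign:
    """Quantitative-trait design: ``n`` unrelated individuals.

    ``h2`` is used only for power calculations (the SE does not depend on it)
    and may be omitted for pure SE computations.
    """

    n: int
    h2: Optional[float] = None
    var_pi: float = VAR_PI_DEFAULT

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 2:
            raise ValueError(f"n={self.n!r} must be an integer >= 2")
        if self.h2 is not None and not (0.0 <= self.h2 <= 1.0):
            raise ValueError(f"h2={self.h2!r} must lie in [0, 1]")
        _check_var_pi(self.var_pi)


@dataclass(frozen=True)
class CaseControlDesign:
    """Case-control design with prevalence ``prevalence`` and optional liability h2.

    ``case_fraction`` defaults to ``n_cases / (n_cases + n_controls)``; it may
    be overridden (e.g. when planning with round numbers).
    """

    n_cases: int
    n_controls: int
    prevalence: float = 0.5
    case_fraction: Optional[float] = None
    h2_liab: Optional[float] = None
    var_pi: float = VAR_PI_DEFAULT

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls"):
            val = getattr(self, name)
            if int(val) != val or val < 1:
                raise ValueError(f"{name}={val!r} must be an integer >= 1")
        if self.case_fraction is not None and not (0.0 < self.case_fraction < 1.0):
            raise ValueError(f"case_fraction={self.case_fraction!r} must lie in (0, 1)")
        if self.h2_liab is not None and not (0.0 <= self.h2_liab <= 1.0):
            raise ValueError(f"h2_liab={self.h2_liab!r} must lie in [0, 1]")
        _check_var_pi(self.var_pi)
        # validates prevalence range as a side effect
        make_liability_model(self.prevalence, self.v)

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def v(self) -> float:
        if self.case_fraction is not None:
            return self.case_fraction
        return self.n_cases / self.n

    @property
    def liability(self) -> LiabilityModel:
        return make_liability_model(self.prevalence, self.v)

    @property
    def h2_obs(self) -> Optional[float]:
        if self.h2_liab is None:
            return None
        return h2_liab_to_obs(self.h2_liab, self.liability)


@dataclass(frozen=True)
class BivariateDesign:
    """Two-trait design for genetic-correlation SE and power.

    ``mode`` is ``"same_sample"`` (one set of N individuals measured for both
    traits; ``rp`` required for SE computation) or ``"different_samples"``
    (disjoint sets of n1 and n2 individuals; supplying ``rp`` is an error
    because the residual covariance is undefined across disjoint samples).
    Heritabilities are on the trait scale for quantitative traits and the
    observed 0/1 scale for case-control traits (rG itself is scale-invariant).
    """

    mode: Literal["same_sample", "different_samples"]
    n1: int
    h2_1: float
    h2_2: float
    rg: float
    n2: Optional[int] = None
    rp: Optional[float] = None
    var_pi: float = VAR_PI_DEFAULT

    def __post_init__(self) -> None:
        if self.mode not in ("same_sample", "different_samples"):
            raise ValueError(f"mode={self.mode!r} must be 'same_sample' or 'different_samples'")
        if int(self.n1) != self.n1 or self.n1 < 2:
            raise ValueError(f"n1={self.n1!r} must be an integer >= 2")
        if self.mode == "different_samples":
            if self.n2 is None:
                raise ValueError("different_samples mode requires n2")
            if int(self.n2) != self.n2 or self.n2 < 2:
                raise ValueError(f"n2={self.n2!r} must be an integer >= 2")
            if self.rp is not None:
                raise ValueError(
                    "rp must not be supplied in different_samples mode: the residual "
                    "covariance between disjoint samples is undefined"
                )
        else:
            if self.n2 is not None and self.n2 != self.n1:
                raise ValueError("same_sample mode uses a single sample size n1")
        for name in ("h2_1", "h2_2"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name}={val!r} must lie in [0, 1]")
        if not (-1.0 <= self.rg <= 1.0):
            raise ValueError(f"rg={self.rg!r} must lie in [-1, 1]")
        if self.rp is not None and not (-1.0 <= self.rp <= 1.0):
            raise ValueError(f"rp={self.rp!r} must lie in [-1, 1]")
        _check_var_pi(self.var_pi)

    @property
    def n(self) -> int:
        """Sample size of the (single) set in same_sample mode."""
        return self.n1


def var_h2_qt(design: UnivariateDesign) -> float:
    """Sampling variance of the SNP-heritability estimate, quantitative trait.

    ``2 / (N^2 * var_pi)`` — independent of the heritability itself.

    >>> round(math.sqrt(var_h2_qt(UnivariateDesign(n=3925))), 3)
    0.081
    """
    return 2.0 / (design.n**2 * design.var_pi)


def var_h2_cc_obs(design: CaseControlDesign) -> float:
    """Sampling variance of observed-scale SNP heritability in a case-control study.

    Identical in form to the quantitative-trait result, with
    ``N = n_cases + n_controls``: the 0/1 status is analysed as a linear
    (observed-scale) phenotype.
    """
    return 2.0 / (design.n**2 * design.var_pi)


def se_h2_cc_liab(design: CaseControlDesign) -> float:
    """SE of the liability-scale SNP-heritability estimate.

    The observed-scale SE multiplied by the linear transform factor
    ``c(K, v)`` of the liability module.
    """
    return math.sqrt(var_h2_cc_obs(design)) * design.liability.c


def var_rg_same_sample(design: BivariateDesign) -> float:
    """Sampling variance of rG when both traits are measured on the same sample.

    ``[(1 - rG*rP)^2 + (rG - rP)^2] / (N^2 * var_pi * h2_1 * h2_2)``.
    Well behaved as rG, rP -> 1 (the variance goes to 0 continuously, unlike
    the classical pedigree approximations of Reeve and Robertson).
    """
    if design.mode != "same_sample":
        raise ValueError("var_rg_same_sample requires mode='same_sample'")
    if design.rp is None:
        raise ValueError(
            "same-sample rG variance requires the phenotypic correlation rp; "
            "supply rp explicitly (it has no default)"
        )
    _check_h2_for_rg(design.h2_1, "h2_1")
    _check_h2_for_rg(design.h2_2, "h2_2")
    rg, rp = design.rg, design.rp
    num = (1.0 - rg * rp) ** 2 + (rg - rp) ** 2
    return num / (design.n**2 * design.var_pi * design.h2_1 * design.h2_2)


def var_rg_diff_samples(design: BivariateDesign) -> float:
    """Sampling variance of rG when the two traits are measured on disjoint samples.

    Delta-method composition of the sampling variances of the genetic
    covariance, ``var(c_hat) = 1/(N1*N2*var_pi)``, and of the two
    heritabilities, ``var(h2_k_hat) = 2/(Nk^2*var_pi)``:

    ``(1/var_pi) * [1/(h2_1*h2_2*N1*N2) + rG^2/(2*h2_1^2*N1^2) + rG^2/(2*h2_2^2*N2^2)]``
    """
    if design.mode != "different_samples":
        raise ValueError("var_rg_diff_samples requires mode='different_samples'")
    _check_h2_for_rg(design.h2_1, "h2_1")
    _check_h2_for_rg(design.h2_2, "h2_2")
    h1, h2, rg = design.h2_1, design.h2_2, design.rg
    n1, n2 = design.n1, design.n2
    term = (
        1.0 / (h1 * h2 * n1 * n2)
        + rg**2 / (2.0 * h1**2 * n1**2)
        + rg**2 / (2.0 * h2**2 * n2**2)
    )
    return term / design.var_pi


def _resolve_observed_h2(
    which: str,
    h2_obs: Optional[float],
    h2_liab: Optional[float],
    prevalence: Optional[float],
    case_fraction: Optional[float],
) -> float:
    if h2_obs is not None:
        if h2_liab is not None:
            raise ValueError(f"give either h2_obs or h2_liab for trait {which}, not both")
        return h2_obs
    if h2_liab is None:
        raise ValueError(f"trait {which} needs h2_obs, or h2_liab with prevalence and case_fraction")
    if prevalence is None or case_fraction is None:
        raise ValueError(
            f"liability-scale input for trait {which} requires prevalence and case_fraction"
        )
    return h2_liab_to_obs(h2_liab, make_liability_model(prevalence, case_fraction))


def var_rg_cc_cc(
    n1: int,
    n2: int,
    rg: float,
    *,
    h2_obs_1: Optional[float] = None,
    h2_obs_2: Optional[float] = None,
    h2_liab_1: Optional[float] = None,
    prevalence_1: Optional[float] = None,
    case_fraction_1: Optional[float] = None,
    h2_liab_2: Optional[float] = None,
    prevalence_2: Optional[float] = None,
    case_fraction_2: Optional[float] = None,
    var_pi: float = VAR_PI_DEFAULT,
) -> float:
    """rG sampling variance for two independent case-control studies.

    Heritabilities may be given on the observed scale directly, or on the
    liability scale together with each study's prevalence and case fraction
    (converted internally; rG itself needs no transformation because the
    observed/liability scales differ by a linear factor).
    """
    h1 = _resolve_observed_h2("1", h2_obs_1, h2_liab_1, prevalence_1, case_fraction_1)
    h2 = _resolve_observed_h2("2", h2_obs_2, h2_liab_2, prevalence_2, case_fraction_2)
    design = BivariateDesign(
        mode="different_samples", n1=n1, n2=n2, h2_1=h1, h2_2=h2, rg=rg, var_pi=var_pi
    )
    return var_rg_diff_samples(design)


def var_rg_qt_cc(
    n_qt: int,
    n_cc: int,
    rg: float,
    h2_qt: float,
    *,
    h2_obs_cc: Optional[float] = None,
    h2_liab_cc: Optional[float] = None,
    prevalence: Optional[float] = None,
    case_fraction: Optional[float] = None,
    var_pi: float = VAR_PI_DEFAULT,
) -> float:
    """rG sampling variance for a quantitative trait vs. an independent case-control study."""
    h_cc = _resolve_observed_h2("cc", h2_obs_cc, h2_liab_cc, prevalence, case_fraction)
    design = BivariateDesign(
        mode="different_samples", n1=n_qt, n2=n_cc, h2_1=h2_qt, h2_2=h_cc, rg=rg, var_pi=var_pi
    )
    return var_rg_diff_samples(design)


def ratio_same_vs_diff(n: int, n1: int, n2: int) -> float:
    """Ratio of same-sample to different-samples rG sampling variance for independent traits.

    In the rG = rP = 0 limit the two variances reduce to
    ``1/(N^2 var_pi h2_1 h2_2)`` and ``1/(N1 N2 var_pi h2_1 h2_2)``, so the
    ratio is simply ``N1*N2 / N^2``.
    """
    return (n1 * n2) / (n * n)
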