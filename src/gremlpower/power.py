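"""Non-central chi-square power and minimum sample size for (co)variance detection.

The Wald statistic ``(theta_hat / se)^2`` for theta in {h2_SNP, rG} is
asymptotically non-central chi-square with 1 degree of freedom and
non-centrality lambda = theta^2 / var(theta_hat).  Power at type-I error rate
alpha is the probability that this variable exceeds the central chi-square(1)
quantile q_{1-alpha}.  Because var(theta_hat) scales as 1/N^2, the NCP grows
quadratically with sample size.

Power of a case-control design is invariant to the scale (observed vs.
liability) on which it is expressed: theta and its SE transform by the same
linear factor, leaving lambda unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Union

import pandas as pd
from scipy.stats import chi2, ncx2

from .sampling_variance import (
    BivariateDesign,
    CaseControlDesign,
    UnivariateDesign,
    se_h2_cc_liab,
    var_h2_qt,
    var_rg_diff_samples,
    var_rg_same_sample,
)

__all__ = ["PowerResult", "MinNResult", "ncp", "power_from_ncp", "power_for_design",
           "min_n_for_power", "power_curve"]

Design = Union[UnivariateDesign, CaseControlDesign, BivariateDesign]


@dataclass(frozen=True)
class PowerResult:
    """Parameter value, its SE, the non-centrality and the resulting power."""

    theta: float
    se: float
    ncp: float
    alpha: float
    power: float


@dataclass(frozen=True)
class MinNResult:
    """Minimum-N solution.

    ``n`` is the reported (possibly rounded) size, ``n_exact`` the smallest
    integer size meeting the target before rounding.  For two-sample designs
    both refer to set 1 and ``n2``/``n2_exact`` give the companion set scaled
    by the fixed ratio.
    """

    n: int
    n_exact: int
    power_at_n: float
    target_power: float
    alpha: float
    n2: Optional[int] = None
    n2_exact: Optional[int] = None


def ncp(theta: float, var_theta: float) -> float:
    """Non-centrality parameter ``theta^2 / var(theta_hat)``."""
    if not var_theta > 0:
        raise ValueError(f"var_theta={var_theta!r} must be positive")
    return theta * theta / var_theta


def power_from_ncp(lam: float, alpha: float) -> float:
    """P[chi2_1(lam) > q_{1-alpha}] for the two-sided Wald chi-square test."""
    if lam < 0:
        raise ValueError(f"lam={lam!r} must be non-negative")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha={alpha!r} must lie in (0, 1)")
    if lam == 0.0:
        return alpha  # size of the test, exactly
    q = chi2.isf(alpha, df=1)
    return float(ncx2.sf(q, df=1, nc=lam))


def _theta_and_se(design: Design) -> tuple[float, float]:
    """Parameter of interest and its theoretical SE for any supported design."""
    if isinstance(design, UnivariateDesign):
        if design.h2 is None:
            raise ValueError("UnivariateDesign.h2 is required for power calculations")
        return design.h2, math.sqrt(var_h2_qt(design))
    if isinstance(design, CaseControlDesign):
        if design.h2_liab is None:
            raise ValueError("CaseControlDesign.h2_liab is required for power calculations")
        # liability scale; lambda is identical on the observed scale
        return design.h2_liab, se_h2_cc_liab(design)
    if isinstance(design, BivariateDesign):
        if design.mode == "same_sample":
            var = var_rg_same_sample(design)
        else:
            var = var_rg_diff_samples(design)
        return design.rg, math.sqrt(var)
    raise TypeError(f"unsupported design type {type(design).__name__}")


def power_for_design(design: Design, alpha: float = 0.05) -> PowerResult:
    """SE, non-centrality and power of the chi-square(1) Wald test for a design."""
    theta, se = _theta_and_se(design)
    lam = ncp(theta, se * se)
    return PowerResult(theta=theta, se=se, ncp=lam, alpha=alpha, power=power_from_ncp(lam, alpha))


def _rescaled(design: Design, n: int, ratio: float) -> Design:
    """Copy of ``design`` at sample size ``n`` (set 1 for two-sample designs)."""
    if isinstance(design, UnivariateDesign):
        return UnivariateDesign(n=n, h2=design.h2, var_pi=design.var_pi)
    if isinstance(design, CaseControlDesign):
        v = design.v
        n_cases = max(1, round(v * n))
        n_controls = max(1, n - n_cases)
        return CaseControlDesign(
            n_cases=n_cases,
            n_controls=n_controls,
            prevalence=design.prevalence,
            case_fraction=v,
            h2_liab=design.h2_liab,
            var_pi=design.var_pi,
        )
    if isinstance(design, BivariateDesign):
        n2 = None if design.mode == "same_sample" else max(2, math.ceil(ratio * n))
        return BivariateDesign(
            mode=design.mode,
            n1=n,
            n2=n2,
            h2_1=design.h2_1,
            h2_2=design.h2_2,
            rg=design.rg,
            rp=design.rp,
            var_pi=design.var_pi,
        )
    raise TypeError(f"unsupported design type {type(design).__name__}")


def min_n_for_power(
    design: Design,
    target_power: float = 0.80,
    alpha: float = 0.05,
    rounding: Literal["none", "ceil_100"] = "ceil_100",
) -> MinNResult:
    """Smallest sample size whose Wald-test power reaches ``target_power``.

    Monotone bisection over integer N (power is increasing in N).  With
    ``rounding="ceil_100"`` the reported N is rounded up to the next multiple
    of 100 — the convention that reproduces the published minimum sizes — and
    the unrounded solution is carried alongside.  For two-sample bivariate
    designs the ratio n2/n1 is held fixed and both sizes are scaled.
    """
    if not (0.0 < target_power < 1.0):
        raise ValueError(f"target_power={target_power!r} must lie in (0, 1)")
    if rounding not in ("none", "ceil_100"):
        raise ValueError(f"rounding={rounding!r} must be 'none' or 'ceil_100'")
    theta, _ = _theta_and_se(design)
    if theta == 0:
        raise ValueError("the design's parameter is 0: no finite sample size attains the target")
    ratio = 1.0
    if isinstance(design, BivariateDesign) and design.mode == "different_samples":
        ratio = design.n2 / design.n1

    def power_at(n: int) -> float:
        return power_for_design(_rescaled(design, n, ratio), alpha=alpha).power

    lo, hi = 2, 128
    while power_at(hi) < target_power:
        lo, hi = hi, hi * 2
        if hi > 1 << 32:
            raise RuntimeError("sample size solver failed to bracket the target power")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    n_exact = lo
    n = n_exact if rounding == "none" else 100 * math.ceil(n_exact / 100)
    achieved = power_at(n)
    assert achieved >= target_power
    n2 = n2_exact = None
    if isinstance(design, BivariateDesign) and design.mode == "different_samples":
        n2 = math.ceil(ratio * n)
        n2_exact = math.ceil(ratio * n_exact)
    return MinNResult(
        n=n,
        n_exact=n_exact,
        power_at_n=achieved,
        target_power=target_power,
        alpha=alpha,
        n2=n2,
        n2_exact=n2_exact,
    )


def power_curve(design: Design, n_grid: Sequence[int], alpha: float = 0.05) -> pd.DataFrame:
    """Power as a function of sample size.

    ``n_grid`` enumerates the total sample size (set-1 size for two-sample
    designs, with n2 scaled by the design's fixed ratio).  Returns a DataFrame
    with columns ``n, se, ncp, power``; power is non-decreasing along an
    increasing grid.
    """
    if len(n_grid) == 0:
        raise ValueError("n_grid must be non-empty")
    ratio = 1.0
    if isinstance(design, BivariateDesign) and design.mode == "different_samples":
        ratio = design.n2 / design.n1
    rows = []
    for n in n_grid:
        res = power_for_design(_rescaled(design, int(n), ratio), alpha=alpha)
        rows.append({"n": int(n), "se": res.se, "ncp": res.ncp, "power": res.power})
    return pd.DataFrame(rows)


def plot_power_curves(
    curves: dict[str, pd.DataFrame], path: str, title: str = "Statistical power"
) -> None:
    """Write a PNG/SVG of one or more power curves (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, df in curves.items():
        ax.plot(df["n"], df["power"], label=label)
    ax.set_xlabel("sample size")
    ax.set_ylabel("power")
    ax.set_ylim(0, 1)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
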