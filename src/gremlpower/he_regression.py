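"""Haseman-Elston pairwise-product regressions: h2, genetic covariance, rG.

For unrelated individuals, GREML is asymptotically equivalent to ordinary
least squares of pairwise phenotype products on pairwise SNP relatedness:

* univariate: ``y_j * y_k`` on ``A_jk`` over the N(N-1)/2 pairs j < k;
  the slope estimates h2 (phenotypes standardized).
* cross-set covariance: ``y1_i * y2_j`` on ``(A12)_ij`` over all N1*N2
  cross pairs of two disjoint samples; the slope estimates the genetic
  covariance.
* same-sample covariance: the symmetrized product
  ``(y1_j*y2_k + y1_k*y2_j)/2`` on ``A_jk`` over j < k.

The genetic correlation is ``rg = cov / sqrt(h2_1 * h2_2)``, flagged
undefined (NaN) when either heritability estimate is non-positive.

The regressions are computed from closed-form sufficient statistics (sums of
products and quadratic forms) rather than by materializing the pair-level
design vectors; the result is exactly OLS and is verified against a naive
pair-loop oracle in the test suite.  Contrasts sharing an individual are
correlated, but that correlation is negligible in the unrelated-sample
regime this estimator is derived for, so no reweighting is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .grm import GRM, RELATEDNESS_CUTOFF_DEFAULT, empirical_var_pi

__all__ = [
    "HEFit",
    "BivariateFit",
    "he_univariate",
    "he_cross_covariance",
    "he_bivariate_same_sample",
    "he_bivariate_different_samples",
    "read_phenotypes",
    "align_phenotypes",
]


@dataclass(frozen=True)
class HEFit:
    """One pairwise-product regression: slope, residual-based and theory SEs."""

    slope: float
    intercept: float
    se_empirical: float
    se_theory: float
    n_contrasts: int


@dataclass(frozen=True)
class BivariateFit:
    """Two heritability fits, a covariance fit, and the derived genetic correlation."""

    h2_1: HEFit
    h2_2: HEFit
    cov: HEFit
    rg: float
    se_rg_theory: float
    rp: Optional[float] = None


def _standardize(y: np.ndarray, label: str) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    sd = y.std()
    if sd == 0:
        raise ValueError(f"{label} has zero variance; cannot standardize")
    return (y - y.mean()) / sd


def _pair_ols(
    n_contrasts: int, s_a: float, s_aa: float, s_z: float, s_zz: float, s_za: float
) -> tuple[float, float, float]:
    """OLS slope, intercept and empirical slope SE from pair-level sufficient statistics."""
    abar = s_a / n_contrasts
    zbar = s_z / n_contrasts
    saa_c = s_aa - n_contrasts * abar * abar
    if saa_c <= 0:
        raise ValueError("relatedness has zero variance across contrasts; regression undefined")
    sza_c = s_za - n_contrasts * abar * zbar
    szz_c = s_zz - n_contrasts * zbar * zbar
    slope = sza_c / saa_c
    intercept = zbar - slope * abar
    sse = max(szz_c - slope * sza_c, 0.0)
    resid_var = sse / max(n_contrasts - 2, 1)
    se = math.sqrt(resid_var / saa_c)
    return slope, intercept, se


def _offdiag_sums(A: np.ndarray) -> tuple[int, float, float]:
    """(n_pairs, sum a, sum a^2) over the strict upper triangle, without materializing it."""
    n = A.shape[0]
    diag = A.diagonal()
    s_a = (A.sum() - diag.sum()) / 2.0
    s_aa = ((A * A).sum() - (diag * diag).sum()) / 2.0
    return n * (n - 1) // 2, s_a, s_aa


def he_univariate(
    y: Union[np.ndarray, Sequence[float]],
    grm: GRM,
    standardize: bool = True,
    var_pi: Optional[float] = None,
    relatedness_cutoff: Optional[float] = RELATEDNESS_CUTOFF_DEFAULT,
) -> HEFit:
    """Estimate h2 by regressing pairwise phenotype products on relatedness.

    ``se_empirical`` is the residual-based OLS slope SE; ``se_theory`` is
    ``sqrt(2 / (N^2 * var_pi))`` with ``var_pi`` taken from the GRM
    empirically (related pairs above ``relatedness_cutoff`` pruned) unless
    supplied.
    """
    y = np.asarray(y, dtype=float)
    A = grm.values
    if y.shape != (A.shape[0],):
        raise ValueError(f"phenotype length {y.shape} does not match GRM size {A.shape[0]}")
    if standardize:
        y = _standardize(y, "phenotype")
    n = A.shape[0]
    n_pairs, s_a, s_aa = _offdiag_sums(A)
    sy, sy2 = y.sum(), (y * y).sum()
    s_z = (sy * sy - sy2) / 2.0
    s_zz = (sy2 * sy2 - (y**4).sum()) / 2.0
    s_za = (y @ A @ y - (y * y * A.diagonal()).sum()) / 2.0
    slope, intercept, se_emp = _pair_ols(n_pairs, s_a, s_aa, s_z, s_zz, s_za)
    vp = var_pi if var_pi is not None else empirical_var_pi(grm, relatedness_cutoff)
    se_theory = math.sqrt(2.0 / (n * n * vp))
    return HEFit(slope, intercept, se_emp, se_theory, n_pairs)


def he_cross_covariance(
    y1: Union[np.ndarray, Sequence[float]],
    y2: Union[np.ndarray, Sequence[float]],
    a12: np.ndarray,
    ids1: Optional[Sequence[str]] = None,
    ids2: Optional[Sequence[str]] = None,
    standardize: bool = True,
    var_pi: Optional[float] = None,
) -> HEFit:
    """Estimate the genetic covariance of two traits measured on disjoint samples.

    Regresses every cross product ``y1_i * y2_j`` on the cross-set
    relatedness ``(A12)_ij``.  ``se_theory = sqrt(1 / (N1 * N2 * var_pi))``
    with ``var_pi`` the variance of the cross-block entries unless supplied.
    """
    if ids1 is not None and ids2 is not None and set(ids1) & set(ids2):
        raise ValueError(
            "sample sets overlap: the cross-covariance regression assumes disjoint samples"
        )
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    a12 = np.asarray(a12, dtype=float)
    if a12.shape != (y1.size, y2.size):
        raise ValueError(f"a12 shape {a12.shape} does not match phenotype lengths")
    if standardize:
        y1 = _standardize(y1, "phenotype 1")
        y2 = _standardize(y2, "phenotype 2")
    n1, n2 = a12.shape
    n_pairs = n1 * n2
    s_a = a12.sum()
    s_aa = (a12 * a12).sum()
    s_z = y1.sum() * y2.sum()
    s_zz = (y1 * y1).sum() * (y2 * y2).sum()
    s_za = y1 @ a12 @ y2
    slope, intercept, se_emp = _pair_ols(n_pairs, s_a, s_aa, s_z, s_zz, s_za)
    vp = var_pi if var_pi is not None else float(np.var(a12, ddof=1))
    se_theory = math.sqrt(1.0 / (n_pairs * vp))
    return HEFit(slope, intercept, se_emp, se_theory, n_pairs)


def _he_symmetrized_cov(
    y1: np.ndarray, y2: np.ndarray, grm: GRM, var_pi: float, rp: float
) -> HEFit:
    """Same-sample covariance: symmetrized cross product on off-diagonal relatedness."""
    A = grm.values
    n = A.shape[0]
    n_pairs, s_a, s_aa = _offdiag_sums(A)
    s = y1 * y2
    s_z = (y1.sum() * y2.sum() - s.sum()) / 2.0
    # sum over j<k of ((y1_j y2_k + y1_k y2_j)/2)^2, by expansion
    s_zz = (
        (y1 * y1).sum() * (y2 * y2).sum()
        - (y1 * y1 * y2 * y2).sum()
        + s.sum() ** 2
        - (s * s).sum()
    ) / 4.0
    s_za = (y1 @ A @ y2 - (s * A.diagonal()).sum()) / 2.0
    slope, intercept, se_emp = _pair_ols(n_pairs, s_a, s_aa, s_z, s_zz, s_za)
    # var of a standardized covariance estimate ~ (1 + rP^2) per effective contrast
    se_theory = math.sqrt((1.0 + rp * rp) / (n * n * var_pi))
    return HEFit(slope, intercept, se_emp, se_theory, n_pairs)


def _rg_from_fits(
    fit1: HEFit, fit2: HEFit, cov: HEFit
) -> float:
    if fit1.slope <= 0 or fit2.slope <= 0:
        warnings.warn(
            "non-positive heritability estimate: genetic correlation undefined (NaN)",
            stacklevel=3,
        )
        return math.nan
    return cov.slope / math.sqrt(fit1.slope * fit2.slope)


def he_bivariate_same_sample(
    y1: Union[np.ndarray, Sequence[float]],
    y2: Union[np.ndarray, Sequence[float]],
    grm: GRM,
    standardize: bool = True,
    var_pi: Optional[float] = None,
    relatedness_cutoff: Optional[float] = RELATEDNESS_CUTOFF_DEFAULT,
) -> BivariateFit:
    """Bivariate HE analysis of two traits measured on the same individuals.

    The theory SE of rg plugs the estimated heritabilities, the estimated rg,
    the sample phenotypic correlation and the empirical var_pi into the
    same-sample approximation formula.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if standardize:
        y1 = _standardize(y1, "phenotype 1")
        y2 = _standardize(y2, "phenotype 2")
    vp = var_pi if var_pi is not None else empirical_var_pi(grm, relatedness_cutoff)
    rp = float(np.corrcoef(y1, y2)[0, 1])
    fit1 = he_univariate(y1, grm, standardize=False, var_pi=vp)
    fit2 = he_univariate(y2, grm, standardize=False, var_pi=vp)
    cov = _he_symmetrized_cov(y1, y2, grm, vp, rp)
    rg = _rg_from_fits(fit1, fit2, cov)
    n = grm.n
    if math.isnan(rg):
        se_rg = math.nan
    else:
        num = (1.0 - rg * rp) ** 2 + (rg - rp) ** 2
        se_rg = math.sqrt(num / (n * n * vp * fit1.slope * fit2.slope))
    return BivariateFit(h2_1=fit1, h2_2=fit2, cov=cov, rg=rg, se_rg_theory=se_rg, rp=rp)


def he_bivariate_different_samples(
    y1: Union[np.ndarray, Sequence[float]],
    y2: Union[np.ndarray, Sequence[float]],
    grm1: GRM,
    grm2: GRM,
    a12: np.ndarray,
    standardize: bool = True,
    var_pi: Optional[float] = None,
    relatedness_cutoff: Optional[float] = RELATEDNESS_CUTOFF_DEFAULT,
) -> BivariateFit:
    """Bivariate HE analysis of two traits measured on disjoint samples.

    Composes a univariate fit per sample with the cross-set covariance
    regression; the theory SE of rg uses the different-samples delta-method
    formula at the estimated values.
    """
    if set(grm1.ids) & set(grm2.ids):
        raise ValueError("sample sets overlap: different-samples analysis requires disjoint sets")
    vp1 = var_pi if var_pi is not None else empirical_var_pi(grm1, relatedness_cutoff)
    vp2 = var_pi if var_pi is not None else empirical_var_pi(grm2, relatedness_cutoff)
    fit1 = he_univariate(y1, grm1, standardize=standardize, var_pi=vp1)
    fit2 = he_univariate(y2, grm2, standardize=standardize, var_pi=vp2)
    vp12 = var_pi if var_pi is not None else float(np.var(np.asarray(a12), ddof=1))
    cov = he_cross_covariance(
        y1, y2, a12, ids1=grm1.ids, ids2=grm2.ids, standardize=standardize, var_pi=vp12
    )
    rg = _rg_from_fits(fit1, fit2, cov)
    n1, n2 = grm1.n, grm2.n
    if math.isnan(rg):
        se_rg = math.nan
    else:
        h1, h2 = fit1.slope, fit2.slope
        var_rg = (
            1.0 / (h1 * h2 * n1 * n2 * vp12)
            + rg**2 / (2.0 * h1**2 * n1**2 * vp1)
            + rg**2 / (2.0 * h2**2 * n2**2 * vp2)
        )
        se_rg = math.sqrt(var_rg)
    return BivariateFit(h2_1=fit1, h2_2=fit2, cov=cov, rg=rg, se_rg_theory=se_rg, rp=None)


def read_phenotypes(path: Union[str, Path]) -> pd.DataFrame:
    """Read a GCTA-style phenotype file: whitespace-delimited FID IID value, NA = missing."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["fid", "iid", "value"],
        na_values=["NA"], dtype={"fid": str, "iid": str},
    )
    return df


def align_phenotypes(df: pd.DataFrame, ids: Sequence[str]) -> np.ndarray:
    """Phenotype values ordered to ``ids``; raises on missing individuals or values."""
    series = df.set_index("iid")["value"]
    missing = [i for i in ids if i not in series.index]
    if missing:
        raise ValueError(f"{len(missing)} ids missing from phenotype file, e.g. {missing[0]!r}")
    values = series.loc[list(ids)].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("missing phenotype values among the requested ids")
    return values
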