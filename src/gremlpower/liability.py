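"""Liability-threshold quantities and the observed <-> liability scale transform.

A disease with population prevalence ``K`` is modelled as a thresholded
standard-normal liability: an individual is affected when its liability
exceeds ``t = Phi^{-1}(1 - K)``.  SNP-heritability estimated on the 0/1
observed scale of an (often ascertained) case-control sample, with case
proportion ``v``, converts to the population liability scale by the linear
factor

    c = K^2 (1 - K)^2 / (z^2 * v (1 - v)) = (1 - K)^2 / (i^2 * v (1 - v))

where ``z`` is the normal density at the threshold and ``i = z / K`` is the
selection intensity (mean liability of cases).  Standard errors transform by
the same factor, so Wald test statistics — and hence power — are invariant to
the scale on which a case-control analysis is expressed.

Note the direction of the correction under strong ascertainment: for a rare
disease studied with ``v = 0.5``, ``c < 1`` (e.g. ``c(0.01, 0.5) = 0.552``),
because ascertainment concentrates liability-scale information in the sample.
``c`` increases with ``K`` at fixed ``v`` and equals ``pi/2`` at
``K = v = 0.5``.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm

__all__ = ["LiabilityModel", "make_liability_model", "h2_obs_to_liab", "h2_liab_to_obs"]

# z/K is numerically fragile in the extreme tails and outside the regime the
# approximation theory was developed for.
_K_MIN = 1e-6


@dataclass(frozen=True)
class LiabilityModel:
    """Threshold-model quantities for a (prevalence, case-proportion) pair.

    Attributes
    ----------
    K : float
        Population prevalence of the disease, ``0 < K < 1``.
    v : float
        Proportion of cases in the analysed sample, ``0 < v < 1``.
    t : float
        Liability threshold, ``Phi^{-1}(1 - K)``.
    z : float
        Standard-normal density at ``t``.
    i : float
        Selection intensity ``z / K`` (mean liability of cases).
    c : float
        Observed-to-liability scaling factor for heritabilities and their
        standard errors.
    """

    K: float
    v: float
    t: float
    z: float
    i: float
    c: float


def make_liability_model(K: float, v: float) -> LiabilityModel:
    """Build a :class:`LiabilityModel` from prevalence ``K`` and case proportion ``v``.

    Parameters
    ----------
    K : float
        Population prevalence, required to lie in ``(1e-6, 1 - 1e-6)``;
        values outside that band are rejected rather than extrapolated.
    v : float
        Case proportion of the sample, in ``(0, 1)``.

    Returns
    -------
    LiabilityModel

    Examples
    --------
    >>> m = make_liability_model(0.5, 0.5)
    >>> round(m.c, 7)            # pi/2 at the symmetric threshold
    1.5707963
    """
    if not (_K_MIN < K < 1.0 - _K_MIN):
        raise ValueError(
            f"prevalence K={K!r} out of range: must lie in ({_K_MIN}, {1 - _K_MIN})"
        )
    if not (0.0 < v < 1.0):
        raise ValueError(f"case proportion v={v!r} out of range: must lie in (0, 1)")
    t = norm.isf(K)  # Phi^{-1}(1 - K)
    z = norm.pdf(t)
    i = z / K
    c = (K * (1.0 - K)) ** 2 / (z * z * v * (1.0 - v))
    return LiabilityModel(K=K, v=v, t=t, z=z, i=i, c=c)


def h2_obs_to_liab(h2_obs: float, model: LiabilityModel) -> float:
    """Convert observed-scale (0/1) SNP heritability to the liability scale.

    Strictly linear: ``h2_liab = c * h2_obs``.
    """
    if h2_obs < 0:
        raise ValueError(f"h2_obs={h2_obs!r} must be non-negative")
    return h2_obs * model.c


def h2_liab_to_obs(h2_liab: float, model: LiabilityModel) -> float:
    """Convert liability-scale SNP heritability to the observed 0/1 scale.

    Inverse of :func:`h2_obs_to_liab`: ``h2_obs = h2_liab / c``.
    """
    if h2_liab < 0:
        raise ValueError(f"h2_liab={h2_liab!r} must be non-negative")
    return h2_liab / model.c
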