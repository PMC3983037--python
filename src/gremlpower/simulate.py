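"""Synthetic genotype/phenotype generator and the replicate verification harness.

The generator emulates exactly the statistical structure the closed-form
theory assumes: unrelated individuals, genome-wide SNPs in Hardy-Weinberg
and linkage equilibrium (allele frequencies uniform over ``maf_range``),
a polygenic additive architecture with configurable h2, a genetic
correlation induced either by correlated causal effects or by a shared
subset of causal variants, and liability-threshold case-control
ascertainment from an oversampled population pool.

With independent SNPs the variance of GRM off-diagonals is 1/m, which plays
the role the genome-wide constant 2e-5 plays for real data; the replicate
harness therefore reports the theory SE computed with both 1/m and the
empirical var_pi of the simulated GRM.

All randomness flows from a single integer seed through a
``numpy.random.SeedSequence``: the genotype draw and every replicate get
independent child streams, so replicate r is reproducible on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .grm import GRM, GenotypeMatrix, compute_grm, empirical_var_pi
from .he_regression import (
    he_bivariate_different_samples,
    he_bivariate_same_sample,
    he_univariate,
)
from .liability import make_liability_model

__all__ = [
    "SimulationConfig",
    "PhenotypeDraw",
    "CaseControlSample",
    "VerificationReport",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_case_control",
    "run_replicates",
]

_DESIGNS = ("univariate", "bivariate_same_sample", "bivariate_different_samples", "case_control")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulation experiment.

    Defaults are the verification-scale conditions used throughout: n = 2000
    individuals, m = 10000 independent SNPs with allele frequencies uniform
    on (0.05, 0.5), a fully polygenic architecture (every SNP causal), and
    100 replicates.
    """

    design: str = "univariate"
    n: int = 2000
    n2: Optional[int] = None
    m: int = 10000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: Optional[int] = None
    h2: float = 0.5
    h2_2: Optional[float] = None
    rg: float = 0.0
    re: float = 0.0
    rg_mechanism: str = "correlated_effects"
    prevalence: Optional[float] = None
    case_fraction: float = 0.5
    pool_multiplier: Optional[float] = None
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in _DESIGNS:
            raise ValueError(f"design={self.design!r}; must be one of {_DESIGNS}")
        if self.n < 2 or self.m < 1:
            raise ValueError("need n >= 2 individuals and m >= 1 SNPs")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range={self.maf_range!r} must lie within (0, 0.5]")
        if self.n_causal is not None and not (1 <= self.n_causal <= self.m):
            raise ValueError(f"n_causal={self.n_causal!r} must lie in [1, m]")
        for name in ("h2", "h2_2"):
            val = getattr(self, name)
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValueError(f"{name}={val!r} must lie in [0, 1]")
        if abs(self.rg) > 1 or abs(self.re) > 1:
            raise ValueError("rg and re must lie in [-1, 1]")
        if self.rg_mechanism not in ("correlated_effects", "shared_fraction"):
            raise ValueError(f"rg_mechanism={self.rg_mechanism!r}")
        if self.design == "bivariate_different_samples" and self.n2 is None:
            raise ValueError("bivariate_different_samples requires n2")
        if self.design == "case_control" and self.prevalence is None:
            raise ValueError("case_control design requires prevalence")
        if self.prevalence is not None and not (0.0 < self.prevalence < 1.0):
            raise ValueError(f"prevalence={self.prevalence!r} must lie in (0, 1)")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError(f"case_fraction={self.case_fraction!r} must lie in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def n_causal_resolved(self) -> int:
        return self.m if self.n_causal is None else self.n_causal

    @property
    def h2_2_resolved(self) -> float:
        return self.h2 if self.h2_2 is None else self.h2_2

    @property
    def n_total(self) -> int:
        """Individuals to genotype: both sets for different-samples, the pool for case-control."""
        if self.design == "bivariate_different_samples":
            return self.n + self.n2
        if self.design == "case_control":
            return math.ceil(self.n * self.pool_multiplier_resolved)
        return self.n

    @property
    def pool_multiplier_resolved(self) -> float:
        if self.pool_multiplier is not None:
            return self.pool_multiplier
        # enough expected cases for the target case count, with a 2x margin
        return max(5.0, 2.0 * self.case_fraction / self.prevalence)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "maf_range" in raw:
            raw["maf_range"] = tuple(raw["maf_range"])
        return cls(**raw)


@dataclass(frozen=True)
class PhenotypeDraw:
    """One simulated phenotype draw: observed vectors and the true genetic values."""

    phenotypes: tuple[np.ndarray, ...]
    genetic_values: tuple[np.ndarray, ...]

    @property
    def y(self) -> np.ndarray:
        return self.phenotypes[0]


@dataclass(frozen=True)
class CaseControlSample:
    """Ascertained case-control sample drawn from a simulated population pool."""

    ids: list[str]
    indices: np.ndarray
    status: np.ndarray
    liability: np.ndarray
    genetic_values: np.ndarray


def _as_rng(rng: Optional[Union[int, np.random.Generator]]) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def simulate_genotypes(
    cfg: SimulationConfig,
    rng: Optional[Union[int, np.random.Generator]] = None,
    n: Optional[int] = None,
) -> GenotypeMatrix:
    """Draw HWE/LE genotypes: p_i ~ U(maf_range), counts ~ Binomial(2, p_i).

    ``n`` overrides the config-resolved individual count (both sets for
    different-samples designs, the population pool for case-control).
    """
    rng = _as_rng(cfg.seed if rng is None else rng)
    n = cfg.n_total if n is None else n
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.m)
    counts = rng.binomial(2, p, size=(n, cfg.m)).astype(float)
    ids = [f"ind{i + 1:06d}" for i in range(n)]
    return GenotypeMatrix(ids=ids, counts=counts)


def _standardized_columns(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardized genotype matrix and the polymorphic-column index (cached)."""
    return g.standardized()


def _scale_to_var(x: np.ndarray, target_var: float) -> np.ndarray:
    """Rescale a vector so its realized variance equals ``target_var`` exactly."""
    if target_var == 0.0:
        return np.zeros_like(x)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot rescale a constant vector to positive variance")
    return x * (math.sqrt(target_var) / sd)


def _draw_effect_pair(cfg: SimulationConfig, n_causal: int, rng: np.random.Generator):
    """Causal-effect vectors for two traits under the configured rG mechanism."""
    if cfg.rg_mechanism == "correlated_effects":
        u1 = rng.standard_normal(n_causal)
        u2 = cfg.rg * u1 + math.sqrt(max(1.0 - cfg.rg**2, 0.0)) * rng.standard_normal(n_causal)
        return u1, u2
    # shared_fraction: a proportion rg of causal variants carries the SAME
    # effect in both traits; the remainder are trait-specific.  With equal
    # per-variant effect variances the genetic correlation equals the shared
    # fraction.
    if cfg.rg < 0:
        raise ValueError(
            "shared_fraction cannot induce a negative rg; use rg_mechanism='correlated_effects'"
        )
    s_exact = cfg.rg * n_causal
    s = round(s_exact)
    if abs(s_exact - s) > 1e-8:
        raise ValueError(
            f"rg={cfg.rg} is not a multiple of 1/n_causal={1 / n_causal}; "
            "the shared-causal-fraction mechanism cannot hit it exactly — "
            "use rg_mechanism='correlated_effects'"
        )
    shared = rng.standard_normal(s)
    u1 = np.concatenate([shared, rng.standard_normal(n_causal - s)])
    u2 = np.concatenate([shared, rng.standard_normal(n_causal - s)])
    return u1, u2


def simulate_phenotypes(
    g: GenotypeMatrix,
    cfg: SimulationConfig,
    rng: Optional[Union[int, np.random.Generator]] = None,
) -> PhenotypeDraw:
    """Draw phenotypes ``y = g + e`` on standardized genotypes.

    Causal effects are standard normal at ``n_causal`` loci; genetic values
    are rescaled so the realized genetic variance is exactly h2 and residuals
    so the realized residual variance is exactly 1 - h2.  Bivariate designs
    correlate the genetic parts through the configured mechanism and, for
    same-sample designs, the residual parts with correlation ``re`` — so the
    phenotypic correlation is rg*sqrt(h2_1*h2_2) + re*sqrt((1-h2_1)(1-h2_2)).
    """
    rng = _as_rng(cfg.seed if rng is None else rng)
    w, poly_idx = _standardized_columns(g)
    n_causal = min(cfg.n_causal_resolved, poly_idx.size)
    causal = rng.choice(poly_idx, size=n_causal, replace=False)
    if n_causal == poly_idx.size:
        # fully polygenic: effects are iid, so the column permutation is
        # irrelevant and the large copy can be skipped
        wc = w[:, poly_idx] if poly_idx.size != w.shape[1] else w
    else:
        wc = w[:, causal]

    if cfg.design in ("univariate", "case_control"):
        u = rng.standard_normal(n_causal)
        gv = _scale_to_var(wc @ u, cfg.h2)
        e = _scale_to_var(rng.standard_normal(g.n_individuals), 1.0 - cfg.h2)
        return PhenotypeDraw(phenotypes=(gv + e,), genetic_values=(gv,))

    h2_1, h2_2 = cfg.h2, cfg.h2_2_resolved
    u1, u2 = _draw_effect_pair(cfg, n_causal, rng)
    if cfg.design == "bivariate_same_sample":
        g1 = _scale_to_var(wc @ u1, h2_1)
        g2 = _scale_to_var(wc @ u2, h2_2)
        e1 = rng.standard_normal(g.n_individuals)
        e2 = cfg.re * e1 + math.sqrt(max(1.0 - cfg.re**2, 0.0)) * rng.standard_normal(
            g.n_individuals
        )
        e1 = _scale_to_var(e1, 1.0 - h2_1)
        e2 = _scale_to_var(e2, 1.0 - h2_2)
        return PhenotypeDraw(phenotypes=(g1 + e1, g2 + e2), genetic_values=(g1, g2))

    # different samples: trait 1 on the first n rows, trait 2 on the rest
    n1 = cfg.n
    g1 = _scale_to_var(wc[:n1] @ u1, h2_1)
    g2 = _scale_to_var(wc[n1:] @ u2, h2_2)
    e1 = _scale_to_var(rng.standard_normal(n1), 1.0 - h2_1)
    e2 = _scale_to_var(rng.standard_normal(g.n_individuals - n1), 1.0 - h2_2)
    return PhenotypeDraw(phenotypes=(g1 + e1, g2 + e2), genetic_values=(g1, g2))


def simulate_case_control(
    g_pool: GenotypeMatrix,
    cfg: SimulationConfig,
    rng: Optional[Union[int, np.random.Generator]] = None,
) -> CaseControlSample:
    """Ascertain a case-control sample from a population pool by liability threshold.

    Liability = genetic value (variance h2, liability scale) + normal
    residual; individuals above ``Phi^{-1}(1 - K)`` are cases.  ``n *
    case_fraction`` cases and the complement of controls are sampled without
    replacement.
    """
    rng = _as_rng(cfg.seed if rng is None else rng)
    if cfg.prevalence is None:
        raise ValueError("case_control simulation requires cfg.prevalence")
    draw = simulate_phenotypes(g_pool, replace(cfg, design="case_control"), rng)
    liability = draw.y
    threshold = norm.isf(cfg.prevalence)
    is_case = liability > threshold
    case_idx = np.flatnonzero(is_case)
    control_idx = np.flatnonzero(~is_case)
    n_cases = round(cfg.case_fraction * cfg.n)
    n_controls = cfg.n - n_cases
    if case_idx.size < n_cases:
        achievable = math.floor(case_idx.size / cfg.case_fraction)
        raise ValueError(
            f"pool of {g_pool.n_individuals} yields only {case_idx.size} cases; "
            f"need {n_cases}. Max achievable sample at case_fraction="
            f"{cfg.case_fraction}: ~{achievable}. Increase pool_multiplier."
        )
    if control_idx.size < n_controls:
        raise ValueError(
            f"pool yields only {control_idx.size} controls; need {n_controls}"
        )
    sel_cases = rng.choice(case_idx, size=n_cases, replace=False)
    sel_controls = rng.choice(control_idx, size=n_controls, replace=False)
    indices = np.concatenate([sel_cases, sel_controls])
    status = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    return CaseControlSample(
        ids=[g_pool.ids[i] for i in indices],
        indices=indices,
        status=status,
        liability=liability[indices],
        genetic_values=draw.genetic_values[0][indices],
    )


@dataclass
class VerificationReport:
    """Replicate-level estimates plus the summary comparing empirical and theory SEs."""

    config: SimulationConfig
    replicates: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def summary_text(self) -> str:
        s = self.summary
        lines = [
            f"design            : {self.config.design}",
            f"replicates        : {s['n_replicates']}",
            f"truth             : {s['truth']:.4f}",
            f"mean estimate     : {s['mean_estimate']:.4f}",
            f"SD of estimates   : {s['sd_estimate']:.4f}",
            f"mean empirical SE : {s['mean_se_empirical']:.4f}",
            f"theory SE (emp. var_pi) : {s['se_theory_empirical']:.4f}",
            f"theory SE (1/m var_pi)  : {s['se_theory_inv_m']:.4f}",
        ]
        return "\n".join(lines)

    def to_csv(self, path: Union[str, Path]) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            for key, val in self.summary.items():
                fh.write(f"# {key}: {val}\n")
            self.replicates.to_csv(fh, index=False)


def _grm_block(g: GenotypeMatrix, grm: GRM, lo: int, hi: int) -> GRM:
    return GRM(
        ids=g.ids[lo:hi],
        values=grm.values[lo:hi, lo:hi],
        n_snps=grm.n_snps[lo:hi, lo:hi],
    )


def run_replicates(cfg: SimulationConfig) -> VerificationReport:
    """Simulate, estimate and summarize over ``cfg.n_replicates`` replicates.

    Genotypes (and hence the GRM) are drawn once and held fixed across
    replicates — mirroring a fixed genotyped cohort — while causal effects,
    residuals and (for case-control) ascertainment are redrawn every
    replicate.  Deterministic for a given seed.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_replicates + 1)
    geno_rng = np.random.default_rng(children[0])
    rep_rngs = [np.random.default_rng(c) for c in children[1:]]

    if cfg.design == "case_control":
        return _run_case_control(cfg, geno_rng, rep_rngs)

    g = simulate_genotypes(cfg, geno_rng)
    grm = compute_grm(g)
    inv_m = 1.0 / cfg.m

    # simulated samples contain no cryptic relatives, so var_pi uses every pair
    rows = []
    if cfg.design == "univariate":
        vp = empirical_var_pi(grm, relatedness_cutoff=None)
        for rng in rep_rngs:
            draw = simulate_phenotypes(g, cfg, rng)
            fit = he_univariate(draw.y, grm, var_pi=vp)
            rows.append({"estimate": fit.slope, "se_empirical": fit.se_empirical})
        truth = cfg.h2
        se_theory_emp = math.sqrt(2.0 / (cfg.n**2 * vp))
        se_theory_inv_m = math.sqrt(2.0 / (cfg.n**2 * inv_m))
    elif cfg.design == "bivariate_same_sample":
        vp = empirical_var_pi(grm, relatedness_cutoff=None)
        for rng in rep_rngs:
            draw = simulate_phenotypes(g, cfg, rng)
            fit = he_bivariate_same_sample(*draw.phenotypes, grm, var_pi=vp)
            rows.append(
                {
                    "estimate": fit.rg,
                    "se_empirical": fit.se_rg_theory,
                    "h2_1": fit.h2_1.slope,
                    "h2_2": fit.h2_2.slope,
                }
            )
        truth = cfg.rg
        h1, h2 = cfg.h2, cfg.h2_2_resolved
        rp = cfg.rg * math.sqrt(h1 * h2) + cfg.re * math.sqrt((1 - h1) * (1 - h2))
        num = (1.0 - cfg.rg * rp) ** 2 + (cfg.rg - rp) ** 2
        se_theory_emp = math.sqrt(num / (cfg.n**2 * vp * h1 * h2))
        se_theory_inv_m = math.sqrt(num / (cfg.n**2 * inv_m * h1 * h2))
    else:  # bivariate_different_samples
        n1, n2 = cfg.n, cfg.n2
        grm1 = _grm_block(g, grm, 0, n1)
        grm2 = _grm_block(g, grm, n1, n1 + n2)
        a12 = grm.values[:n1, n1:]
        vp1 = empirical_var_pi(grm1, relatedness_cutoff=None)
        vp2 = empirical_var_pi(grm2, relatedness_cutoff=None)
        vp12 = float(np.var(a12, ddof=1))
        for rng in rep_rngs:
            draw = simulate_phenotypes(g, cfg, rng)
            fit = he_bivariate_different_samples(
                *draw.phenotypes, grm1, grm2, a12, var_pi=vp12
            )
            rows.append(
                {
                    "estimate": fit.rg,
                    "se_empirical": fit.se_rg_theory,
                    "h2_1": fit.h2_1.slope,
                    "h2_2": fit.h2_2.slope,
                }
            )
        truth = cfg.rg
        h1, h2 = cfg.h2, cfg.h2_2_resolved

        def _var_rg(v1: float, v2: float, v12: float) -> float:
            return (
                1.0 / (h1 * h2 * n1 * n2 * v12)
                + cfg.rg**2 / (2.0 * h1**2 * n1**2 * v1)
                + cfg.rg**2 / (2.0 * h2**2 * n2**2 * v2)
            )

        se_theory_emp = math.sqrt(_var_rg(vp1, vp2, vp12))
        se_theory_inv_m = math.sqrt(_var_rg(inv_m, inv_m, inv_m))

    df = pd.DataFrame(rows)
    estimates = df["estimate"].to_numpy()
    summary = {
        "n_replicates": cfg.n_replicates,
        "truth": truth,
        "mean_estimate": float(estimates.mean()),
        "sd_estimate": float(estimates.std(ddof=1)),
        "mean_se_empirical": float(df["se_empirical"].mean()),
        "se_theory_empirical": se_theory_emp,
        "se_theory_inv_m": se_theory_inv_m,
    }
    return VerificationReport(config=cfg, replicates=df, summary=summary)


def _run_case_control(
    cfg: SimulationConfig,
    geno_rng: np.random.Generator,
    rep_rngs: list[np.random.Generator],
) -> VerificationReport:
    g_pool = simulate_genotypes(cfg, geno_rng)
    model = make_liability_model(cfg.prevalence, cfg.case_fraction)
    inv_m = 1.0 / cfg.m
    rows = []
    vps = []
    for rng in rep_rngs:
        sample = simulate_case_control(g_pool, cfg, rng)
        g_sub = GenotypeMatrix(
            ids=sample.ids, counts=g_pool.counts[sample.indices]
        )
        grm = compute_grm(g_sub)
        vp = empirical_var_pi(grm, relatedness_cutoff=None)
        vps.append(vp)
        fit = he_univariate(sample.status, grm, var_pi=vp)
        rows.append(
            {
                "estimate": fit.slope * model.c,  # liability scale
                "estimate_observed": fit.slope,
                "se_empirical": fit.se_empirical * model.c,
            }
        )
    df = pd.DataFrame(rows)
    estimates = df["estimate"].to_numpy()
    vp_mean = float(np.mean(vps))
    summary = {
        "n_replicates": cfg.n_replicates,
        "truth": cfg.h2,
        "mean_estimate": float(estimates.mean()),
        "sd_estimate": float(estimates.std(ddof=1)),
        "mean_se_empirical": float(df["se_empirical"].mean()),
        "se_theory_empirical": model.c * math.sqrt(2.0 / (cfg.n**2 * vp_mean)),
        "se_theory_inv_m": model.c * math.sqrt(2.0 / (cfg.n**2 * inv_m)),
    }
    return VerificationReport(config=cfg, replicates=df, summary=summary)
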