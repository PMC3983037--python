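"""SNP-derived genetic relationship matrices (GRMs) and GCTA-style text I/O.

The GRM entry for individuals j, k over M SNPs with allele frequencies p_i is

    A_jk = (1/M) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

with the diagonal computed by the same formula at j = k.  Among unrelated
individuals the off-diagonals are distributed about zero (and may be
negative); their variance, ``var_pi``, is the constant that scales every
sampling-variance formula in this package.  For M independent SNPs in
Hardy-Weinberg equilibrium, var_pi -> 1/M.

Missing genotypes are handled per pair, complete-case: each pair's entry
averages over the SNPs observed in both individuals, with the per-pair SNP
count recorded.  The text format is the GCTA whitespace-triplet dialect:
``<prefix>.grm`` holds ``index1 index2 n_snps value`` (1-based, lower
triangle including the diagonal) and ``<prefix>.grm.id`` one ``FID IID`` pair
per line; gzip compression is optional.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["GenotypeMatrix", "GRM", "compute_grm", "empirical_var_pi",
           "read_grm", "write_grm", "read_genotypes", "write_genotypes"]

#: Conventional relatedness threshold above which a pair is treated as
#: cryptically related and excluded from var_pi estimation.
RELATEDNESS_CUTOFF_DEFAULT = 0.025


@dataclass
class GenotypeMatrix:
    """Allele-count matrix (individuals x SNPs) with optional external frequencies.

    ``counts`` holds 0/1/2 with NaN for missing.  ``freqs`` are per-SNP allele
    frequencies of the counted allele; when None they are estimated from the
    sample (the GCTA default).
    """

    ids: list[str]
    counts: np.ndarray
    freqs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D (individuals x SNPs) array")
        if len(self.ids) != self.counts.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids but {self.counts.shape[0]} genotype rows"
            )
        valid = np.isnan(self.counts) | np.isin(self.counts, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = self.counts[~valid].flat[0]
            raise ValueError(f"genotype counts must be 0, 1, 2 or missing; found {bad!r}")
        if self.freqs is not None:
            self.freqs = np.asarray(self.freqs, dtype=float)
            if self.freqs.shape != (self.counts.shape[1],):
                raise ValueError("freqs must have one entry per SNP")

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP frequency of the counted allele (external if supplied)."""
        if self.freqs is not None:
            return self.freqs
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.counts, axis=0) / 2.0

    def standardized(self) -> tuple[np.ndarray, np.ndarray]:
        """Column-standardized genotypes (missing as 0) and the polymorphic-column index.

        Cached: the matrix is large and reused heavily by the simulation
        harness; invalidate by constructing a new GenotypeMatrix.
        """
        cached = getattr(self, "_std_cache", None)
        if cached is not None:
            return cached
        p = self.allele_frequencies()
        poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
        w = np.zeros_like(self.counts)
        w[:, poly] = (self.counts[:, poly] - 2.0 * p[poly]) / np.sqrt(
            2.0 * p[poly] * (1.0 - p[poly])
        )
        w[np.isnan(self.counts)] = 0.0
        result = (w, np.flatnonzero(poly))
        object.__setattr__(self, "_std_cache", result)
        return result


@dataclass
class GRM:
    """Symmetric SNP-relatedness matrix with ids and per-pair SNP counts."""

    ids: list[str]
    values: np.ndarray
    n_snps: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n_snps = np.asarray(self.n_snps)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"values must be {n}x{n} to match ids")
        if self.n_snps.shape != (n, n):
            raise ValueError(f"n_snps must be {n}x{n} to match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def offdiagonal(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries as a flat vector."""
        return self.values[np.triu_indices(self.n, k=1)]

    def submatrix(self, ids: Sequence[str]) -> "GRM":
        """GRM restricted to ``ids`` (in the given order)."""
        idx = [self.ids.index(i) for i in ids]
        sel = np.ix_(idx, idx)
        return GRM(ids=list(ids), values=self.values[sel], n_snps=self.n_snps[sel])

    def cross_block(self, ids1: Sequence[str], ids2: Sequence[str]) -> np.ndarray:
        """Rectangular relatedness block between two disjoint id sets."""
        if set(ids1) & set(ids2):
            raise ValueError("cross_block requires disjoint id sets")
        i1 = [self.ids.index(i) for i in ids1]
        i2 = [self.ids.index(i) for i in ids2]
        return self.values[np.ix_(i1, i2)]


def compute_grm(g: GenotypeMatrix) -> GRM:
    """Build the SNP-derived GRM from an allele-count matrix.

    Monomorphic SNPs (sample frequency 0 or 1) are dropped with a logged
    count.  Raises if any pair of individuals shares no observed SNP.
    """
    if g.n_individuals < 2:
        raise ValueError("need at least 2 individuals to compute a GRM")
    p = g.allele_frequencies()
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.info("compute_grm: dropped %d monomorphic/unusable SNPs", n_dropped)
    if not poly.any():
        raise ValueError("no polymorphic SNPs left after filtering")
    x = g.counts[:, poly]
    p = p[poly]
    missing = np.isnan(x)
    z = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    z[missing] = 0.0
    num = z @ z.T
    m_poly = int(poly.sum())
    if missing.any():
        obs = (~missing).astype(float)
        cnt_int = np.rint(obs @ obs.T).astype(np.int64)
    else:  # complete data: skip the counting matmul
        cnt_int = np.full((g.n_individuals, g.n_individuals), m_poly, dtype=np.int64)
    if (cnt_int == 0).any():
        raise ValueError("some pair of individuals has no SNP observed in both")
    values = num / cnt_int
    values = (values + values.T) / 2.0  # enforce exact symmetry
    return GRM(ids=list(g.ids), values=values, n_snps=cnt_int)


def empirical_var_pi(
    grm: GRM, relatedness_cutoff: Optional[float] = RELATEDNESS_CUTOFF_DEFAULT
) -> float:
    """Variance of off-diagonal relatedness, optionally pruning related pairs.

    Pairs with relatedness above ``relatedness_cutoff`` (default 0.025, the
    conventional cryptic-relatedness threshold) are excluded before taking
    the variance; pass None to keep all pairs.
    """
    if grm.n < 3:
        raise ValueError("need at least 3 individuals to estimate var_pi")
    off = grm.offdiagonal()
    if relatedness_cutoff is not None:
        off = off[off <= relatedness_cutoff]
    if off.size < 2:
        raise ValueError("fewer than 2 off-diagonal pairs retained for var_pi")
    return float(np.var(off, ddof=1))


def _open_text(path: Path, mode: str):
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _grm_paths(prefix: Union[str, Path], compress: bool) -> tuple[Path, Path]:
    prefix = Path(prefix)
    grm_path = prefix.with_name(prefix.name + (".grm.gz" if compress else ".grm"))
    id_path = prefix.with_name(prefix.name + ".grm.id")
    return grm_path, id_path


def write_grm(grm: GRM, prefix: Union[str, Path], compress: bool = False) -> None:
    """Write GCTA-style text triplets (lower triangle, 1-based) plus the id file."""
    grm_path, id_path = _grm_paths(prefix, compress)
    with open(id_path, "w") as fh:
        for iid in grm.ids:
            fh.write(f"{iid}\t{iid}\n")
    with _open_text(grm_path, "w") as fh:
        for j in range(grm.n):
            for k in range(j + 1):
                fh.write(f"{j + 1}\t{k + 1}\t{int(grm.n_snps[j, k])}\t{grm.values[j, k]:.6f}\n")


def read_grm(prefix: Union[str, Path]) -> GRM:
    """Read a text GRM written by :func:`write_grm` (or by GCTA).

    Accepts a lower-triangle-only file and reconstructs the full symmetric
    matrix; malformed lines raise with their line number.
    """
    grm_path, id_path = _grm_paths(prefix, compress=False)
    if not grm_path.exists():
        gz = grm_path.with_name(grm_path.name + ".gz")
        if gz.exists():
            grm_path = gz
        else:
            raise FileNotFoundError(f"no GRM file at {grm_path} (or .gz)")
    ids = []
    with open(id_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{id_path}:{lineno}: expected 'FID IID', got {line!r}")
            ids.append(parts[1])
    n = len(ids)
    values = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=np.int64)
    with _open_text(grm_path, "r") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{grm_path}:{lineno}: expected 4 fields, got {len(parts)}")
            try:
                j, k, m = int(parts[0]), int(parts[1]), int(parts[2])
                val = float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{grm_path}:{lineno}: {exc}") from None
            if not (1 <= j <= n and 1 <= k <= n):
                raise ValueError(
                    f"{grm_path}:{lineno}: indices ({j}, {k}) outside the {n} ids in {id_path}"
                )
            j, k = j - 1, k - 1
            values[j, k] = values[k, j] = val
            counts[j, k] = counts[k, j] = m
    if np.isnan(values).any():
        missing = int(np.isnan(values[np.tril_indices(n)]).sum())
        raise ValueError(f"{grm_path}: {missing} lower-triangle entries missing")
    return GRM(ids=ids, values=values, n_snps=counts)


def write_genotypes(g: GenotypeMatrix, path: Union[str, Path]) -> None:
    """Write the simple text genotype format: header of SNP names, one id + counts row each."""
    path = Path(path)
    with _open_text(path, "w") as fh:
        fh.write("id\t" + "\t".join(f"snp{i + 1}" for i in range(g.n_snps)) + "\n")
        for iid, row in zip(g.ids, g.counts):
            vals = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write(iid + "\t" + "\t".join(vals) + "\n")


def read_genotypes(path: Union[str, Path]) -> GenotypeMatrix:
    """Read the text genotype format written by :func:`write_genotypes`."""
    path = Path(path)
    ids: list[str] = []
    rows: list[list[float]] = []
    with _open_text(path, "r") as fh:
        header = fh.readline().split()
        n_snps = len(header) - 1
        for lineno, line in enumerate(fh, 2):
            parts = line.split()
            if len(parts) != n_snps + 1:
                raise ValueError(f"{path}:{lineno}: expected {n_snps + 1} fields, got {len(parts)}")
            ids.append(parts[0])
            rows.append([np.nan if v == "NA" else float(v) for v in parts[1:]])
    return GenotypeMatrix(ids=ids, counts=np.array(rows))
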