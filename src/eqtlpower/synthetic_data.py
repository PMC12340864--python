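"""Synthetic genotype, expression, and paired summary-statistic data.

The generator produces data with exactly the statistical structure the
analytic machinery assumes, so every downstream stage (scanning,
distribution fitting, colocalization) is testable without any cohort
download:

* Genotypes are allele counts (0/1/2) built from two haplotypes.  Each
  haplotype is a latent Gaussian AR(1) process thresholded at
  ``Phi^-1(maf)`` per variant, which gives Hardy-Weinberg marginals and
  a tunable, monotonically decaying local LD controlled by ``ld_rho``.
* Expression is a linear genetic signal plus Gaussian noise, scaled to
  unit total variance, then rank-inverse-normal transformed (RINT) --
  the standardization assumed by the power formulas.  Effects are
  planted on the latent (pre-RINT) scale; at realistic effect sizes the
  RINT changes the genotype-expression correlation by well under 0.001.
* Paired eQTL/GWAS summary statistics are produced by simulating two
  independent cohorts at the same locus and running per-variant
  regressions, with the causal variant shared or distinct between the
  traits.

All randomness flows from explicit seeds; there is no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signal_strength import beta_from_r_maf

__all__ = [
    "GenotypeMatrix",
    "SimulatedStudy",
    "LocusConfig",
    "VariantSummaryStats",
    "simulate_genotypes",
    "rank_inverse_normal",
    "simulate_expression_study",
    "simulate_summary_stats_pair",
    "BLOM_OFFSET",
]

#: Blom's rank offset, the common choice in eQTL pipelines.
BLOM_OFFSET = 0.375


@dataclass
class GenotypeMatrix:
    """Allele-count matrix (individuals x variants) with variant metadata."""

    values: np.ndarray
    mafs: np.ndarray
    positions: np.ndarray
    ld_rho: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.mafs = np.asarray(self.mafs, dtype=float)
        self.positions = np.asarray(self.positions)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (individuals x variants)")
        if self.values.shape[1] != self.mafs.size or self.mafs.size != self.positions.size:
            raise ValueError("mafs/positions length must match variant count")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path) -> None:
        """Write a simple dosage TSV: one row per individual, one column per variant."""
        cols = [f"var_{p}" for p in self.positions]
        pd.DataFrame(self.values, columns=cols).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, ld_rho: float = 0.0) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t")
        values = df.to_numpy(dtype=np.int8)
        positions = np.array([int(c.split("_")[1]) for c in df.columns])
        mafs = values.mean(axis=0) / 2.0
        mafs = np.minimum(mafs, 1.0 - mafs)
        return cls(values=values, mafs=mafs, positions=positions, ld_rho=ld_rho)


@dataclass
class SimulatedStudy:
    """Genotypes plus RINT expression and the planted truth table."""

    genotypes: GenotypeMatrix
    expression: np.ndarray
    truth: list  # list of (variant_index, beta, r)
    seed: int

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.truth, columns=["variant_index", "beta", "r"])


def simulate_genotypes(
    n: int,
    m: int,
    mafs,
    ld_rho: float = 0.0,
    positions: Optional[Sequence[int]] = None,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> GenotypeMatrix:
    """HWE genotypes with local LD from a thresholded latent AR(1) process.

    Each of the two haplotypes per individual is an AR(1) Gaussian
    vector across variants with autocorrelation ``ld_rho``; allele j is
    carried when the latent value falls below ``Phi^-1(maf_j)``.
    Marginally each variant is Bernoulli(maf) per haplotype, so HWE
    holds; adjacent variants are positively LD-correlated for
    ``ld_rho > 0`` with correlation decaying in distance.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be positive")
    mafs = np.broadcast_to(np.asarray(mafs, dtype=float), (m,)).copy()
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("all mafs must be in (0, 0.5]")
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError(f"ld_rho must be in [0, 1), got {ld_rho}")
    if positions is None:
        positions = np.arange(m) * 1000
    positions = np.asarray(positions)
    if rng is None:
        rng = np.random.default_rng(seed)

    thresholds = stats.norm.ppf(mafs)
    haplos = np.zeros((2, n, m), dtype=np.int8)
    for h in range(2):
        z = np.empty((n, m))
        z[:, 0] = rng.standard_normal(n)
        if m > 1:
            innov = rng.standard_normal((n, m - 1))
            scale = math.sqrt(1.0 - ld_rho**2)
            for j in range(1, m):
                z[:, j] = ld_rho * z[:, j - 1] + scale * innov[:, j - 1]
        haplos[h] = z < thresholds
    values = (haplos[0] + haplos[1]).astype(np.int8)
    return GenotypeMatrix(values=values, mafs=mafs, positions=positions, ld_rho=ld_rho)


def rank_inverse_normal(values, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Rank inverse normal transformation.

    Maps value i to ``Phi^-1((rank_i - offset) / (n - 2*offset + 1))``
    with average ranks for ties.  The default offset 3/8 is Blom's.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("rank_inverse_normal expects a 1-D vector")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values")
    if np.all(x == x[0]):
        raise ValueError("degenerate input: all values equal")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))


def _rint_columns(mat: np.ndarray, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Column-wise RINT for a 2-D matrix (no tie handling needed for noise)."""
    n = mat.shape[0]
    ranks = stats.rankdata(mat, method="average", axis=0)
    return stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))


def simulate_expression_study(
    genotypes: GenotypeMatrix,
    causal: Sequence[tuple[int, float]],
    noise_seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedStudy:
    """Plant causal signals and return a RINT-standardized expression study.

    ``causal`` is a list of ``(variant_index, r)`` pairs.  The latent
    expression is ``sum_k beta_k g_k + eps`` with ``beta_k`` derived
    from the planted ``r_k`` at that variant's MAF and the noise
    variance set so the latent total variance is 1 (assuming
    independent causal variants).  The returned expression is the RINT
    of the latent values.
    """
    if rng is None:
        rng = np.random.default_rng(noise_seed)
    r_total = 0.0
    for idx, r in causal:
        if not (0 <= idx < genotypes.n_variants):
            raise ValueError(f"causal variant index {idx} out of range")
        r_total += r**2
    if r_total >= 1.0:
        raise ValueError(
            f"sum of planted r^2 is {r_total:.3f} >= 1: infeasible architecture"
        )
    n = genotypes.n_individuals
    latent = np.zeros(n)
    truth = []
    for idx, r in causal:
        maf = float(genotypes.mafs[idx])
        beta = beta_from_r_maf(r, maf)
        g = genotypes.values[:, idx].astype(float)
        latent += beta * (g - 2.0 * maf)
        truth.append((idx, beta, r))
    latent += rng.normal(0.0, math.sqrt(1.0 - r_total), n)
    expression = rank_inverse_normal(latent)
    return SimulatedStudy(
        genotypes=genotypes, expression=expression, truth=truth, seed=noise_seed
    )


@dataclass
class VariantSummaryStats:
    """Per-variant marginal association statistics for one trait at one locus."""

    variant_ids: list
    betas: np.ndarray
    ses: np.ndarray
    n: int
    mafs: np.ndarray
    trait_type: str = "quantitative"

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.ses = np.asarray(self.ses, dtype=float)
        self.mafs = np.asarray(self.mafs, dtype=float)
        if not (len(self.variant_ids) == self.betas.size == self.ses.size == self.mafs.size):
            raise ValueError("summary-stat fields must have equal length")
        if np.any(self.ses <= 0):
            raise ValueError("all standard errors must be strictly positive")

    @property
    def z(self) -> np.ndarray:
        return self.betas / self.ses

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "beta": self.betas,
                "se": self.ses,
                "n": self.n,
                "maf": self.mafs,
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, trait_type: str = "quantitative") -> "VariantSummaryStats":
        df = pd.read_csv(path, sep="\t")
        for col in ("variant_id", "beta", "se", "n", "maf"):
            if col not in df.columns:
                raise ValueError(f"summary-stat table {path} missing column {col!r}")
        return cls(
            variant_ids=[str(v) for v in df["variant_id"]],
            betas=df["beta"].to_numpy(),
            ses=df["se"].to_numpy(),
            n=int(df["n"].iloc[0]),
            mafs=df["maf"].to_numpy(),
            trait_type=trait_type,
        )


def marginal_summary_stats(
    genotypes: GenotypeMatrix, phenotype: np.ndarray, prefix: str = "var"
) -> VariantSummaryStats:
    """Single-variant regression of a phenotype on each variant in turn."""
    g = genotypes.values.astype(float)
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    varg = (gc**2).sum(axis=0)
    mono = varg == 0
    varg_safe = np.where(mono, 1.0, varg)
    beta = gc.T @ yc / varg_safe
    resid_ss = (yc**2).sum() - beta**2 * varg_safe
    sigma2 = np.maximum(resid_ss, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / varg_safe)
    beta = np.where(mono, 0.0, beta)
    se = np.where(mono, np.inf, se)
    ids = [f"{prefix}_{p}" for p in genotypes.positions]
    mafs = np.minimum(g.mean(axis=0) / 2.0, 1.0 - g.mean(axis=0) / 2.0)
    # report se=large finite for monomorphic variants to keep the container valid
    se = np.where(np.isfinite(se), se, 1e6)
    return VariantSummaryStats(
        variant_ids=ids, betas=beta, ses=se, n=n, mafs=mafs, trait_type="quantitative"
    )


@dataclass
class LocusConfig:
    """Configuration for one simulated eQTL/GWAS locus pair."""

    n_variants: int = 50
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_rho: float = 0.5
    r_eqtl: float = 0.2
    r_gwas: float = 0.05
    causal_index: Optional[int] = None
    gwas_causal_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_variants < 2:
            raise ValueError("a locus needs at least 2 variants")


def simulate_summary_stats_pair(
    locus: LocusConfig,
    n_eqtl: int,
    n_gwas: int,
    shared: bool,
    seed: int = 0,
    max_retries: int = 10,
) -> tuple[VariantSummaryStats, VariantSummaryStats]:
    """Simulate an (eQTL, GWAS) pair of marginal summary statistics.

    Two independent cohorts are drawn at the same locus (same MAFs and
    LD structure).  When ``shared`` the GWAS trait's causal variant is
    the eQTL causal variant; otherwise a distinct variant is chosen.
    Monomorphic simulated variants trigger a bounded resampling retry.
    """
    if n_eqtl < 4 or n_gwas < 4:
        raise ValueError("both study sizes must be >= 4")
    rng = np.random.default_rng(seed)
    m = locus.n_variants
    mafs = rng.uniform(locus.maf_low, locus.maf_high, m)
    ci = locus.causal_index if locus.causal_index is not None else int(rng.integers(m))
    if shared:
        gi = ci
    elif locus.gwas_causal_index is not None:
        gi = locus.gwas_causal_index
    else:
        choices = [j for j in range(m) if j != ci]
        gi = int(rng.choice(choices))

    for attempt in range(max_retries):
        g_eqtl = simulate_genotypes(n_eqtl, m, mafs, locus.ld_rho, rng=rng)
        g_gwas = simulate_genotypes(n_gwas, m, mafs, locus.ld_rho, rng=rng)
        if (g_eqtl.values.std(axis=0) == 0).any() or (g_gwas.values.std(axis=0) == 0).any():
            import warnings

            warnings.warn(
                f"monomorphic simulated variant at attempt {attempt}; resampling",
                stacklevel=2,
            )
            continue
        eqtl_study = simulate_expression_study(
            g_eqtl, [(ci, locus.r_eqtl)], rng=rng
        )
        gwas_study = simulate_expression_study(
            g_gwas, [(gi, locus.r_gwas)], rng=rng
        )
        stats1 = marginal_summary_stats(g_eqtl, eqtl_study.expression)
        stats2 = marginal_summary_stats(g_gwas, gwas_study.expression)
        return stats1, stats2
    raise RuntimeError(
        f"failed to simulate a polymorphic locus in {max_retries} attempts"
    )
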