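"""Approximate-Bayes-factor colocalization and the sample-size experiment.

Given per-variant marginal summary statistics for two traits at one
locus, the single-causal-variant enumeration assigns posterior
probability to five hypotheses:

* H0 - no association with either trait
* H1 / H2 - association with trait 1 / trait 2 only
* H3 - both traits associated, distinct causal variants
* H4 - both traits associated, one shared causal variant

The per-variant evidence is Wakefield's approximate Bayes factor.  With
``V = se**2``, ``W`` the prior variance of the effect and shrinkage
``k = W / (V + W)``::

    log ABF = 0.5 * log(1 - k) + 0.5 * z**2 * k,   z = beta / se

Hypothesis sums are accumulated on the log-sum-exp scale, so the
enumeration is stable for arbitrarily strong signals.

The module also hosts the sample-size experiment: simulate many loci
with eQTL strengths drawn from a signal-strength distribution, a fixed
fraction of loci sharing the GWAS causal variant, and compare the
number of colocalizing GWAS loci between a small and a large eQTL
study.  A GWAS locus counts as colocalized when PPH4 >= 0.5 against at
least one *detected* eQTL (lead p below the scan threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .power_analysis import DEFAULT_ALPHA
from .signal_distribution import SignalStrengthDistribution, decile_edges, assign_decile
from .synthetic_data import LocusConfig, VariantSummaryStats, simulate_summary_stats_pair

__all__ = [
    "ColocResult",
    "ColocPriors",
    "log_abf",
    "coloc_abf",
    "ColocScenario",
    "coloc_experiment",
    "DEFAULT_PRIOR_SD_QUANTITATIVE",
    "DEFAULT_PRIOR_SD_CASE_CONTROL",
]

#: Field-standard single-variant priors.
DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5
#: Prior effect-size SD for quantitative traits / case-control log-odds.
DEFAULT_PRIOR_SD_QUANTITATIVE = 0.15
DEFAULT_PRIOR_SD_CASE_CONTROL = 0.2


@dataclass(frozen=True)
class ColocPriors:
    p1: float = DEFAULT_P1
    p2: float = DEFAULT_P2
    p12: float = DEFAULT_P12

    def __post_init__(self) -> None:
        for name, v in (("p1", self.p1), ("p2", self.p2), ("p12", self.p12)):
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    priors: ColocPriors
    prior_effect_sd: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "pph0": self.pph0,
            "pph1": self.pph1,
            "pph2": self.pph2,
            "pph3": self.pph3,
            "pph4": self.pph4,
            "p1": self.priors.p1,
            "p2": self.priors.p2,
            "p12": self.priors.p12,
            "prior_effect_sd_trait1": self.prior_effect_sd[0],
            "prior_effect_sd_trait2": self.prior_effect_sd[1],
        }


def log_abf(beta, se, prior_effect_sd: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor (association vs null)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be strictly positive")
    if prior_effect_sd <= 0:
        raise ValueError(f"prior_effect_sd must be > 0, got {prior_effect_sd}")
    v = se**2
    w = prior_effect_sd**2
    k = w / (v + w)
    z = beta / se
    return 0.5 * np.log1p(-k) + 0.5 * z**2 * k


def _prior_sd_for(stats_: VariantSummaryStats) -> float:
    if stats_.trait_type == "case_control":
        return DEFAULT_PRIOR_SD_CASE_CONTROL
    return DEFAULT_PRIOR_SD_QUANTITATIVE


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b; -inf when equal within rounding."""
    if b >= a:
        return -np.inf
    return a + math.log1p(-math.exp(b - a))


def coloc_abf(
    stats1: VariantSummaryStats,
    stats2: VariantSummaryStats,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
    prior_sd1: Optional[float] = None,
    prior_sd2: Optional[float] = None,
) -> ColocResult:
    """Single-causal-variant colocalization of two traits at one locus.

    Both traits must present the same variants in the same order
    (harmonized upstream).
    """
    if stats1.variant_ids != stats2.variant_ids:
        raise ValueError(
            "variant sets differ between traits; harmonize before colocalizing"
        )
    if len(stats1.variant_ids) < 2:
        raise ValueError("need at least 2 variants for colocalization")
    priors = ColocPriors(p1=p1, p2=p2, p12=p12)
    sd1 = prior_sd1 if prior_sd1 is not None else _prior_sd_for(stats1)
    sd2 = prior_sd2 if prior_sd2 is not None else _prior_sd_for(stats2)

    la = log_abf(stats1.betas, stats1.ses, sd1)
    lb = log_abf(stats2.betas, stats2.ses, sd2)
    s1 = float(logsumexp(la))
    s2 = float(logsumexp(lb))
    s12 = float(logsumexp(la + lb))

    lh0 = 0.0
    lh1 = math.log(p1) + s1
    lh2 = math.log(p2) + s2
    lh3 = math.log(p1) + math.log(p2) + _logdiffexp(s1 + s2, s12)
    lh4 = math.log(p12) + s12
    logs = np.array([lh0, lh1, lh2, lh3, lh4])
    post = np.exp(logs - logsumexp(logs))
    post /= post.sum()
    return ColocResult(
        pph0=float(post[0]),
        pph1=float(post[1]),
        pph2=float(post[2]),
        pph3=float(post[3]),
        pph4=float(post[4]),
        priors=priors,
        prior_effect_sd=(sd1, sd2),
    )


@dataclass
class ColocScenario:
    """Configuration of the eQTL-sample-size colocalization experiment.

    Each locus carries one eQTL signal with strength drawn from
    ``dist`` and a GWAS signal whose causal variant is shared with
    probability ``shared_fraction``; otherwise the GWAS causal variant
    is a different (possibly LD-linked) variant at the locus.
    """

    n_loci: int = 200
    shared_fraction: float = 0.3
    n_eqtl_small: int = 420
    n_eqtl_large: int = 2256
    n_gwas: int = 10000
    r_gwas: float = 0.06
    n_variants: int = 40
    ld_rho: float = 0.5
    maf_low: float = 0.05
    maf_high: float = 0.5
    dist: SignalStrengthDistribution = field(
        default_factory=lambda: SignalStrengthDistribution(
            mu=-2.3, sigma=0.6, source_label="synthetic eQTL signal strengths"
        )
    )
    alpha_eqtl: float = DEFAULT_ALPHA
    pph4_threshold: float = 0.5
    p1: float = DEFAULT_P1
    p2: float = DEFAULT_P2
    p12: float = DEFAULT_P12

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("scenario must define at least one locus")
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError("shared_fraction must be in [0, 1]")


@dataclass
class ColocExperimentReport:
    """Counts and decile-stratified proportions from one experiment run."""

    counts: dict  # arm ("small"/"large") -> number of colocalized GWAS loci
    n_detected: dict  # arm -> number of detected eQTL signals
    sizes: dict  # arm -> eQTL sample size
    fold_change: float
    per_locus: pd.DataFrame
    decile_table: pd.DataFrame  # colocalization proportion by r decile (large study)
    scenario: ColocScenario
    seed: int


def coloc_experiment(scenario: ColocScenario, seed: int = 0) -> ColocExperimentReport:
    """Run the sample-size colocalization experiment.

    For each locus and each eQTL study size, the eQTL is "detected"
    when its lead variant's marginal p-value clears the scan threshold;
    detected eQTL are then tested for colocalization against the (size-
    independent) GWAS statistics of the locus.  The report carries the
    count of colocalized GWAS loci per study size, their fold change,
    and the proportion of detected signals colocalizing by decile of
    the planted signal strength in the large study.
    """
    rng = np.random.default_rng(seed)
    arms = {"small": scenario.n_eqtl_small, "large": scenario.n_eqtl_large}
    rows = []
    r_values = scenario.dist.sample(scenario.n_loci, rng)
    r_values = np.clip(r_values, 1e-4, 0.9)
    shared_flags = rng.random(scenario.n_loci) < scenario.shared_fraction
    from scipy import stats as sps

    for i in range(scenario.n_loci):
        locus = LocusConfig(
            n_variants=scenario.n_variants,
            maf_low=scenario.maf_low,
            maf_high=scenario.maf_high,
            ld_rho=scenario.ld_rho,
            r_eqtl=float(r_values[i]),
            r_gwas=scenario.r_gwas,
        )
        locus_seed = int(rng.integers(2**30 - 2))
        for k, (arm, n_eqtl) in enumerate(arms.items()):
            eqtl_stats, gwas_stats = simulate_summary_stats_pair(
                locus,
                n_eqtl=n_eqtl,
                n_gwas=scenario.n_gwas,
                shared=bool(shared_flags[i]),
                seed=2 * locus_seed + k,
            )
            z = eqtl_stats.z
            t_abs = np.abs(z)
            pvals = 2.0 * sps.t.sf(t_abs, n_eqtl - 2)
            detected = bool(pvals.min() < scenario.alpha_eqtl)
            if detected:
                res = coloc_abf(
                    eqtl_stats,
                    gwas_stats,
                    p1=scenario.p1,
                    p2=scenario.p2,
                    p12=scenario.p12,
                )
                pph4 = res.pph4
            else:
                pph4 = float("nan")
            rows.append(
                {
                    "locus": i,
                    "arm": arm,
                    "n_eqtl": n_eqtl,
                    "r_eqtl": float(r_values[i]),
                    "shared": bool(shared_flags[i]),
                    "detected": detected,
                    "pph4": pph4,
                    "colocalized": detected and pph4 >= scenario.pph4_threshold,
                }
            )
    per_locus = pd.DataFrame(rows)
    counts = {
        arm: int(per_locus.query("arm == @arm")["colocalized"].sum())
        for arm in arms
    }
    n_detected = {
        arm: int(per_locus.query("arm == @arm")["detected"].sum()) for arm in arms
    }
    small, large = counts["small"], counts["large"]
    fold = float(large) / small if small > 0 else float("inf") if large > 0 else 1.0

    # decile stratification of detected signals in the large study
    big = per_locus.query("arm == 'large' and detected").copy()
    if len(big) >= 10 and np.unique(np.abs(big["r_eqtl"])).size >= 10:
        bins = decile_edges(big["r_eqtl"].to_numpy())
        big["decile"] = [assign_decile(r, bins) for r in big["r_eqtl"]]
        decile_table = (
            big.groupby("decile")["colocalized"]
            .agg(n_signals="size", n_coloc="sum", proportion="mean")
            .reset_index()
        )
    else:
        decile_table = pd.DataFrame(
            columns=["decile", "n_signals", "n_coloc", "proportion"]
        )
    return ColocExperimentReport(
        counts=counts,
        n_detected=n_detected,
        sizes=dict(arms),
        fold_change=fold,
        per_locus=per_locus,
        decile_table=decile_table,
        scenario=scenario,
        seed=seed,
    )
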