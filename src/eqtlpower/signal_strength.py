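"""Effect-size algebra for eQTL signal strength.

An eQTL signal is a conditionally distinct association between a variant
and a gene's expression.  Its strength can be summarized by the Pearson
correlation *r* between allele count and (unit-variance) expression.
Under Hardy-Weinberg equilibrium the genotype variance on allele-count
coding is ``2*maf*(1-maf)``, so for expression standardized to unit
variance::

    r = beta * sqrt(2 * maf * (1 - maf))

where ``beta`` is the per-allele effect on the standardized scale.
``r**2`` is the fraction of expression variance explained by genotype,
which makes *r* comparable across variants with different allele
frequencies and across studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "EqtlSignal",
    "r_from_beta_maf",
    "beta_from_r_maf",
    "variance_explained",
    "fold_maf",
    "read_signal_table",
    "write_signal_table",
    "SIGNAL_TABLE_COLUMNS",
]

#: Canonical column order of the signal-table TSV format.
SIGNAL_TABLE_COLUMNS = [
    "gene_id",
    "variant_id",
    "beta",
    "se",
    "maf",
    "p_value",
    "rank",
    "tss_distance",
    "r",
]


def _check_maf(maf: float) -> None:
    if not (0.0 < maf <= 0.5):
        raise ValueError(f"maf must be in (0, 0.5], got {maf!r}")


def r_from_beta_maf(beta: float, maf: float) -> float:
    """Signal strength *r* implied by a per-allele effect and allele frequency.

    Parameters
    ----------
    beta
        Per-allele effect on expression standardized to unit variance
        (expression-SD per allele).
    maf
        Minor allele frequency, in ``(0, 0.5]``.

    Returns
    -------
    float
        ``beta * sqrt(2*maf*(1-maf))``; carries the sign of ``beta``.

    Raises
    ------
    ValueError
        If ``maf`` is outside ``(0, 0.5]`` or the implied ``|r| >= 1``
        (infeasible for a correlation).
    """
    _check_maf(maf)
    r = beta * math.sqrt(2.0 * maf * (1.0 - maf))
    if abs(r) >= 1.0:
        raise ValueError(
            f"beta={beta}, maf={maf} imply |r|={abs(r):.4f} >= 1: "
            "infeasible effect for unit-variance expression"
        )
    return r


def beta_from_r_maf(r: float, maf: float) -> float:
    """Per-allele effect implied by signal strength *r* at a given MAF.

    Inverse of :func:`r_from_beta_maf`: ``beta = r / sqrt(2*maf*(1-maf))``.
    """
    _check_maf(maf)
    if abs(r) >= 1.0:
        raise ValueError(f"|r| must be < 1, got {r!r}")
    return r / math.sqrt(2.0 * maf * (1.0 - maf))


def variance_explained(r: float) -> float:
    """Fraction of expression variance explained by genotype (``r**2``)."""
    if abs(r) >= 1.0:
        raise ValueError(f"|r| must be < 1, got {r!r}")
    return r * r


def fold_maf(af: float, beta: Optional[float] = None) -> tuple[float, Optional[float]]:
    """Fold an allele frequency onto the minor allele.

    Frequencies above 0.5 are replaced by ``1 - af`` and the effect sign
    is flipped so that ``beta`` refers to the minor allele.
    """
    if not (0.0 < af < 1.0):
        raise ValueError(f"allele frequency must be in (0, 1), got {af!r}")
    if af > 0.5:
        return 1.0 - af, (None if beta is None else -beta)
    return af, beta


@dataclass
class EqtlSignal:
    """One conditionally distinct gene-variant association.

    ``rank`` is 1 for the primary signal and >1 for signals found after
    conditioning on stronger ones.  ``tss_distance`` is the absolute
    distance in base pairs from the lead variant to the gene's TSS.
    When ``beta``, ``maf`` and ``r`` are all present they must be
    mutually consistent (``|r| = |beta| * sqrt(2*maf*(1-maf))``).
    """

    gene_id: str
    variant_id: str
    beta: Optional[float] = None
    maf: Optional[float] = None
    se: Optional[float] = None
    r: Optional[float] = None
    rank: int = 1
    tss_distance: Optional[int] = None
    p_value: Optional[float] = None
    chrom: Optional[str] = None
    position: Optional[int] = None  # 1-based variant coordinate
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.maf is not None:
            maf, beta = fold_maf(self.maf, self.beta)
            if maf != self.maf:
                self.maf = maf
                self.beta = beta
                if self.r is not None:
                    self.r = -self.r
            _check_maf(self.maf)
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")
        if self.r is not None and abs(self.r) >= 1.0:
            raise ValueError(f"|r| must be < 1, got {self.r}")
        if self.r is None and self.beta is not None and self.maf is not None:
            self.r = r_from_beta_maf(self.beta, self.maf)
        elif self.r is not None and self.beta is not None and self.maf is not None:
            expected = r_from_beta_maf(self.beta, self.maf)
            if abs(abs(self.r) - abs(expected)) > 1e-9:
                raise ValueError(
                    f"inconsistent signal: r={self.r} but beta/maf imply {expected}"
                )
        if self.tss_distance is not None and self.tss_distance < 0:
            raise ValueError("tss_distance must be non-negative")
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")

    @property
    def abs_r(self) -> float:
        if self.r is None:
            raise ValueError("signal has no r value")
        return abs(self.r)

    def variance_explained(self) -> float:
        return variance_explained(self.abs_r)


def signals_to_frame(signals: Iterable[EqtlSignal]) -> pd.DataFrame:
    """Collect signals into a DataFrame in the canonical column order."""
    rows = []
    for s in signals:
        rows.append(
            {
                "gene_id": s.gene_id,
                "variant_id": s.variant_id,
                "beta": s.beta,
                "se": s.se,
                "maf": s.maf,
                "p_value": s.p_value,
                "rank": s.rank,
                "tss_distance": s.tss_distance,
                "r": s.r,
            }
        )
    return pd.DataFrame(rows, columns=SIGNAL_TABLE_COLUMNS)


def write_signal_table(signals: Iterable[EqtlSignal], path) -> None:
    """Write signals to the tab-separated signal-table format."""
    signals_to_frame(signals).to_csv(path, sep="\t", index=False)


def read_signal_table(path) -> list[EqtlSignal]:
    """Read a signal-table TSV.

    The header is required.  The ``r`` column is optional and is
    computed from ``beta`` and ``maf`` when absent.  Frequencies above
    0.5 are folded to the minor allele on ingest.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "variant_id", "beta", "maf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"signal table {path} missing columns: {sorted(missing)}")

    def _opt(row, col, cast=float):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return cast(row[col])

    out = []
    for _, row in df.iterrows():
        out.append(
            EqtlSignal(
                gene_id=str(row["gene_id"]),
                variant_id=str(row["variant_id"]),
                beta=float(row["beta"]),
                maf=float(row["maf"]),
                se=_opt(row, "se"),
                p_value=_opt(row, "p_value"),
                rank=int(row["rank"]) if "rank" in df.columns and not pd.isna(row["rank"]) else 1,
                tss_distance=_opt(row, "tss_distance", int),
                r=_opt(row, "r"),
            )
        )
    return out
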