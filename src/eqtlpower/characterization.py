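"""Decile-stratified characterization of eQTL signals.

Weak eQTL signals — the ones only larger studies can detect — look
more like GWAS signals than strong ones: they sit further from the
TSS of their gene, overlap promoters less and distal enhancers more,
and are more often attached to loss-intolerant (high-pLI) or
transcription-factor genes.  This module computes those per-decile
summaries from a signal table plus generic annotation inputs (BED
interval tracks and plain gene-ID lists).

Coordinate conventions: BED intervals are 0-based half-open; variant
positions are 1-based and converted on ingest, with a variant treated
as a length-1 interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .signal_distribution import DecileBins, assign_decile
from .signal_strength import EqtlSignal

__all__ = [
    "AnnotationSet",
    "read_bed",
    "read_gene_list",
    "tss_distance_by_decile",
    "fraction_beyond",
    "annotation_overlap_by_decile",
]


def read_bed(path) -> dict[str, np.ndarray]:
    """Read a BED3 file into per-chromosome sorted (start, end) arrays."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line") from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            intervals.setdefault(chrom, []).append((start, end))
    return {
        chrom: np.array(sorted(ivs), dtype=np.int64)
        for chrom, ivs in intervals.items()
    }


def read_gene_list(path) -> set[str]:
    """Read a plain-text gene-ID list (one identifier per line)."""
    out = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                out.add(g)
    return out


@dataclass
class AnnotationSet:
    """Promoter/enhancer interval tracks plus high-pLI and TF gene flags."""

    promoters: dict[str, np.ndarray] = field(default_factory=dict)
    enhancers: dict[str, np.ndarray] = field(default_factory=dict)
    high_pli_genes: set = field(default_factory=set)
    tf_genes: set = field(default_factory=set)

    @classmethod
    def from_files(cls, promoters=None, enhancers=None, pli=None, tf=None):
        return cls(
            promoters=read_bed(promoters) if promoters else {},
            enhancers=read_bed(enhancers) if enhancers else {},
            high_pli_genes=read_gene_list(pli) if pli else set(),
            tf_genes=read_gene_list(tf) if tf else set(),
        )


def _point_in_intervals(track: dict[str, np.ndarray], chrom: str, pos_1based: int) -> bool:
    """Containment of a 1-based variant position in a 0-based half-open track."""
    ivs = track.get(chrom)
    if ivs is None or ivs.size == 0:
        return False
    p = pos_1based - 1
    return bool(np.any((ivs[:, 0] <= p) & (p < ivs[:, 1])))


def _signal_position(sig: EqtlSignal) -> tuple[str, int]:
    if sig.position is not None:
        return (sig.chrom or "1", int(sig.position))
    # fall back to "chrom:pos" encoded variant identifiers
    parts = sig.variant_id.replace("_", ":").split(":")
    for i in range(len(parts) - 1):
        if parts[i + 1].isdigit():
            return (parts[i], int(parts[i + 1]))
    raise ValueError(
        f"signal {sig.variant_id} carries no lead-variant position"
    )


def tss_distance_by_decile(
    signals: Sequence[EqtlSignal], bins: DecileBins
) -> pd.DataFrame:
    """Count, median, and quartiles of |TSS distance| per decile of |r|."""
    rows = {k: [] for k in range(1, 11)}
    for sig in signals:
        if sig.tss_distance is None:
            raise ValueError(f"signal {sig.variant_id} lacks tss_distance")
        rows[assign_decile(sig, bins)].append(abs(sig.tss_distance))
    out = []
    for k in range(1, 11):
        d = np.asarray(rows[k], dtype=float)
        if d.size:
            out.append(
                {
                    "decile": k,
                    "count": d.size,
                    "median": float(np.median(d)),
                    "q1": float(np.percentile(d, 25)),
                    "q3": float(np.percentile(d, 75)),
                }
            )
        else:
            out.append(
                {"decile": k, "count": 0, "median": np.nan, "q1": np.nan, "q3": np.nan}
            )
    return pd.DataFrame(out)


def fraction_beyond(signals: Sequence[EqtlSignal], threshold_bp: int) -> float:
    """Fraction of signals at TSS distance >= threshold (inclusive)."""
    if threshold_bp < 0:
        raise ValueError("threshold must be non-negative")
    dists = [abs(s.tss_distance) for s in signals if s.tss_distance is not None]
    if len(dists) != len(signals):
        raise ValueError("all signals must carry tss_distance")
    if not dists:
        return 0.0
    return float(np.mean(np.asarray(dists) >= threshold_bp))


def annotation_overlap_by_decile(
    signals: Sequence[EqtlSignal],
    annotations: AnnotationSet,
    bins: DecileBins,
) -> pd.DataFrame:
    """Per-decile proportions: promoter, enhancer, high-pLI, TF."""
    buckets: dict[int, dict[str, list[bool]]] = {
        k: {"promoter": [], "enhancer": [], "high_pli": [], "tf": []}
        for k in range(1, 11)
    }
    for sig in signals:
        k = assign_decile(sig, bins)
        chrom, pos = _signal_position(sig)
        buckets[k]["promoter"].append(
            _point_in_intervals(annotations.promoters, chrom, pos)
        )
        buckets[k]["enhancer"].append(
            _point_in_intervals(annotations.enhancers, chrom, pos)
        )
        buckets[k]["high_pli"].append(sig.gene_id in annotations.high_pli_genes)
        buckets[k]["tf"].append(sig.gene_id in annotations.tf_genes)
    out = []
    for k in range(1, 11):
        b = buckets[k]
        n = len(b["promoter"])
        row = {"decile": k, "count": n}
        for key in ("promoter", "enhancer", "high_pli", "tf"):
            row[f"prop_{key}"] = float(np.mean(b[key])) if n else np.nan
        out.append(row)
    return pd.DataFrame(out)
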