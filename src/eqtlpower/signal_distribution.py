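"""Signal-strength distributions, detection fractions, and decile bins.

The absolute signal strengths ``|r|`` observed across all signals of an
eQTL study are well described by a log-normal distribution.  Fitting
that distribution and integrating the analytic power curve against it
answers the design question "what fraction of all eQTL signals would a
study of size n detect?"::

    detection_fraction(n) = integral_0^1 power(r, n) f(r) dr

where ``f`` is the fitted density truncated and renormalized on (0, 1)
(|r| < 1 by definition while the log-normal has unbounded support).

A caveat that matters for interpretation: fitting to *detected* signals
over-represents strong effects (detection truncation / winner's curse),
so detection fractions computed from such a fit are optimistic.  The
fit is deliberately a plain maximum-likelihood fit with no truncation
correction; reports carry a note to that effect.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .power_analysis import DEFAULT_ALPHA, power
from .signal_strength import EqtlSignal

__all__ = [
    "SignalStrengthDistribution",
    "DecileBins",
    "fit_lognormal",
    "detection_fraction",
    "decile_edges",
    "assign_decile",
    "TRUNCATION_NOTE",
]

TRUNCATION_NOTE = (
    "Fitted to detected signals without truncation correction; the "
    "distribution is biased toward strong effects and detection "
    "fractions computed from it are optimistic."
)


@dataclass
class SignalStrengthDistribution:
    """Log-normal model for ``|r|`` over all signals of a study.

    ``mu`` and ``sigma`` are the mean and SD of ``log|r|``.  A
    ``sigma`` of exactly 0 denotes a degenerate point mass at
    ``exp(mu)`` (useful for reducing the detection-fraction integral
    to the plain power function).
    """

    mu: float
    sigma: float
    n_signals: int = 0
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def is_point_mass(self) -> bool:
        return self.sigma == 0.0

    @classmethod
    def point_mass(cls, r: float, source_label: str = "point mass") -> "SignalStrengthDistribution":
        if not (0.0 < r < 1.0):
            raise ValueError(f"point mass location must be in (0, 1), got {r}")
        return cls(mu=math.log(r), sigma=0.0, source_label=source_label)

    def pdf(self, r):
        """Density on (0, inf); not truncated (see :func:`detection_fraction`)."""
        if self.is_point_mass:
            raise ValueError("point-mass distribution has no density")
        return stats.lognorm.pdf(r, s=self.sigma, scale=math.exp(self.mu))

    def cdf(self, r):
        if self.is_point_mass:
            return (np.asarray(r) >= math.exp(self.mu)).astype(float)
        return stats.lognorm.cdf(r, s=self.sigma, scale=math.exp(self.mu))

    def mass_above_one(self) -> float:
        """Probability mass at |r| >= 1; should be negligible for real fits."""
        if self.is_point_mass:
            return 0.0
        return float(stats.lognorm.sf(1.0, s=self.sigma, scale=math.exp(self.mu)))

    def sample(self, size: int, rng: np.random.Generator, truncate: bool = True) -> np.ndarray:
        """Draw |r| values; with ``truncate``, redraw any values >= 1."""
        if self.is_point_mass:
            return np.full(size, math.exp(self.mu))
        out = rng.lognormal(self.mu, self.sigma, size)
        if truncate:
            while True:
                bad = out >= 1.0
                if not bad.any():
                    break
                out[bad] = rng.lognormal(self.mu, self.sigma, int(bad.sum()))
        return out

    def to_json(self, path) -> None:
        d = asdict(self)
        d["note"] = TRUNCATION_NOTE
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SignalStrengthDistribution":
        with open(path) as fh:
            d = json.load(fh)
        d.pop("note", None)
        return cls(**d)


def fit_lognormal(
    r_values: Sequence[float], source_label: str = ""
) -> SignalStrengthDistribution:
    """Maximum-likelihood log-normal fit to observed ``|r|`` values.

    ``mu`` is the mean and ``sigma`` the SD (denominator ``n``) of the
    log values.  Requires at least 10 values strictly inside (0, 1).
    """
    r = np.asarray(r_values, dtype=float)
    if r.size < 10:
        raise ValueError(f"need >= 10 values to fit, got {r.size}")
    if np.any(r <= 0.0) or np.any(r >= 1.0):
        raise ValueError("all |r| values must lie strictly in (0, 1)")
    logs = np.log(r)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs, ddof=0))
    if sigma < 1e-12:
        raise ValueError("degenerate fit: all values identical (sigma = 0)")
    return SignalStrengthDistribution(
        mu=mu, sigma=sigma, n_signals=int(r.size), source_label=source_label
    )


_R_LO = 1e-6
_R_HI = 1.0 - 1e-6


def detection_fraction(
    dist: SignalStrengthDistribution,
    n: int,
    alpha: float = DEFAULT_ALPHA,
    method: str = "noncentral_t",
    rtol: float = 1e-6,
) -> float:
    """Expected fraction of all signals detected at sample size ``n``.

    Gauss-Legendre quadrature of ``power(r, n) * f(r)`` on the log-r
    scale over ``r in [1e-6, 1-1e-6]``, with the log-normal density
    renormalized to unit mass on (0, 1).  The rule is refined (point
    count doubled from 256) until successive estimates differ by less
    than ``rtol``.
    """
    if n < 4:
        raise ValueError(f"n must be >= 4, got {n}")
    if dist.is_point_mass:
        return float(power(math.exp(dist.mu), n, alpha, method))

    norm = float(stats.lognorm.cdf(1.0, s=dist.sigma, scale=math.exp(dist.mu)))
    if norm <= 0:
        raise ValueError("distribution has no mass on (0, 1)")
    a, b = math.log(_R_LO), math.log(_R_HI)

    def estimate(npts: int) -> float:
        x, w = np.polynomial.legendre.leggauss(npts)
        u = 0.5 * (b - a) * x + 0.5 * (b + a)  # log r
        r = np.exp(u)
        # density of log r is normal(mu, sigma); jacobian dr = r du cancels
        # with f(r) = phi(log r) / r, leaving phi(log r) du.
        dens = stats.norm.pdf(u, loc=dist.mu, scale=dist.sigma) / norm
        pw = power(r, n, alpha, method)
        return float(0.5 * (b - a) * np.sum(w * dens * pw))

    prev = estimate(256)
    for npts in (512, 1024, 2048, 4096):
        cur = estimate(npts)
        if abs(cur - prev) < rtol:
            return min(max(cur, 0.0), 1.0)
        prev = cur
    raise RuntimeError(
        f"detection-fraction quadrature did not converge (last delta "
        f"{abs(cur - prev):.2e} at {npts} points; mu={dist.mu}, sigma={dist.sigma}, n={n})"
    )


@dataclass
class DecileBins:
    """Decile bin edges for |r|: 11 ascending values from 0 to 1.

    Bin ``k`` (1-based) is the left-open, right-closed interval
    ``(edges[k-1], edges[k]]``.
    """

    edges: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.shape != (11,):
            raise ValueError("DecileBins requires exactly 11 edges")
        if self.edges[0] != 0.0 or self.edges[-1] != 1.0:
            raise ValueError("edges must start at 0 and end at 1")
        if np.any(np.diff(self.edges) < 0):
            raise ValueError("edges must be non-decreasing")
        if np.any(np.diff(self.edges) == 0):
            warnings.warn("degenerate decile bins: some edges collapsed", stacklevel=3)

    def __len__(self) -> int:
        return 10


def decile_edges(r_values: Sequence[float]) -> DecileBins:
    """Decile edges from observed |r| via order-statistic quantiles.

    Uses the inverse-empirical-CDF (type-1) quantile: the k-th decile
    edge is the ``ceil(k/10 * n)``-th order statistic.  The outer edges
    are pinned to 0 and 1 so the ten intervals ``(a, b]`` cover (0, 1].
    """
    r = np.sort(np.abs(np.asarray(r_values, dtype=float)))
    if r.size < 10:
        raise ValueError(f"need >= 10 values for decile edges, got {r.size}")
    qs = [r[math.ceil(k / 10.0 * r.size) - 1] for k in range(1, 10)]
    return DecileBins(np.array([0.0, *qs, 1.0]))


def assign_decile(signal, bins: DecileBins) -> int:
    """Decile index (1..10) of a signal's |r| under right-closed bins."""
    if isinstance(signal, EqtlSignal):
        value = signal.abs_r
    else:
        value = abs(float(signal))
    if value <= 0.0:
        raise ValueError("|r| = 0 is below the support of the decile bins")
    if value > 1.0:
        raise ValueError(f"|r| must be <= 1, got {value}")
    idx = int(np.searchsorted(bins.edges, value, side="left"))
    return min(max(idx, 1), 10)
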